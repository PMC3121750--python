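"""Genomic-relationship heritability: GRM, relatedness pruning, REML.

Single-component restricted maximum likelihood on the observed (0/1)
case-control scale, with the variance structure
``Var(y) = sigma_g^2 GRM + sigma_e^2 I``.  The estimated observed-scale
heritability is transformed to the liability scale with the prevalence-
and ascertainment-dependent factor (see
:func:`archpipe.liability.liability_scale_transform`).

The implementation eigendecomposes the GRM once, after which each REML
iteration is O(n p^2): average-information (AI) updates with an EM step
fallback when an AI step would leave the parameter space, matching the
strategy of large-scale variance-component software at desk scale.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import MISSING, Cohort
from .liability import liability_scale_transform

__all__ = [
    "GRM",
    "RemlFit",
    "compute_grm",
    "prune_related",
    "reml_h2",
    "matched_subsample",
    "write_grm",
    "read_grm",
]


@dataclass(frozen=True)
class GRM:
    """Genetic relationship matrix with sample ids and SNP count."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    m_snps: int

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")


@dataclass(frozen=True)
class RemlFit:
    """REML variance-component fit on the observed scale.

    ``h2_obs`` is sigma_g^2 / (sigma_g^2 + sigma_e^2); ``h2_liab`` its
    liability-scale transform given prevalence ``K`` and sample case
    fraction ``P``; confidence intervals by the delta method (the
    liability transform is linear in ``h2_obs``).
    """

    h2_obs: float
    se_obs: float
    h2_liab: float
    se_liab: float
    ci_obs: tuple[float, float]
    ci_liab: tuple[float, float]
    sigma_g: float
    sigma_e: float
    K: float
    P: float
    loglik: float
    loglik_trace: tuple[float, ...]
    n_iter: int
    converged: bool


def compute_grm(genotypes: np.ndarray, sample_ids=None) -> GRM:
    """Standardized-dosage GRM: ``A_jk = (1/m) sum_i z_ij z_ik``.

    ``z`` is the dosage centered at twice the sample allele frequency and
    scaled by ``sqrt(2 p (1-p))``.  Missing dosages are mean-imputed per
    SNP (contributing zero after centering); monomorphic SNPs are
    excluded.
    """
    g = genotypes.astype(np.float64)
    g[genotypes == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    g = g[:, poly]
    p = p[poly]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.nan_to_num(z)
    m = z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    A = (z @ z.T) / m
    if sample_ids is None:
        sample_ids = tuple(str(i) for i in range(A.shape[0]))
    return GRM(values=A, sample_ids=tuple(map(str, sample_ids)), m_snps=m)


def prune_related(grm: GRM, threshold: float = 0.025) -> list[str]:
    """Greedy relatedness pruning; returns the retained sample ids.

    Repeatedly removes the sample involved in the most over-threshold
    relationships (ties broken by sample id) until no off-diagonal entry
    exceeds ``threshold``.
    """
    A = np.abs(grm.values.copy())
    np.fill_diagonal(A, 0.0)
    active = np.ones(len(grm.sample_ids), dtype=bool)
    ids = np.array(grm.sample_ids)
    while True:
        over = (A > threshold) & active[:, None] & active[None, :]
        deg = over.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        worst = deg.max()
        cand = np.flatnonzero(deg == worst)
        # deterministic tie-break by sample id
        drop = cand[np.argsort(ids[cand])[0]]
        active[drop] = False
        if active.sum() <= 1:
            break
    return [sid for sid, a in zip(grm.sample_ids, active) if a]


def _reml_loglik(
    lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray, sg: float, se: float
) -> float:
    """Restricted log-likelihood in the GRM eigenbasis (constants dropped)."""
    d = sg * lam + se
    if np.any(d <= 0):
        return -np.inf
    Xtd = Xt / d[:, None]
    XtVX = Xt.T @ Xtd
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, Xtd.T @ yt)
    r = yt - Xt @ beta
    quad = r @ (r / d)
    return -0.5 * (np.sum(np.log(d)) + logdet_x + quad)


def reml_h2(
    grm: GRM,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    K: float = 0.01,
    P: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RemlFit:
    """Single-GRM REML on a 0/1 phenotype with liability-scale transform.

    AI-REML iterations in the eigenbasis of the GRM, EM fallback when an
    AI update leaves the admissible region (variance components are
    constrained to a small positive floor).  Convergence when the change
    in restricted log-likelihood is below ``tol``.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        # standardize columns so the rank check and linear solves are
        # insensitive to covariate scale; zero-variance columns are dropped
        sd = covariates.std(axis=0)
        covariates = (covariates[:, sd > 0] - covariates[:, sd > 0].mean(axis=0)) / sd[sd > 0]
        X = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    if P is None:
        P = float(y.mean())

    lam, U = np.linalg.eigh(grm.values)
    yt = U.T @ y
    Xt = U.T @ X

    vp = float(np.var(y, ddof=1))
    floor = 1e-8 * vp
    sg, se = 0.5 * vp, 0.5 * vp
    ll = _reml_loglik(lam, yt, Xt, sg, se)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = sg * lam + se
        Xtd = Xt / d[:, None]
        XtVX = Xt.T @ Xtd
        XtVX_inv = np.linalg.inv(XtVX)
        beta = XtVX_inv @ (Xtd.T @ yt)
        r = yt - Xt @ beta
        Py = r / d
        # P-projected quantities: P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1
        # acting on a vector v in the eigenbasis
        def Pv(v: np.ndarray) -> np.ndarray:
            vd = v / d
            return vd - Xtd @ (XtVX_inv @ (Xt.T @ vd))

        PGPy = Pv(lam * Py)
        PPy = Pv(Py)
        # first derivatives: dl/ds_g = -0.5(tr(P G) - y'P G P y)
        tr_PG = np.sum(lam / d) - np.einsum(
            "ij,jk,ik->", Xtd, XtVX_inv, Xt * (lam / d)[:, None]
        )
        tr_P = np.sum(1.0 / d) - np.einsum(
            "ij,jk,ik->", Xtd, XtVX_inv, Xt * (1.0 / d)[:, None]
        )
        score = np.array(
            [
                -0.5 * (tr_PG - Py @ (lam * Py)),
                -0.5 * (tr_P - Py @ Py),
            ]
        )
        AI = 0.5 * np.array(
            [
                [(lam * Py) @ PGPy, (lam * Py) @ PPy],
                [(lam * Py) @ PPy, Py @ PPy],
            ]
        )
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            cand = np.array([sg, se]) + step
            if np.all(cand > floor):
                cand_ll = _reml_loglik(lam, yt, Xt, cand[0], cand[1])
                if cand_ll >= trace[-1] - 1e-12:
                    new = (cand[0], cand[1], cand_ll)
        if new is None:
            # EM update: always admissible, monotone
            n_eff = n - X.shape[1]
            sg_em = sg + (sg**2 / n_eff) * (Py @ (lam * Py) - tr_PG)
            se_em = se + (se**2 / n_eff) * (Py @ Py - tr_P)
            sg_em = max(sg_em, floor)
            se_em = max(se_em, floor)
            new = (sg_em, se_em, _reml_loglik(lam, yt, Xt, sg_em, se_em))
        sg, se, ll = new
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    # observed-information SE of (sg, se) from the AI matrix at optimum
    d = sg * lam + se
    Xtd = Xt / d[:, None]
    XtVX_inv = np.linalg.inv(Xt.T @ Xtd)
    beta = XtVX_inv @ (Xtd.T @ yt)
    Py = (yt - Xt @ beta) / d

    def Pv(v: np.ndarray) -> np.ndarray:
        vd = v / d
        return vd - Xtd @ (XtVX_inv @ (Xt.T @ vd))

    PGPy = Pv(lam * Py)
    PPy = Pv(Py)
    AI = 0.5 * np.array(
        [
            [(lam * Py) @ PGPy, (lam * Py) @ PPy],
            [(lam * Py) @ PPy, Py @ PPy],
        ]
    )
    try:
        cov_s = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_s = np.full((2, 2), np.nan)
    tot = sg + se
    h2_obs = sg / tot
    # delta method: grad of sg/(sg+se) wrt (sg, se)
    grad = np.array([se, -sg]) / tot**2
    se_obs = float(np.sqrt(max(grad @ cov_s @ grad, 0.0)))
    scale = liability_scale_transform(1.0, K, P)
    h2_liab = h2_obs * scale
    se_liab = se_obs * scale
    ci_obs = (h2_obs - 1.96 * se_obs, h2_obs + 1.96 * se_obs)
    return RemlFit(
        h2_obs=float(h2_obs),
        se_obs=se_obs,
        h2_liab=float(h2_liab),
        se_liab=float(se_liab),
        ci_obs=ci_obs,
        ci_liab=(ci_obs[0] * scale, ci_obs[1] * scale),
        sigma_g=float(sg),
        sigma_e=float(se),
        K=K,
        P=float(P),
        loglik=float(trace[-1]),
        loglik_trace=tuple(float(v) for v in trace),
        n_iter=it,
        converged=converged,
    )


def matched_subsample(
    cohort: Cohort,
    ratio: int = 4,
    match_on: tuple[str, ...] = ("age", "pc1", "pc2", "pc3", "pc4", "pc5"),
    seed: int | None = None,
) -> Cohort:
    """Select ``ratio`` controls per case by stratified nearest matching.

    Within each sex stratum, controls are chosen greedily for each case
    (random case order) as the nearest unused neighbours in standardized
    (age, PC...) space.  When a sex stratum runs out of controls a global
    pool is used, with a warning.
    """
    rng = np.random.default_rng(seed)
    feats = [f for f in match_on if f in cohort.samples.columns]
    if not feats:
        raise ValueError("no matching features present in cohort.samples")
    F = cohort.samples[feats].to_numpy(dtype=float)
    F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) > 0, F.std(axis=0), 1.0)
    status = cohort.status
    sex = cohort.samples["sex"].to_numpy()
    keep = list(np.flatnonzero(status == 1))
    used = np.zeros(cohort.n_samples, dtype=bool)
    used[status == 1] = True
    import warnings

    for s in np.unique(sex):
        cases = np.flatnonzero((status == 1) & (sex == s))
        pool = np.flatnonzero((status == 0) & (sex == s))
        rng.shuffle(cases)
        for ci in cases:
            avail = pool[~used[pool]]
            if avail.size < ratio:
                warnings.warn(
                    f"sex stratum {s} exhausted; falling back to global pool",
                    stacklevel=2,
                )
                avail = np.flatnonzero((status == 0) & ~used)
            if avail.size == 0:
                break
            dist = np.linalg.norm(F[avail] - F[ci], axis=1)
            take = avail[np.argsort(dist, kind="stable")[:ratio]]
            used[take] = True
            keep.extend(take.tolist())
    keep = sorted(keep)
    return Cohort(
        samples=cohort.samples.iloc[keep].reset_index(drop=True),
        genotypes=cohort.genotypes[keep],
        snps=cohort.snps.copy(),
        spec=cohort.spec,
    )


def write_grm(grm: GRM, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize as gzipped lower-triangle TSV plus an id file.

    Layout: ``<prefix>.grm.gz`` rows ``i j m_snps A_ij`` (1-based, j<=i);
    ``<prefix>.grm.id`` one sample id per line.
    """
    prefix = Path(prefix)
    grm_path = prefix.with_suffix(".grm.gz")
    id_path = prefix.with_suffix(".grm.id")
    with gzip.open(grm_path, "wt") as fh:
        for i in range(len(grm.sample_ids)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t{grm.values[i, j]:.10g}\n")
    with open(id_path, "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")
    return grm_path, id_path


def read_grm(prefix: str | Path) -> GRM:
    """Read the :func:`write_grm` layout."""
    prefix = Path(prefix)
    ids = [line.split()[0] for line in open(prefix.with_suffix(".grm.id"))]
    n = len(ids)
    A = np.zeros((n, n))
    m = 0
    with gzip.open(prefix.with_suffix(".grm.gz"), "rt") as fh:
        for line in fh:
            i, j, m_s, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            A[i, j] = A[j, i] = float(v)
            m = int(m_s)
    return GRM(values=A, sample_ids=tuple(ids), m_snps=m)
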
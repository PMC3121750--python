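"""Elastic-net sparse logistic risk models with false-positive calibration.

The fitting problem is the penalized negative log-likelihood

``min_{b0, b}  sum_i [log(1 + e^{eta_i}) - y_i eta_i] + lambda1 ||b||_1
+ lambda2 ||b||_2^2``,    ``eta = b0 + X b``,

solved by cyclic coordinate descent on iteratively reweighted quadratic
approximations (the glmnet strategy) with an active-set outer loop and a
KKT certificate on exit.  The L1 weight is chosen to control the expected
number of truly null SNPs entering the model: under the null, SNP j
enters only when its score statistic ``|U_j| = |sum_i x_ij (y_i - ybar)|``
exceeds ``lambda1``, so ``sum_j 2 Phi(-lambda1 / sigma_j) = target``
bounds E[false positives], with ``sigma_j^2 = ybar (1 - ybar) sum_i
x_ij^2``.

Models carry a per-SNP missing-data weight ``w_miss = beta * 2 *
(training effect-allele frequency)``: the score contribution used when a
genotype is missing at prediction time (mean-dosage imputation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import MISSING, Cohort

__all__ = [
    "SparseModel",
    "FoldPlan",
    "fit_sparse_logistic",
    "lambda1_for_efp",
    "fit_model_series",
    "bias_corrected_refit",
    "profile_score_from_or_table",
    "predict_scores",
    "matched_cv_folds",
    "count_regions",
]

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class SparseModel:
    """A fitted (or table-derived) per-SNP additive log-odds model.

    ``entries`` columns: snp, effect_allele, beta (log-odds per allele
    copy), w_miss (score contribution when the genotype is missing).
    Only non-zero betas are stored.
    """

    intercept: float
    entries: pd.DataFrame
    lambda1: float = 0.0
    lambda2: float = 0.0
    efp_bound: float | None = None
    bias_corrected: bool = False
    objective: float | None = None
    kkt_residual: float | None = None

    def __post_init__(self) -> None:
        required = {"snp", "effect_allele", "beta", "w_miss"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"entries must have columns {sorted(required)}")
        if len(self.entries):
            if (self.entries["beta"].astype(float) == 0).any():
                raise ValueError("stored entries must all have non-zero beta")
            if not np.isfinite(self.entries["w_miss"].astype(float)).all():
                raise ValueError("w_miss must be finite")

    @property
    def size(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize; header comments carry the scalar metadata."""
        with open(path, "w") as fh:
            fh.write(f"# intercept={self.intercept!r}\n")
            fh.write(f"# lambda1={self.lambda1!r}\n")
            fh.write(f"# lambda2={self.lambda2!r}\n")
            fh.write(f"# efp_bound={self.efp_bound!r}\n")
            fh.write(f"# bias_corrected={int(self.bias_corrected)}\n")
            self.entries[["snp", "effect_allele", "beta", "w_miss"]].to_csv(
                fh, sep="\t", index=False, float_format="%.17g"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SparseModel":
        meta = {}
        lines = []
        for line in open(path):
            if line.startswith("# "):
                k, v = line[2:].strip().split("=", 1)
                meta[k] = v
            else:
                lines.append(line)
        entries = pd.read_csv(
            io.StringIO("".join(lines)), sep="\t", float_precision="round_trip"
        )
        none_or = lambda v: None if v == "None" else float(v)
        return cls(
            intercept=float(meta["intercept"]),
            entries=entries,
            lambda1=float(meta["lambda1"]),
            lambda2=float(meta["lambda2"]),
            efp_bound=none_or(meta["efp_bound"]),
            bias_corrected=bool(int(meta["bias_corrected"])),
        )


@dataclass(frozen=True)
class FoldPlan:
    """Per-sample cross-validation fold labels with their strata."""

    fold: np.ndarray
    stratum: np.ndarray
    n_folds: int


def _mean_impute(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN/MISSING dosages by the per-SNP mean; return (X, means)."""
    X = np.asarray(X, dtype=float)
    X = np.where(X == MISSING, np.nan, X)
    means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    means = np.nan_to_num(means)
    idx = np.where(np.isnan(X))
    if idx[0].size:
        X = X.copy()
        X[idx] = means[idx[1]]
    return X, means


def _cd_solve(
    X: np.ndarray,
    y: np.ndarray,
    lambda1: float,
    lambda2: float,
    beta0: float,
    beta: np.ndarray,
    max_outer: int = 200,
    tol: float = 1e-10,
    kkt_target: float = 0.0,
) -> tuple[float, np.ndarray, float, float]:
    """Coordinate descent on IRLS quadratic approximations.

    Returns (intercept, beta, objective, kkt_residual).  Each outer
    iteration re-linearizes the likelihood at the current point and runs
    cyclic CD (active set, periodic full passes) on the weighted
    quadratic; the loop exits when the KKT residual of the *true*
    penalized logistic objective falls below ``kkt_target``.
    """
    n, m = X.shape

    def objective(b0: float, b: np.ndarray) -> float:
        e = b0 + X @ b
        nll = float(np.sum(np.logaddexp(0.0, e)) - y @ e)
        return nll + lambda1 * np.abs(b).sum() + lambda2 * float(b @ b)

    def kkt_residual(b0: float, b: np.ndarray) -> float:
        e = b0 + X @ b
        mu = 1.0 / (1.0 + np.exp(-e))
        grad = X.T @ (mu - y) + 2.0 * lambda2 * b
        nz = b != 0.0
        res_active = np.abs(grad + lambda1 * np.sign(b))[nz]
        res_zero = np.clip(np.abs(grad[~nz]) - lambda1, 0.0, None)
        return max(
            res_active.max() if res_active.size else 0.0,
            res_zero.max() if res_zero.size else 0.0,
            abs(float(np.sum(mu - y))),
        )

    eta = beta0 + X @ beta
    active = np.flatnonzero(beta != 0.0)
    kkt = np.inf
    for _ in range(max_outer):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-9, None)
        z = eta + (y - mu) / w
        wsum = w.sum()
        for sweep in range(1000):
            max_delta = 0.0
            new0 = beta0 + (w @ (z - eta)) / wsum
            d0 = new0 - beta0
            if d0 != 0.0:
                eta = eta + d0
                beta0 = new0
                max_delta = abs(d0)
            scan = np.arange(m) if sweep % 10 == 0 or active.size == 0 else active
            for j in scan:
                xj = X[:, j]
                wx = w * xj
                wxx = wx @ xj
                num = wx @ (z - eta) + wxx * beta[j]
                den = wxx + 2.0 * lambda2
                bj = np.sign(num) * max(abs(num) - lambda1, 0.0) / den
                d = bj - beta[j]
                if d != 0.0:
                    eta = eta + xj * d
                    beta[j] = bj
                    max_delta = max(max_delta, abs(d))
            active = np.flatnonzero(beta != 0.0)
            if max_delta < tol and sweep % 10 != 0:
                break
        eta = beta0 + X @ beta  # resync against incremental drift
        kkt = kkt_residual(beta0, beta)
        if kkt <= kkt_target:
            break
    return beta0, beta, objective(beta0, beta), float(kkt)


def fit_sparse_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lambda1: float,
    lambda2: float,
    snp_ids=None,
    effect_alleles=None,
    warm: tuple[float, np.ndarray] | None = None,
    efp_bound: float | None = None,
    kkt_tol: float = 1e-6,
) -> SparseModel:
    """Fit the elastic-net logistic model on a dosage matrix.

    Missing dosages (NaN or ``MISSING``) are mean-imputed for fitting;
    the per-SNP training means also define ``w_miss = beta * mean``.
    Raises if the exit KKT residual exceeds ``kkt_tol`` scaled by n.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty weights must be non-negative")
    X, means = _mean_impute(X)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if warm is None:
        ybar = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        beta0, beta = float(np.log(ybar / (1 - ybar))), np.zeros(m)
    else:
        beta0, beta = float(warm[0]), warm[1].copy()
    beta0, beta, obj, kkt = _cd_solve(
        X, y, lambda1, lambda2, beta0, beta, kkt_target=kkt_tol * max(1.0, 0.01 * n)
    )
    if kkt > kkt_tol * max(1.0, n):
        raise RuntimeError(
            f"coordinate descent did not reach KKT tolerance: residual {kkt:.3g}"
        )
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    if effect_alleles is None:
        effect_alleles = ["."] * m
    nz = np.flatnonzero(beta)
    entries = pd.DataFrame(
        {
            "snp": np.asarray(snp_ids)[nz],
            "effect_allele": np.asarray(effect_alleles)[nz],
            "beta": beta[nz],
            "w_miss": beta[nz] * means[nz],
        }
    )
    return SparseModel(
        intercept=float(beta0),
        entries=entries,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        efp_bound=efp_bound,
        objective=obj,
        kkt_residual=kkt,
    )


def lambda1_for_efp(X: np.ndarray, y: np.ndarray, target_efp: float) -> float:
    """L1 weight bounding the expected number of null SNPs selected.

    Solves ``sum_j 2 Phi(-lambda1 / sigma_j) = target_efp`` by monotone
    bisection, ``sigma_j^2 = ybar(1 - ybar) sum_i x_ij^2``.  A target at
    or above the SNP count returns 0 (no selection control) with a
    warning.
    """
    if target_efp <= 0:
        raise ValueError("target_efp must be positive")
    X, _ = _mean_impute(X)
    y = np.asarray(y, dtype=float)
    m = X.shape[1]
    if target_efp >= m:
        import warnings

        warnings.warn(
            f"target E[FP]={target_efp} >= m={m}: lambda1=0", stacklevel=2
        )
        return 0.0
    ybar = y.mean()
    sigma = np.sqrt(ybar * (1.0 - ybar) * (X**2).sum(axis=0))
    sigma = np.clip(sigma, 1e-300, None)

    def efp(lam: float) -> float:
        return float(2.0 * norm.sf(lam / sigma).sum())

    lo, hi = 0.0, float(10.0 * sigma.max())
    while efp(hi) > target_efp:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if efp(mid) > target_efp:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_lambda2(n: int) -> float:
    """Small ridge weight ensuring uniqueness, scaled to the sample size."""
    return 1e-3 * n


def fit_model_series(
    cohort: Cohort,
    efp_grid: tuple[float, ...] = (0.05, 0.5, 5.0, 50.0, 500.0),
    lambda2: float | None = None,
    sample_mask: np.ndarray | None = None,
) -> list[SparseModel]:
    """One model per E[FP] bound, warm-started along the increasing grid."""
    if list(efp_grid) != sorted(efp_grid):
        raise ValueError("efp_grid must be increasing")
    X = cohort.dosage_float()
    y = cohort.status.astype(float)
    if sample_mask is not None:
        X, y = X[sample_mask], y[sample_mask]
    if lambda2 is None:
        lambda2 = default_lambda2(len(y))
    Xi, _ = _mean_impute(X)
    snp_ids = cohort.snps["snp_id"].to_numpy()
    alleles = cohort.snps["allele_minor"].to_numpy()
    models = []
    warm = None
    for bound in efp_grid:
        lam1 = lambda1_for_efp(Xi, y, bound)
        model = fit_sparse_logistic(
            Xi,
            y,
            lam1,
            lambda2,
            snp_ids=snp_ids,
            effect_alleles=alleles,
            warm=warm,
            efp_bound=bound,
        )
        # rebuild dense beta for the next warm start
        dense = np.zeros(cohort.n_snps)
        pos = {s: j for j, s in enumerate(snp_ids)}
        for s, b in zip(model.entries["snp"], model.entries["beta"]):
            dense[pos[s]] = b
        warm = (model.intercept, dense)
        models.append(model)
    return models


def bias_corrected_refit(
    model: SparseModel,
    X: np.ndarray,
    y: np.ndarray,
    snp_ids=None,
    lambda2: float | None = None,
) -> SparseModel:
    """Refit the selected support without the sparsity penalty.

    L1 shrinks retained effects toward zero; dropping it (keeping only
    the small ridge term for stability) on the fixed support de-biases
    the effect sizes.  The support is unchanged by construction.
    ``snp_ids`` names the columns of ``X`` (defaults to the ``snp{j}``
    naming used by :func:`fit_sparse_logistic`).
    """
    y = np.asarray(y, dtype=float)
    if lambda2 is None:
        lambda2 = model.lambda2
    if model.size == 0:
        ybar = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        return replace(
            model,
            intercept=float(np.log(ybar / (1 - ybar))),
            lambda1=0.0,
            bias_corrected=True,
        )
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(X.shape[1])]
    pos = {s: j for j, s in enumerate(snp_ids)}
    cols = [pos[s] for s in model.entries["snp"]]
    Xi, _ = _mean_impute(np.asarray(X, dtype=float)[:, cols])
    sub = fit_sparse_logistic(
        Xi,
        y,
        0.0,
        lambda2,
        snp_ids=model.entries["snp"].to_numpy(),
        effect_alleles=model.entries["effect_allele"].to_numpy(),
        efp_bound=model.efp_bound,
    )
    return replace(sub, lambda1=0.0, bias_corrected=True)


def profile_score_from_or_table(
    table: pd.DataFrame, freqs: pd.Series | dict | None = None
) -> SparseModel:
    """Log-OR profile score from a published association table.

    ``table`` columns: snp, risk_allele (or effect_allele), OR.  The score
    of a sample is the sum of ``log(OR) * dosage`` — the log of the
    product of per-allele odds ratios.  ``freqs`` maps snp -> effect
    allele frequency and defines the missing-data weight
    ``w_miss = log(OR) * 2 * freq``; required for every SNP.
    """
    tab = table.rename(columns={"risk_allele": "effect_allele", "or": "OR"})
    if (tab["OR"] <= 0).any():
        raise ValueError("odds ratios must be positive")
    beta = np.log(tab["OR"].to_numpy(dtype=float))
    if freqs is None:
        freqs = {}
    w_miss = []
    for snp, b in zip(tab["snp"], beta):
        if b == 0.0:
            continue
        if snp not in freqs:
            raise KeyError(f"no effect-allele frequency supplied for {snp}")
        w_miss.append(b * 2.0 * float(freqs[snp]))
    nz = beta != 0.0
    entries = pd.DataFrame(
        {
            "snp": tab["snp"].to_numpy()[nz],
            "effect_allele": tab["effect_allele"].to_numpy()[nz],
            "beta": beta[nz],
            "w_miss": w_miss,
        }
    )
    return SparseModel(intercept=0.0, entries=entries)


def predict_scores(
    model: SparseModel,
    cohort: Cohort,
    on_unresolvable: str = "error",
    strand: str = "forward",
) -> np.ndarray:
    """Per-sample risk score ``intercept + sum(beta * dosage | w_miss)``.

    Model SNPs are matched to cohort SNPs by id; the effect allele must be
    one of the two cohort alleles (dosage is flipped to ``2 - g`` when the
    effect allele is the major one).  With ``strand="forward"`` both
    datasets are trusted to report forward-strand alleles (the generator's
    convention); ``strand="strict"`` additionally rejects strand-ambiguous
    A/T and C/G SNPs, as appropriate when merging externally sourced
    tables.  Unresolvable SNPs follow ``on_unresolvable``: "error" or
    "skip" (with warning).
    """
    if strand not in ("forward", "strict"):
        raise ValueError("strand must be 'forward' or 'strict'")
    import warnings

    snps = cohort.snps.set_index("snp_id")
    g = cohort.dosage_float()
    scores = np.full(cohort.n_samples, model.intercept, dtype=float)
    for _, row in model.entries.iterrows():
        snp, ea, beta, w_miss = (
            row["snp"], row["effect_allele"], row["beta"], row["w_miss"],
        )

        def unresolved(msg: str) -> bool:
            if on_unresolvable == "skip":
                warnings.warn(msg, stacklevel=2)
                return True
            raise KeyError(msg)

        if snp not in snps.index:
            if unresolved(f"model SNP {snp} absent from cohort"):
                continue
        minor = snps.loc[snp, "allele_minor"]
        major = snps.loc[snp, "allele_major"]
        if ea == ".":
            dosage = g[:, snps.index.get_loc(snp)]
        elif ea not in (minor, major):
            if unresolved(f"effect allele {ea} not among {snp} alleles {major}/{minor}"):
                continue
        elif strand == "strict" and frozenset({str(minor), str(major)}) in _AMBIGUOUS:
            if unresolved(f"strand-ambiguous alleles for {snp} ({major}/{minor})"):
                continue
        elif ea == minor:
            dosage = g[:, snps.index.get_loc(snp)]
        else:
            dosage = 2.0 - g[:, snps.index.get_loc(snp)]
        contrib = np.where(np.isnan(dosage), w_miss, beta * np.nan_to_num(dosage))
        scores += contrib
    return scores


def matched_cv_folds(
    cohort: Cohort, n_folds: int = 5, n_age_bins: int = 10, seed: int | None = None
) -> FoldPlan:
    """Stratified fold assignment: sex x age-decile strata, balanced folds.

    Within each stratum, cases and controls are separately shuffled and
    dealt round-robin, so every stratum contributes near-equal counts to
    each fold and the case:control ratio is approximately constant across
    folds.  Strata with fewer members than folds are merged with the
    neighbouring age decile.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    age = cohort.samples["age"].to_numpy(dtype=float)
    sex = cohort.samples["sex"].to_numpy()
    status = cohort.status
    # age deciles on the pooled sample
    qs = np.quantile(age, np.linspace(0, 1, n_age_bins + 1)[1:-1])
    decile = np.searchsorted(qs, age, side="right")
    stratum = np.array([f"sex{s}_age{d}" for s, d in zip(sex, decile)])
    # merge tiny strata into the neighbouring decile
    for s in np.unique(sex):
        for d in range(n_age_bins):
            mask = (sex == s) & (decile == d)
            if 0 < mask.sum() < n_folds:
                nbr = d - 1 if d > 0 else d + 1
                decile[mask] = nbr
    stratum = np.array([f"sex{s}_age{d}" for s, d in zip(sex, decile)])
    fold = np.zeros(cohort.n_samples, dtype=int)
    start = 0
    for st in np.unique(stratum):
        for cls in (0, 1):
            idx = np.flatnonzero((stratum == st) & (status == cls))
            idx = idx[rng.permutation(idx.size)]
            fold[idx] = (np.arange(idx.size) + start) % n_folds + 1
            start += idx.size
    return FoldPlan(fold=fold, stratum=stratum, n_folds=n_folds)


def count_regions(
    model: SparseModel, snps: pd.DataFrame, window_kb: float = 250.0
) -> int:
    """Distinct genomic regions among model SNPs (single-linkage clusters).

    SNPs on the same chromosome within ``window_kb`` of each other chain
    into one region.
    """
    if model.size == 0:
        return 0
    meta = snps.set_index("snp_id")
    window = window_kb * 1000.0
    n_regions = 0
    sel = meta.loc[model.entries["snp"]]
    for _, grp in sel.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=float))
        n_regions += 1 + int((np.diff(pos) > window).sum())
    return n_regions
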
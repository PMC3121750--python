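"""SNP QC and per-SNP logistic likelihood-ratio association scans.

Per-SNP association uses a logistic regression of case status on the
minor-allele count (log-additive coding) plus covariates, tested with the
likelihood-ratio test against the covariate-only null (1 df).  SNPs are
filtered beforehand on call rate, minor-allele frequency and a
Hardy-Weinberg exact test; ancestry is summarized by classical
multidimensional scaling of the allele-sharing distance matrix; and the
genomic-control inflation factor summarizes residual test-statistic
inflation.  Quasi-complete separation (rare alleles with empty cells) is
handled by a Firth-type penalized fallback, flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .cohort import MISSING, Cohort

__all__ = [
    "QCConfig",
    "AssocResult",
    "hwe_exact_p",
    "qc_filter",
    "logistic_lrt_scan",
    "genomic_control_lambda",
    "mds_components",
    "heterogeneity_test",
    "power_trend",
]

ASSOC_COLUMNS = [
    "snp", "chr", "pos", "allele_major", "allele_minor", "maf", "call_rate",
    "hwe_p", "or", "ci_low", "ci_high", "p_lrt", "n_used",
]


@dataclass(frozen=True)
class QCConfig:
    """Per-SNP exclusion thresholds and scan covariates.

    The default MAF floor is deliberately low: panels can carry rare
    custom variants of large effect that a conventional 1% floor would
    discard.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.001
    hwe_alpha: float = 1e-6
    covariates: tuple[str, ...] = ("sex", "age")

    def __post_init__(self) -> None:
        for v in (self.min_call_rate, self.min_maf, self.hwe_alpha):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"QC thresholds must be in [0, 1], got {v}")


@dataclass(frozen=True)
class AssocResult:
    """One SNP's association summary (OR per minor allele, LRT p)."""

    snp: str
    maf: float
    call_rate: float
    hwe_p: float
    beta: float
    se: float
    or_ci: tuple[float, float]
    p_lrt: float
    n_used: int
    firth: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, by probability mass).

    Conditional on the allele counts, the number of heterozygotes follows
    the exact HWE distribution; the p-value sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    Monomorphic genotypes return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # probabilities over heterozygote counts of the same parity, by the
    # standard two-directional recurrence from the mode
    het_obs = n_Aa
    probs = np.zeros(n_rare + 1)
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)(c-h+2)) with
    # r = n_rare, c = 2n - n_rare homozygote allele pools
    r_al = n_rare
    c_al = 2 * n - n_rare
    h = mid
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            (r_al - h + 2.0) * (c_al - h + 2.0)
        )
        h -= 2
    h = mid
    while h + 2 <= n_rare:
        probs[h + 2] = probs[h] * (r_al - h) * (c_al - h) / (
            (h + 2.0) * (h + 1.0)
        )
        h += 2
    probs /= probs.sum()
    p_obs = probs[het_obs]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(g_col: np.ndarray) -> tuple[int, int, int, int]:
    valid = g_col != MISSING
    gv = g_col[valid]
    return (
        int((gv == 0).sum()),
        int((gv == 1).sum()),
        int((gv == 2).sum()),
        int(valid.sum()),
    )


def qc_filter(cohort: Cohort, qc: QCConfig) -> tuple[Cohort, pd.DataFrame]:
    """Apply SNP QC; return the filtered cohort and a per-SNP report.

    The report lists call rate, MAF, HWE exact p (computed in controls
    when both classes are present, else in all samples), and the failed
    rules per SNP.  Filtering is idempotent.
    """
    g = cohort.genotypes
    status = cohort.status
    ctrl = status == 0
    use_ctrl = ctrl.any() and (status == 1).any()
    rows = []
    for j in range(cohort.n_snps):
        col = g[:, j]
        n0, n1, n2, n_called = _genotype_counts(col)
        call_rate = n_called / len(col)
        maf = (n1 + 2 * n2) / (2 * n_called) if n_called else 0.0
        maf = min(maf, 1.0 - maf)
        hc = col[ctrl] if use_ctrl else col
        c0, c1, c2, _ = _genotype_counts(hc)
        hwe = hwe_exact_p(c0, c1, c2)
        fails = []
        if call_rate < qc.min_call_rate:
            fails.append("call_rate")
        if maf < qc.min_maf:
            fails.append("maf")
        if hwe < qc.hwe_alpha:
            fails.append("hwe")
        rows.append(
            {
                "snp_id": cohort.snps["snp_id"].iloc[j],
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe,
                "fails": ",".join(fails),
                "pass": not fails,
            }
        )
    report = pd.DataFrame(rows)
    keep = report["pass"].to_numpy()
    filtered = Cohort(
        samples=cohort.samples.copy(),
        genotypes=cohort.genotypes[:, keep],
        snps=cohort.snps.loc[keep].reset_index(drop=True),
        spec=cohort.spec,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# logistic regression machinery


def _logistic_nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson logistic fit.

    Returns (beta, covariance, loglik, converged); convergence is gradient
    max-norm below ``tol`` scaled by n.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[0] = np.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol * n:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (separation drift)
        norm_step = np.max(np.abs(step))
        if norm_step > 10.0:
            step *= 10.0 / norm_step
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    ll = -_logistic_nll(beta, X, y)
    return beta, cov, ll, converged


def fit_logistic_firth(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """Firth-penalized logistic fit (Jeffreys prior).

    Maximizes ``loglik + 0.5 log det I(beta)``; finite estimates exist
    under separation.  Returns (beta, covariance, penalized loglik).
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        Xw = X * w[:, None]
        H = Xw.T @ X
        Hinv = np.linalg.pinv(H)
        # hat diagonal of the weighted design
        hat = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], Hinv, X * np.sqrt(w)[:, None])
        grad = X.T @ (y - mu + hat * (0.5 - mu))
        step = Hinv @ grad
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(H)
    ll_pen = -_logistic_nll(beta, X, y) + 0.5 * logdet
    return beta, np.linalg.pinv(H), ll_pen


def _covariate_matrix(cohort: Cohort, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(cohort.n_samples)]
    for name in covariates:
        if name not in cohort.samples.columns:
            raise KeyError(f"covariate {name!r} not in cohort samples")
        col = cohort.samples[name]
        if col.dtype == object:
            col = pd.factorize(col)[0]
        cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols)


def logistic_lrt_scan(
    cohort: Cohort,
    covariates: tuple[str, ...] = (),
    qc_report: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP logistic likelihood-ratio scan, complete cases per SNP.

    Returns a DataFrame in the fixed ``ASSOC_COLUMNS`` order (odds ratio
    per minor allele, Wald 95% CI from observed information, LRT p on
    1 df) plus ``beta``, ``se`` and ``firth`` columns.
    """
    X_full = _covariate_matrix(cohort, tuple(covariates))
    y_full = cohort.status.astype(float)
    g = cohort.genotypes
    null_cache: dict[bytes, float] = {}
    rows = []
    z = norm.isf(0.025)
    for j in range(cohort.n_snps):
        col = g[:, j].astype(float)
        ok = g[:, j] != MISSING
        n_used = int(ok.sum())
        n0, n1, n2, n_called = _genotype_counts(g[:, j])
        maf = (n1 + 2 * n2) / (2 * n_called) if n_called else 0.0
        maf = min(maf, 1.0 - maf)
        X0 = X_full[ok]
        y = y_full[ok]
        key = ok.tobytes()
        if key not in null_cache:
            _, _, ll0, _ = fit_logistic(X0, y)
            null_cache[key] = ll0
        ll0 = null_cache[key]
        X1 = np.column_stack([X0, col[ok]])
        beta, cov, ll1, conv = fit_logistic(X1, y)
        firth = False
        if not conv or np.abs(beta[-1]) > 15.0:
            firth = True
            beta, cov, _ = fit_logistic_firth(X1, y)
            _, _, ll0p = fit_logistic_firth(X0, y)
            # LRT on the penalized likelihoods of the converged fits
            eta = X1 @ beta
            ll1 = -(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
            ll0 = null_cache[key]
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        p = float(chi2.sf(lrt, df=1))
        b = float(beta[-1])
        se = float(np.sqrt(max(cov[-1, -1], 0.0)))
        snp = cohort.snps.iloc[j]
        rows.append(
            {
                "snp": snp["snp_id"],
                "chr": snp.get("chrom", "."),
                "pos": snp.get("pos", 0),
                "allele_major": snp.get("allele_major", "."),
                "allele_minor": snp.get("allele_minor", "."),
                "maf": maf,
                "call_rate": n_used / cohort.n_samples,
                "hwe_p": np.nan,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "p_lrt": max(p, 5e-324),
                "n_used": n_used,
                "beta": b,
                "se": se,
                "firth": firth,
            }
        )
    out = pd.DataFrame(rows)
    if qc_report is not None:
        hwe = qc_report.set_index("snp_id")["hwe_p"]
        out["hwe_p"] = out["snp"].map(hwe).to_numpy()
    return out[ASSOC_COLUMNS + ["beta", "se", "firth"]]


def genomic_control_lambda(pvals: np.ndarray) -> float:
    """Genomic-control inflation factor from a vector of 1-df p-values.

    Median of the implied chi-square statistics divided by the null
    median of chi-square(1), 0.4549.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("need at least one p-value")
    stats = chi2.isf(np.clip(pvals, 1e-300, 1.0), df=1)
    return float(np.median(stats) / chi2.isf(0.5, df=1))


def mds_components(genotypes: np.ndarray, k: int = 5) -> np.ndarray:
    """Classical MDS coordinates from the allele-sharing distance.

    The distance between two samples is one minus the mean per-SNP shared
    allele fraction (1, 0.5, 0 for identical homozygotes / one shared
    allele / opposite homozygotes), i.e. ``mean(|g_u - g_v|) / 2`` over
    SNPs called in both.  Coordinates come from the eigendecomposition of
    the double-centered squared-distance matrix, ordered by eigenvalue.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = genotypes.astype(float)
    g[genotypes == MISSING] = np.nan
    n = g.shape[0]
    obs = ~np.isnan(g)
    gz = np.nan_to_num(g)
    # sum over shared-called SNPs of |g_u - g_v| via indicator expansion
    abs_diff = np.zeros((n, n))
    ind = [(gz == v) & obs for v in (0.0, 1.0, 2.0)]
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            abs_diff += abs(a - b) * (ind[a].astype(float) @ ind[b].astype(float).T)
    n_shared = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(n_shared > 0, abs_diff / n_shared / 2.0, 0.0)
    np.fill_diagonal(D, 0.0)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-10).sum())
    if k > n_pos:
        import warnings

        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating MDS to {n_pos}",
            stacklevel=2,
        )
        k = max(n_pos, 1)
    return vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))


def attach_pcs(cohort: Cohort, k: int = 5) -> Cohort:
    """Attach MDS ancestry coordinates as ``pc1..pck`` sample columns."""
    coords = mds_components(cohort.genotypes, k)
    out = cohort.copy()
    for j in range(coords.shape[1]):
        out.samples[f"pc{j + 1}"] = coords[:, j]
    return out


def heterogeneity_test(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """Two-sided normal test of effect-size difference between two groups."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    zstat = (beta1 - beta2) / np.sqrt(se1**2 + se2**2)
    return float(2.0 * norm.sf(abs(zstat)))


def power_trend(
    or_published: float,
    maf: float,
    n_case: int,
    n_control: int,
    alpha: float = 5e-8,
) -> float:
    """Power of the two-sided 1-df trend test under a log-additive model.

    Control genotype frequencies are HWE at ``maf``; case frequencies are
    the control frequencies tilted by ``OR^g`` and renormalized.  The
    non-centrality of the score (trend) statistic follows from the
    difference in mean genotype between cases and controls over the
    pooled variance.
    """
    if or_published <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    p0 = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    g = np.array([0.0, 1.0, 2.0])
    w = p0 * or_published**g
    p1 = w / w.sum()
    mu0, mu1 = p0 @ g, p1 @ g
    var0 = p0 @ g**2 - mu0**2
    var1 = p1 @ g**2 - mu1**2
    # pooled null variance at the mixture frequency
    frac_case = n_case / (n_case + n_control)
    p_mix = frac_case * p1 + (1 - frac_case) * p0
    var_mix = p_mix @ g**2 - (p_mix @ g) ** 2
    se_null = np.sqrt(var_mix * (1.0 / n_case + 1.0 / n_control))
    se_alt = np.sqrt(var1 / n_case + var0 / n_control)
    z_crit = norm.isf(alpha / 2.0)
    delta = mu1 - mu0
    # reject when |Z| > z_crit with Z ~ N(delta/se_null, (se_alt/se_null)^2)
    upper = norm.sf((z_crit * se_null - delta) / se_alt)
    lower = norm.cdf((-z_crit * se_null - delta) / se_alt)
    return float(upper + lower)
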
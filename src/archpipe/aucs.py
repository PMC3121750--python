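"""Plain and covariate-adjusted AUC, difference tests, predicted AUC.

The covariate-adjusted AUC is the probability that a random case
outscores a random control *drawn from the same covariate stratum*: a
stratified Mann-Whitney statistic with strata weighted by their
case-control pair counts.  It removes apparent discrimination that is
attributable to covariates (sex, age, ancestry, platform, CV fold)
rather than to the score itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .sparse import SparseModel

__all__ = [
    "AUCResult",
    "plain_auc",
    "covariate_adjusted_auc",
    "auc_difference_test",
    "predicted_auc",
    "default_strata",
]


@dataclass(frozen=True)
class AUCResult:
    """Pair-weighted stratified AUC with per-stratum bookkeeping.

    ``auc`` equals ``sum_s w_s auc_s`` with ``w_s`` proportional to
    ``n_case_s * n_control_s``; the statistic is exactly the probability
    that a random case outscores a random matched control (ties 1/2).
    """

    auc: float
    n_strata_used: int
    n_strata_skipped: int
    n_pairs: float
    per_stratum: pd.DataFrame
    ci_low: float | None = None
    ci_high: float | None = None


def plain_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both cases and controls are required")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def covariate_adjusted_auc(
    scores: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    n_boot: int = 0,
    seed: int | None = None,
) -> AUCResult:
    """Stratified (covariate-adjusted) AUC.

    Strata lacking a case or a control contribute no case-control pairs
    and are excluded (counted in ``n_strata_skipped``).  With ``n_boot``
    > 0 a stratified bootstrap CI (resampling cases and controls
    independently within strata) is attached.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    strata = np.asarray(strata)
    rows = []
    skipped = 0
    for s in pd.unique(strata):
        mask = strata == s
        ys = y[mask]
        n1, n0 = int((ys == 1).sum()), int((ys == 0).sum())
        if n1 == 0 or n0 == 0:
            skipped += 1
            continue
        rows.append(
            {
                "stratum": s,
                "n_case": n1,
                "n_control": n0,
                "auc_s": plain_auc(scores[mask], ys),
                "w": n1 * n0,
            }
        )
    if not rows:
        raise ValueError("no stratum contains both a case and a control")
    per = pd.DataFrame(rows)
    w = per["w"].to_numpy(dtype=float)
    auc = float((per["auc_s"].to_numpy() * w).sum() / w.sum())
    ci = (None, None)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = _stratified_boot_auc(scores, y, strata, per["stratum"], rng, n_boot)
        ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return AUCResult(
        auc=auc,
        n_strata_used=len(per),
        n_strata_skipped=skipped,
        n_pairs=float(w.sum()),
        per_stratum=per.drop(columns="w"),
        ci_low=ci[0],
        ci_high=ci[1],
    )


def _stratified_boot_auc(scores, y, strata, used_strata, rng, n_boot):
    """Bootstrap distribution of the stratified AUC (vector of length n_boot)."""
    aucs = np.zeros(n_boot)
    weights = np.zeros(n_boot)
    num = np.zeros(n_boot)
    for s in used_strata:
        mask = strata == s
        sc_case = scores[mask & (y == 1)]
        sc_ctrl = scores[mask & (y == 0)]
        n1, n0 = sc_case.size, sc_ctrl.size
        for b in range(n_boot):
            cs = rng.choice(sc_case, n1, replace=True)
            ct = rng.choice(sc_ctrl, n0, replace=True)
            ranks = rankdata(np.concatenate([cs, ct]))
            u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
            num[b] += u
            weights[b] += n1 * n0
    return num / weights


def auc_difference_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sided paired test that score A has higher adjusted AUC than B.

    A paired stratified bootstrap resamples cases and controls within
    strata (the same resample evaluated under both scores) and reports
    ``p = (#{dAUC <= 0} + 1) / (B + 1)`` plus the observed AUC
    difference.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y)
    strata = np.asarray(strata)
    obs_a = covariate_adjusted_auc(scores_a, y, strata)
    obs_b = covariate_adjusted_auc(scores_b, y, strata)
    rng = np.random.default_rng(seed)
    diffs = np.zeros(n_boot)
    num_a = np.zeros(n_boot)
    num_b = np.zeros(n_boot)
    wsum = np.zeros(n_boot)
    for s in obs_a.per_stratum["stratum"]:
        mask = strata == s
        case_idx = np.flatnonzero(mask & (y == 1))
        ctrl_idx = np.flatnonzero(mask & (y == 0))
        n1, n0 = case_idx.size, ctrl_idx.size
        for b in range(n_boot):
            cs = rng.choice(case_idx, n1, replace=True)
            ct = rng.choice(ctrl_idx, n0, replace=True)
            for sc, acc in ((scores_a, num_a), (scores_b, num_b)):
                ranks = rankdata(np.concatenate([sc[cs], sc[ct]]))
                acc[b] += ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
            wsum[b] += n1 * n0
    diffs = (num_a - num_b) / wsum
    # ties at exactly zero (e.g. identical scores) count half, so equal
    # scores give p ~ 0.5 rather than 1
    below = float((diffs < 0.0).sum()) + 0.5 * float((diffs == 0.0).sum())
    p = (below + 1.0) / (n_boot + 1.0)
    return p, float(obs_a.auc - obs_b.auc)


def predicted_auc(model: SparseModel, freqs: pd.DataFrame) -> float:
    """Model-implied AUC from per-SNP genotype frequencies.

    ``freqs``: one row per model SNP (indexed or keyed by ``snp``) with
    columns ``case_p0, case_p1, case_p2, ctrl_p0, ctrl_p1, ctrl_p2`` —
    genotype frequencies of the *effect-allele* dosage in cases and
    controls.  Treating per-SNP contributions as independent, case and
    control score distributions are approximated as normals and

    ``AUC = Phi(dmean / sqrt(var_case + var_ctrl))``.
    """
    if model.size == 0:
        return 0.5
    if "snp" in freqs.columns:
        freqs = freqs.set_index("snp")
    missing = [s for s in model.entries["snp"] if s not in freqs.index]
    if missing:
        raise KeyError(f"no genotype frequencies for model SNPs: {missing}")
    g = np.array([0.0, 1.0, 2.0])
    d_mean = 0.0
    var_case = var_ctrl = 0.0
    for _, row in model.entries.iterrows():
        f = freqs.loc[row["snp"]]
        pc = np.array([f["case_p0"], f["case_p1"], f["case_p2"]], dtype=float)
        pt = np.array([f["ctrl_p0"], f["ctrl_p1"], f["ctrl_p2"]], dtype=float)
        b = row["beta"]
        mc, mt = pc @ g, pt @ g
        d_mean += b * (mc - mt)
        var_case += b * b * (pc @ g**2 - mc**2)
        var_ctrl += b * b * (pt @ g**2 - mt**2)
    denom = np.sqrt(var_case + var_ctrl)
    if denom == 0.0:
        return 0.5
    return float(norm.cdf(d_mean / denom))


def default_strata(
    samples: pd.DataFrame,
    n_age_bins: int = 10,
    pc_quantiles: int = 5,
    extra: tuple[str, ...] = (),
) -> np.ndarray:
    """Stratum labels: sex x age decile x PC1 quintile x extra columns.

    ``extra`` may name columns such as ``fold`` or ``platform`` when they
    should be adjusted for.  Missing columns are skipped silently except
    ``sex``/``age`` which are required.
    """
    parts = []
    sex = samples["sex"].astype(str)
    age = samples["age"].to_numpy(dtype=float)
    qs = np.quantile(age, np.linspace(0, 1, n_age_bins + 1)[1:-1])
    parts.append("s" + sex)
    parts.append(pd.Series(np.searchsorted(qs, age, side="right"), index=samples.index).astype(str))
    if "pc1" in samples.columns and pc_quantiles > 1:
        pc1 = samples["pc1"].to_numpy(dtype=float)
        qp = np.quantile(pc1, np.linspace(0, 1, pc_quantiles + 1)[1:-1])
        parts.append(pd.Series(np.searchsorted(qp, pc1, side="right"), index=samples.index).astype(str))
    for name in extra:
        if name in samples.columns:
            parts.append(samples[name].astype(str))
    out = parts[0]
    for p in parts[1:]:
        out = out + "_" + p
    return out.to_numpy()
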
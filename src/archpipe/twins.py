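"""Twin heritability from concordance counts.

Falconer-style estimation: probandwise concordance per zygosity is mapped
to a tetrachoric (latent liability) correlation by solving a bivariate
normal orthant equation, and heritability of liability is twice the
difference between the monozygotic and dizygotic correlations.  Confidence
intervals come from a multinomial bootstrap over the ascertainment-
stratified pair-category counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .liability import liability_params

__all__ = [
    "TwinCounts",
    "TwinH2Estimate",
    "probandwise_concordance",
    "bvn_upper_orthant",
    "tetrachoric_from_concordance",
    "twin_h2",
    "bootstrap_twin_h2",
]



@dataclass(frozen=True)
class TwinCounts:
    """Ascertainment-stratified concordance counts for one zygosity.

    ``n_double_concordant`` pairs were independently ascertained through
    both members, ``n_single_concordant`` through one member only, and
    ``n_discordant`` pairs have exactly one affected member.
    """

    zygosity: str
    n_double_concordant: int
    n_single_concordant: int
    n_discordant: int

    def __post_init__(self) -> None:
        counts = (self.n_double_concordant, self.n_single_concordant, self.n_discordant)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative twin counts: {counts}")
        if sum(counts) == 0:
            raise ValueError("at least one twin pair is required")

    @property
    def total_pairs(self) -> int:
        return self.n_double_concordant + self.n_single_concordant + self.n_discordant


@dataclass(frozen=True)
class TwinH2Estimate:
    """Point estimate and optional bootstrap CI of twin heritability."""

    r_mz: float
    r_dz: float
    h2: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_low_clipped: float | None = None
    ci_high_clipped: float | None = None
    n_boot: int = 0
    seed: int | None = None
    n_degenerate_redrawn: int = 0

    @property
    def exceeds_one(self) -> bool:
        """True when the unclipped point estimate is above 1."""
        return self.h2 > 1.0


def probandwise_concordance(c: TwinCounts) -> float:
    """Probability that the co-twin of an ascertained proband is affected.

    Doubly-ascertained concordant pairs contribute two probands (both of
    whose co-twins are affected); singly-ascertained concordant pairs one;
    discordant pairs one proband with an unaffected co-twin:

    ``C = (2 d + s) / (2 d + s + u)``.
    """
    num = 2 * c.n_double_concordant + c.n_single_concordant
    den = num + c.n_discordant
    if den == 0:
        raise ValueError("no ascertained probands: all counts zero-like")
    return num / den


def bvn_upper_orthant(t1: float, t2: float, r: float) -> float:
    """``P(X > t1, Y > t2)`` for standard bivariate normal with correlation ``r``.

    Evaluated in closed form through Owen's T function,

    ``P = (Phibar(t1) + Phibar(t2))/2 - T(t1, a1) - T(t2, a2) - delta``,

    with ``a_j`` the standard Owen arguments and ``delta`` the quadrant
    correction; accurate to machine precision.  Degenerate correlations
    ``|r| = 1`` are handled directly.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {r}")
    if r == 1.0:
        return float(norm.sf(max(t1, t2)))
    if r == -1.0:
        # X > t1 and -X > t2  <=>  t1 < X < -t2
        return float(max(0.0, norm.cdf(-t2) - norm.cdf(t1)))
    return float(_orthant_owen(np.array([t1]), np.array([t2]), np.array([r]))[0])


def _orthant_owen(t1: np.ndarray, t2: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized Owen's-T orthant probability; requires |r| < 1."""
    from scipy.special import owens_t

    # nudge exact-zero thresholds so the Owen arguments are well defined;
    # the induced error is O(phi(0) * 1e-14)
    h = np.where(t1 == 0.0, 1e-14, np.asarray(t1, float))
    k = np.where(t2 == 0.0, 1e-14, np.asarray(t2, float))
    s = np.sqrt(1.0 - r * r)
    a1 = (k - r * h) / (h * s)
    a2 = (h - r * k) / (k * s)
    val = 0.5 * (norm.sf(h) + norm.sf(k)) - owens_t(h, a1) - owens_t(k, a2)
    val = np.where(h * k < 0.0, val - 0.5, val)
    return np.clip(val, 0.0, 1.0)


def tetrachoric_from_concordance(C: float, K: float, *, xtol: float = 1e-10) -> float:
    """Latent liability correlation of twin pairs with concordance ``C``.

    Solves ``P(L1 > t, L2 > t; r) / K = C`` for ``r`` with ``t`` the
    threshold for prevalence ``K``.  ``C < K`` implies a negative
    correlation and is allowed; ``C = 1`` maps to ``r = 1``.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"concordance must be in [0, 1], got {C}")
    t = liability_params(K).t
    target = C * K

    if C >= 1.0:
        return 1.0

    def f(r: float) -> float:
        return bvn_upper_orthant(t, t, r) - target

    lo, hi = -1.0, 1.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0.0 or f_hi < 0.0:
        raise ValueError(
            f"no tetrachoric correlation in [-1, 1] for C={C}, K={K}"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def twin_h2(mz: TwinCounts, dz: TwinCounts, K: float) -> TwinH2Estimate:
    """Falconer point estimate: ``h2 = 2 (r_MZ - r_DZ)``, unclipped."""
    r_mz = tetrachoric_from_concordance(probandwise_concordance(mz), K)
    r_dz = tetrachoric_from_concordance(probandwise_concordance(dz), K)
    return TwinH2Estimate(r_mz=r_mz, r_dz=r_dz, h2=2.0 * (r_mz - r_dz))


class _TetrachoricInterp:
    """Fast concordance -> correlation map used inside the bootstrap.

    Tabulates the monotone orthant probability on a dense correlation grid
    once per prevalence and inverts by linear interpolation; grid error is
    far below the multinomial noise of any realistic twin series.
    """

    def __init__(self, K: float, n_grid: int = 4001):
        t = liability_params(K).t
        self.K = K
        self.r_grid = np.linspace(-1.0 + 1e-9, 1.0 - 1e-9, n_grid)
        self.p_grid = _orthant_owen(
            np.full(n_grid, t), np.full(n_grid, t), self.r_grid
        )

    def __call__(self, C: np.ndarray) -> np.ndarray:
        target = np.asarray(C, dtype=float) * self.K
        r = np.interp(target, self.p_grid, self.r_grid)
        return np.where(np.asarray(C) >= 1.0, 1.0, r)


def bootstrap_twin_h2(
    mz: TwinCounts,
    dz: TwinCounts,
    K: float,
    n_boot: int = 100_000,
    seed: int | None = None,
) -> TwinH2Estimate:
    """Percentile bootstrap of the Falconer estimate over category counts.

    Resamples the three pair categories per zygosity from independent
    multinomials, recomputes ``2 (r_MZ - r_DZ)`` for each resample, and
    reports the 2.5/97.5 percentile interval (both raw and clipped to
    [0, 1]).  Resamples with an undefined concordance (all categories
    empty in effect) are redrawn; more than 50% degenerate is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = twin_h2(mz, dz, K)
    rng = np.random.default_rng(seed)
    interp = _TetrachoricInterp(K)

    def resample_concordances(c: TwinCounts) -> tuple[np.ndarray, int]:
        n = c.total_pairs
        p = np.array(
            [c.n_double_concordant, c.n_single_concordant, c.n_discordant], float
        ) / n
        draws = rng.multinomial(n, p, size=n_boot).astype(float)
        num = 2.0 * draws[:, 0] + draws[:, 1]
        den = num + draws[:, 2]
        bad = den == 0
        n_bad = int(bad.sum())
        redraws = 0
        while bad.any():
            redraws += int(bad.sum())
            if redraws > 0.5 * n_boot:
                raise ValueError("more than 50% of bootstrap resamples degenerate")
            extra = rng.multinomial(n, p, size=int(bad.sum())).astype(float)
            draws[bad] = extra
            num = 2.0 * draws[:, 0] + draws[:, 1]
            den = num + draws[:, 2]
            bad = den == 0
        return num / den, n_bad

    c_mz, bad_mz = resample_concordances(mz)
    c_dz, bad_dz = resample_concordances(dz)
    h2_boot = 2.0 * (interp(c_mz) - interp(c_dz))
    lo, hi = np.percentile(h2_boot, [2.5, 97.5])
    return TwinH2Estimate(
        r_mz=point.r_mz,
        r_dz=point.r_dz,
        h2=point.h2,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_low_clipped=float(np.clip(lo, 0.0, 1.0)),
        ci_high_clipped=float(np.clip(hi, 0.0, 1.0)),
        n_boot=n_boot,
        seed=seed,
        n_degenerate_redrawn=bad_mz + bad_dz,
    )
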
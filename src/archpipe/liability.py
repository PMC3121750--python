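"""Liability-threshold model: closed-form and root-finding conversions.

The liability-threshold model posits a latent standard-normal "liability"
for a dichotomous trait; an individual is affected when liability exceeds
the threshold ``t = Phi^-1(1 - K)`` set by the population prevalence ``K``.
All conversions in this module are deterministic functions of ``K`` and the
additive heritability of liability ``h2``:

* recurrence-risk ratio in relatives of an affected proband <-> ``h2``,
* ``h2`` -> the maximum AUC attainable by any genetic predictor,
* AUC of a score -> the proportion ``v`` of liability variance it explains,
* observed (0/1) scale heritability -> liability scale, with ascertainment
  correction for case-control sampling.

The recurrence-risk relation uses the truncated-normal (variance-reduction)
approximation; an exact bivariate-normal variant is available via
``exact=True`` and agrees with the approximation to well under 0.01 on h2
for realistic prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "LiabilityParams",
    "RelativeClass",
    "RELATIVE_CLASSES",
    "liability_params",
    "relative_risk_from_h2",
    "h2_from_relative_risk",
    "max_auc_from_h2",
    "v_from_auc",
    "prop_additive_explained",
    "liability_scale_transform",
]

DEFAULT_PREVALENCE = 0.01


@dataclass(frozen=True)
class LiabilityParams:
    """Threshold-model quantities derived from a prevalence ``K``.

    Attributes
    ----------
    K : float
        Population prevalence (lifetime disease probability).
    t : float
        Liability threshold, ``Phi^-1(1 - K)``.
    z : float
        Standard-normal density at ``t``.
    i_case : float
        Mean liability of affected individuals (selection intensity), ``z/K``.
    i_ctrl : float
        Mean liability of unaffected individuals, ``-z/(1 - K)``.
    """

    K: float
    t: float = field(init=False)
    z: float = field(init=False)
    i_case: float = field(init=False)
    i_ctrl: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0, 1), got {self.K}")
        t = norm.isf(self.K)
        z = norm.pdf(t)
        object.__setattr__(self, "t", float(t))
        object.__setattr__(self, "z", float(z))
        object.__setattr__(self, "i_case", float(z / self.K))
        object.__setattr__(self, "i_ctrl", float(-z / (1.0 - self.K)))


@dataclass(frozen=True)
class RelativeClass:
    """A class of relatives identified by its additive relationship ``a``."""

    label: str
    a: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a <= 1.0:
            raise ValueError(f"relationship coefficient must be in (0, 1], got {self.a}")


#: Standard relative classes keyed by short name.
RELATIVE_CLASSES: dict[str, RelativeClass] = {
    "mz": RelativeClass("MZ twin", 1.0),
    "first": RelativeClass("first-degree", 0.5),
    "second": RelativeClass("second-degree", 0.25),
    "third": RelativeClass("third-degree", 0.125),
}


def liability_params(K: float) -> LiabilityParams:
    """Return the threshold-model parameters for prevalence ``K``."""
    return LiabilityParams(K)


def _resolve_rel(rel: RelativeClass | str | float) -> RelativeClass:
    if isinstance(rel, RelativeClass):
        return rel
    if isinstance(rel, str):
        try:
            return RELATIVE_CLASSES[rel]
        except KeyError:
            raise ValueError(
                f"unknown relative class {rel!r}; choose from {sorted(RELATIVE_CLASSES)}"
            ) from None
    return RelativeClass(f"a={rel}", float(rel))


def _bvn_upper_orthant_scalar(t1: float, t2: float, r: float) -> float:
    # local import to avoid a cycle: twins.py provides the quadrature routine
    from .twins import bvn_upper_orthant

    return bvn_upper_orthant(t1, t2, r)


def relative_risk_from_h2(
    h2: float,
    rel: RelativeClass | str | float = "first",
    K: float = DEFAULT_PREVALENCE,
    *,
    exact: bool = False,
) -> float:
    """Recurrence-risk ratio ``lambda_R`` in relatives of affected probands.

    Under the threshold model a relative with additive relationship ``a``
    of an affected proband has liability mean ``a h2 i_case`` and reduced
    variance; the approximate risk is

    ``K_R = 1 - Phi((t - a h2 i) / sqrt(1 - a^2 h2^2 i (i - t)))``

    and ``lambda_R = K_R / K``.  With ``exact=True`` the risk is computed
    from the bivariate-normal upper orthant with liability correlation
    ``a h2`` instead of the truncated-normal approximation.
    """
    rel = _resolve_rel(rel)
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    p = liability_params(K)
    if exact:
        r = rel.a * h2
        k_r = _bvn_upper_orthant_scalar(p.t, p.t, r) / K
        return float(k_r / K)
    a, i, t = rel.a, p.i_case, p.t
    var_red = 1.0 - a * a * h2 * h2 * i * (i - t)
    if var_red <= 0.0:
        raise ValueError(
            f"variance-reduction term non-positive for h2={h2}, a={a}, K={K}"
        )
    t_r = (t - a * h2 * i) / np.sqrt(var_red)
    return float(norm.sf(t_r) / K)


def h2_from_relative_risk(
    lambda_r: float,
    rel: RelativeClass | str | float = "first",
    K: float = DEFAULT_PREVALENCE,
    *,
    exact: bool = False,
    xtol: float = 1e-9,
) -> float:
    """Heritability of liability implied by a recurrence-risk ratio.

    Inverts :func:`relative_risk_from_h2` by monotone root-finding on
    ``h2 in [0, 1 + eps]``.  A root above 1 (the relative risk exceeds what
    full heritability can produce) is returned unclipped; callers that print
    tables flag such values as ">1".
    """
    rel = _resolve_rel(rel)
    if lambda_r < 1.0:
        raise ValueError(f"recurrence-risk ratio must be >= 1, got {lambda_r}")
    if lambda_r * K >= 1.0:
        raise ValueError(
            f"infeasible risk: lambda_r*K = {lambda_r * K:.4g} >= 1 (K={K})"
        )
    if lambda_r == 1.0:
        return 0.0

    def f(h2: float) -> float:
        return relative_risk_from_h2(h2, rel, K, exact=exact) - lambda_r

    hi = 1.0
    # extend past 1 while the relation remains defined, to report ">1" roots
    while f(hi) < 0.0:
        hi += 0.25
        if hi > 2.0:
            raise ValueError(
                f"lambda_r={lambda_r} unattainable for rel a={rel.a}, K={K}"
            )
        try:
            f(hi)
        except ValueError:
            raise ValueError(
                f"lambda_r={lambda_r} unattainable for rel a={rel.a}, K={K}"
            ) from None
    return float(brentq(f, 0.0, hi, xtol=xtol))


def max_auc_from_h2(h2: float, K: float = DEFAULT_PREVALENCE) -> float:
    """Maximum theoretical AUC of a genetic predictor with heritability ``h2``.

    The best possible genetic score is the true genetic liability; cases and
    controls then have normal score distributions with means ``h2*i_case``
    and ``h2*i_ctrl`` and variances reduced by selection, giving

    ``AUC = Phi((i_case - i_ctrl) h2 / sqrt(h2(1 - h2 i_case(i_case - t))
    + h2(1 - h2 i_ctrl(i_ctrl - t))))``.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    if h2 == 0.0:
        return 0.5
    p = liability_params(K)
    i, i2, t = p.i_case, p.i_ctrl, p.t
    num = (i - i2) * h2
    den = np.sqrt(h2 * (1.0 - h2 * i * (i - t)) + h2 * (1.0 - h2 * i2 * (i2 - t)))
    return float(norm.cdf(num / den))


def v_from_auc(auc: float, K: float = DEFAULT_PREVALENCE, *, xtol: float = 1e-12) -> float:
    """Liability variance explained by a score that achieves ``auc``.

    Inverse of :func:`max_auc_from_h2` with the score's variance ``v`` in
    the role of ``h2``: the score explains a fraction ``v`` of liability
    variance, so its discrimination equals that of a trait with
    heritability ``v``.
    """
    if auc < 0.5:
        raise ValueError(f"AUC below 0.5 (anti-predictive score): {auc}")
    if auc >= 1.0:
        raise ValueError(f"AUC must be < 1, got {auc}")
    if auc == 0.5:
        return 0.0
    hi = 1.0 - 1e-13
    if max_auc_from_h2(hi, K) < auc:
        return 1.0
    return float(brentq(lambda v: max_auc_from_h2(v, K) - auc, 0.0, hi, xtol=xtol))


def prop_additive_explained(
    auc: float, h2: float, K: float = DEFAULT_PREVALENCE
) -> float:
    """Proportion of additive genetic variance explained by a genetic profile.

    ``v_from_auc(auc, K) / h2``; exceeds 1 only when ``auc`` is larger than
    the theoretical maximum for ``h2``, which indicates inconsistent inputs
    and triggers a warning.
    """
    if h2 <= 0.0:
        raise ValueError("h2 must be positive to define a proportion of it")
    v = v_from_auc(auc, K)
    ratio = v / h2
    if ratio > 1.0:
        import warnings

        warnings.warn(
            f"AUC {auc} exceeds the maximum {max_auc_from_h2(h2, K):.4f} "
            f"for h2={h2}: proportion {ratio:.3f} > 1",
            stacklevel=2,
        )
    return float(ratio)


def liability_scale_transform(h2_obs: float, K: float, P: float) -> float:
    """Transform observed-scale (0/1) heritability to the liability scale.

    For a case-control sample with case fraction ``P`` drawn from a
    population with prevalence ``K``:

    ``h2_l = h2_obs * K(1-K)/z^2 * K(1-K)/(P(1-P))``

    where ``z`` is the normal density at the threshold.  With ``P = K``
    (random population sample) the second factor is 1 and the expression
    reduces to the classical observed-to-liability factor ``K(1-K)/z^2``.
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must be in (0, 1), got {K}")
    if not 0.0 < P < 1.0:
        raise ValueError(f"case fraction P must be in (0, 1), got {P}")
    p = liability_params(K)
    factor = (K * (1.0 - K) / p.z**2) * (K * (1.0 - K) / (P * (1.0 - P)))
    return float(h2_obs * factor)
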
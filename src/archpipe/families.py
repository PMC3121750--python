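"""Extended-pedigree liability simulation and the sporadic-case proportion.

A "sporadic" case is an affected individual with no affected relatives in
a specified set.  Even for substantially heritable traits most cases of a
rare disease are sporadic: with low prevalence, few of any case's
relatives cross the liability threshold.  This module quantifies that by
Monte-Carlo simulation of an extended pedigree under the multivariate
normal liability model — liabilities jointly normal with covariance
``h2 * A + (1 - h2) * I`` where ``A`` is the additive relationship matrix
— conditioning on an affected index case.

Conditional sampling is exact: the index liability is drawn from the
normal distribution truncated above the threshold, and relatives from the
conditional MVN given the index, so no rejection is needed even at small
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .liability import liability_params

__all__ = [
    "Pedigree",
    "FamilyDraws",
    "SporadicResult",
    "build_default_pedigree",
    "simulate_families",
    "sporadic_proportion",
    "FULL_RELATIVE_SET",
    "FIRST_DEGREE_SET",
]

#: roles counted for the broad "sporadic" definition
FULL_RELATIVE_SET = frozenset(
    {"parent", "child", "sibling", "grandparent", "aunt_uncle", "first_cousin"}
)
#: roles for the narrow definition (no affected parent or sibling)
FIRST_DEGREE_SET = frozenset({"parent", "sibling"})


@dataclass(frozen=True)
class Pedigree:
    """Members with role labels plus their additive relationship matrix.

    Spouses who marry into the family are modelled while building ``A``
    (they are parents of cousins/children) but are excluded from the blood
    set stored here; their liabilities are independent of the index's and
    they are never part of a relative set.
    """

    names: tuple[str, ...]
    roles: tuple[str, ...]
    A: np.ndarray
    index: int = field(default=0)

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.A.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("relationship matrix must be symmetric")

    def members_with_roles(self, roles: frozenset[str] | set[str]) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r in roles]


@dataclass(frozen=True)
class FamilyDraws:
    """Affection statuses for simulated families ascertained via the index.

    ``affected`` is a boolean (n_families, n_members) array following the
    pedigree's member order; the index member's column is all True.
    """

    pedigree: Pedigree
    affected: np.ndarray
    h2: float
    K: float
    seed: int | None


@dataclass(frozen=True)
class SporadicResult:
    proportion: float
    ci_low: float
    ci_high: float
    n_families: int
    n_relatives_considered: int


def _kinship(parents: dict[str, tuple[str | None, str | None]]) -> tuple[list[str], np.ndarray]:
    """Kinship coefficients by the standard recursive tabular method.

    ``parents`` must list every individual after both of its parents
    (founders carry ``(None, None)``).
    """
    names = list(parents)
    idx = {n: i for i, n in enumerate(names)}
    phi = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        f, m = parents[a]
        if f is None:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 + 0.5 * phi[idx[f], idx[m]]
        for j in range(i):
            if f is None:
                phi[i, j] = phi[j, i] = 0.0
            else:
                phi[i, j] = phi[j, i] = 0.5 * (phi[idx[f], j] + phi[idx[m], j])
    return names, phi


def build_default_pedigree(children_per_couple: int = 3) -> Pedigree:
    """Extended pedigree with a fixed number of children for every couple.

    The index has ``c - 1`` siblings and ``c`` children (``c`` =
    ``children_per_couple``); each parent likewise has ``c - 1`` siblings
    (the index's aunts/uncles), each of whom has ``c`` children (first
    cousins); plus 2 parents and 4 grandparents.  With ``c = 3`` that is
    23 blood relatives around the index.
    """
    if children_per_couple < 1:
        raise ValueError("children_per_couple must be >= 1")
    c = children_per_couple
    parents: dict[str, tuple[str | None, str | None]] = {}
    roles: dict[str, str] = {}

    def add(name: str, role: str, f: str | None = None, m: str | None = None) -> None:
        parents[name] = (f, m)
        roles[name] = role

    for g in ("pgf", "pgm", "mgf", "mgm"):
        add(g, "grandparent")
    add("father", "parent", "pgf", "pgm")
    add("mother", "parent", "mgf", "mgm")
    for side, (gf, gm) in (("p", ("pgf", "pgm")), ("m", ("mgf", "mgm"))):
        for i in range(c - 1):
            au = f"{side}_auntuncle_{i}"
            sp = f"{side}_auntuncle_{i}_spouse"
            add(au, "aunt_uncle", gf, gm)
            add(sp, "spouse")
            for j in range(c):
                add(f"{side}_cousin_{i}_{j}", "first_cousin", au, sp)
    add("index", "index", "father", "mother")
    for i in range(c - 1):
        add(f"sibling_{i}", "sibling", "father", "mother")
    add("index_spouse", "spouse")
    for i in range(c):
        add(f"child_{i}", "child", "index", "index_spouse")

    names, phi = _kinship(parents)
    blood = [n for n in names if roles[n] != "spouse"]
    order = ["index"] + [n for n in blood if n != "index"]
    sel = [names.index(n) for n in order]
    A = 2.0 * phi[np.ix_(sel, sel)]
    return Pedigree(
        names=tuple(order),
        roles=tuple(roles[n] for n in order),
        A=A,
        index=0,
    )


def simulate_families(
    ped: Pedigree,
    h2: float,
    K: float,
    n_families: int,
    seed: int | None = None,
    batch_size: int = 100_000,
) -> FamilyDraws:
    """Draw affection statuses for families ascertained through the index.

    Liabilities are MVN(0, ``h2 A + (1 - h2) I``); a member is affected
    when its liability exceeds the threshold for prevalence ``K``.  The
    index is conditioned to be affected by sampling its liability from the
    truncated upper tail and the relatives from the conditional MVN.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    n = len(ped.names)
    t = liability_params(K).t
    C = h2 * ped.A + (1.0 - h2) * np.eye(n)
    ii = ped.index
    others = [k for k in range(n) if k != ii]
    c_oi = C[others, ii]
    cond_cov = C[np.ix_(others, others)] - np.outer(c_oi, c_oi) / C[ii, ii]
    # degenerate structures (h2=1 with duplicated members) make the
    # conditional covariance singular; factor via eigen-clipping then
    try:
        L = np.linalg.cholesky(cond_cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cond_cov)
        if w.min() < -1e-8:
            raise np.linalg.LinAlgError(
                f"conditional liability covariance not PSD for pedigree "
                f"{ped.names} with h2={h2}"
            ) from None
        L = V * np.sqrt(np.clip(w, 0.0, None))

    rng = np.random.default_rng(seed)
    affected = np.empty((n_families, n), dtype=bool)
    affected[:, ii] = True
    done = 0
    sf_t = norm.sf(t)
    while done < n_families:
        nb = min(batch_size, n_families - done)
        # index liability from the upper-truncated standard normal
        li = norm.isf(sf_t * rng.uniform(size=nb))
        z = rng.standard_normal((nb, n - 1))
        lo = (c_oi / C[ii, ii])[None, :] * li[:, None] + z @ L.T
        affected[done : done + nb, others] = lo > t
        done += nb
    return FamilyDraws(pedigree=ped, affected=affected, h2=h2, K=K, seed=seed)


def sporadic_proportion(
    draws: FamilyDraws,
    relative_set: frozenset[str] | set[str] = FULL_RELATIVE_SET,
    alpha: float = 0.05,
) -> SporadicResult:
    """Fraction of index cases with no affected relative in ``relative_set``.

    Attaches a Wilson score interval for the binomial proportion.
    """
    if not relative_set:
        raise ValueError("relative_set must not be empty")
    cols = draws.pedigree.members_with_roles(relative_set)
    if not cols:
        raise ValueError(f"no pedigree member has a role in {sorted(relative_set)}")
    sporadic = ~draws.affected[:, cols].any(axis=1)
    n = sporadic.size
    p = float(sporadic.mean())
    zq = norm.isf(alpha / 2.0)
    denom = 1.0 + zq**2 / n
    center = (p + zq**2 / (2 * n)) / denom
    half = zq * np.sqrt(p * (1 - p) / n + zq**2 / (4 * n**2)) / denom
    return SporadicResult(
        proportion=p,
        ci_low=float(max(0.0, center - half)),
        ci_high=float(min(1.0, center + half)),
        n_families=n,
        n_relatives_considered=len(cols),
    )
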
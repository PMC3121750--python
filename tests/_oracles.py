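"""Independent reference implementations used only to check the package.

Each oracle computes the same quantity as a package routine by a
different, simpler route (enumeration, brute-force quadrature, a generic
constrained optimizer) and is deliberately kept free of archpipe
internals.
"""

import itertools

import numpy as np
from scipy.integrate import dblquad
from scipy.optimize import minimize
from scipy.special import gammaln


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by direct enumeration over heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * min(n_AA, n_aa) + n_Aa
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hs = np.arange(n_a % 2, n_a + 1, 2)
    logp = []
    for h in hs:
        n_hom_rare = (n_a - h) // 2
        n_hom_common = (2 * n - n_a - h) // 2
        logp.append(
            gammaln(n + 1)
            - gammaln(n_hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(n_hom_common + 1)
            + h * np.log(2)
            - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(2 * n - n_a + 1))
        )
    p = np.exp(np.array(logp))
    p /= p.sum()
    obs = p[np.searchsorted(hs, n_Aa)]
    return float(p[p <= obs * (1 + 1e-12)].sum())


def elastic_net_oracle(X, y, lam1, lam2) -> float:
    """Optimal objective value by L-BFGS-B on the split form beta = b+ - b-."""
    n, m = X.shape

    def obj(params):
        b0, bp, bm = params[0], params[1 : 1 + m], params[1 + m :]
        b = bp - bm
        eta = b0 + X @ b
        return (
            np.sum(np.logaddexp(0, eta))
            - y @ eta
            + lam1 * np.sum(bp + bm)
            + lam2 * (b @ b)
        )

    res = minimize(
        obj,
        np.zeros(1 + 2 * m),
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0, None)] * (2 * m),
        options={"maxiter": 50000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.fun


def orthant_brute(t1, t2, r) -> float:
    """2-D adaptive quadrature of the bivariate normal density."""
    det = 1.0 - r * r

    def dens(y, x):
        return np.exp(-(x * x - 2 * r * x * y + y * y) / (2 * det)) / (
            2 * np.pi * np.sqrt(det)
        )

    val, _ = dblquad(dens, t1, 9.0, lambda x: t2, lambda x: 9.0, epsabs=1e-12)
    return val


def auc_brute_force(scores, y) -> float:
    """Exhaustive enumeration over case-control score pairs, ties half."""
    cases = scores[y == 1]
    ctrls = scores[y == 0]
    total = 0.0
    for c, t in itertools.product(cases, ctrls):
        total += 1.0 if c > t else (0.5 if c == t else 0.0)
    return total / (len(cases) * len(ctrls))
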
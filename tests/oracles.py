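"""Independent reference implementations used to check the analysis code.

Everything here deliberately avoids the package's own likelihood and DP
routines: log-densities come from scipy.stats.norm, optimization from brute
grids plus scipy.optimize, and partitions from exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm


def mixture_loglik_ref(x, s, means, weights) -> float:
    """Reference mixture log-likelihood via scipy.stats.norm."""
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    dens = np.zeros(x.size)
    for mu, w in zip(means, weights):
        dens += w * norm.pdf(x, loc=mu, scale=s)
    with np.errstate(divide="ignore"):
        return float(np.log(dens).sum())


def best_loglik_grid(x, s, K, grid_step=1.0) -> float:
    """Maximum mixture log-likelihood found by grid search + local refinement.

    K <= 2 only.  The grid covers the data range; the top grid points seed
    Nelder-Mead refinements of the exact likelihood.
    """
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    lo, hi = x.min() - 1.0, x.max() + 1.0
    mgrid = np.arange(lo, hi + grid_step, grid_step)
    if K == 1:
        best = max(mixture_loglik_ref(x, s, [m], [1.0]) for m in mgrid)
        refined = [
            -minimize(lambda p: -mixture_loglik_ref(x, s, [p[0]], [1.0]),
                      [m0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for m0 in np.linspace(lo, hi, 5)
        ]
        return max([best] + refined)

    assert K == 2
    pis = np.linspace(0.05, 0.95, 19)
    cands = []
    for m1, m2 in itertools.combinations_with_replacement(mgrid, 2):
        for pi in pis:
            ll = mixture_loglik_ref(x, s, [m1, m2], [pi, 1 - pi])
            cands.append((ll, m1, m2, pi))
    cands.sort(reverse=True)
    best = cands[0][0]

    def neg(p):
        m1, m2, t = p
        pi = 1.0 / (1.0 + np.exp(-t))
        return -mixture_loglik_ref(x, s, [m1, m2], [pi, 1 - pi])

    for ll, m1, m2, pi in cands[:5]:
        t0 = np.log(pi / (1 - pi))
        res = minimize(neg, [m1, m2, t0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = max(best, -res.fun)
    return best


def contiguous_partitions(n: int, k: int):
    """All partitions of range(n) into k contiguous non-empty blocks."""
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        yield [(edges[i], edges[i + 1]) for i in range(k)]


def block_loglik_ref(x, s, blocks) -> float:
    """Reference partition log-likelihood (inverse-variance block means)."""
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    total = 0.0
    for i, j in blocks:
        w = 1.0 / s[i:j] ** 2
        mu = np.sum(w * x[i:j]) / np.sum(w)
        total += float(norm.logpdf(x[i:j], loc=mu, scale=s[i:j]).sum())
    return total


def best_partition_ref(x, s, k):
    """Exhaustively optimal contiguous partition (leftmost among ties)."""
    best_ll, best_blocks = -np.inf, None
    for blocks in contiguous_partitions(len(x), k):
        ll = block_loglik_ref(x, s, blocks)
        if ll > best_ll + 1e-12:
            best_ll, best_blocks = ll, blocks
    return best_blocks, best_ll


def fisher_two_sided_ref(table) -> float:
    """Two-sided Fisher p as an exact fraction via comb(), as a float."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        k: comb(r1, k) * comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return sum(v for v in probs.values() if v <= p_obs) / denom
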
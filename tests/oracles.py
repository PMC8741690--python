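"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles — exact integer
arithmetic for hypergeometric tail sums, full enumeration of label
permutations for rank tests, direct bisection of the noncentral
hypergeometric tails for odds-ratio confidence limits — so that agreement
with the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# -- Fisher's exact test ----------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int, tie_tol: float = 1e-7) -> float:
    """Two-sided probability-mass p value in exact rational arithmetic.

    Table probabilities share the common denominator C(n, c1), so they can
    be ordered by their integer numerators C(r1, k) * C(r2, c1 - k); the
    relative tie tolerance is applied in exact arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, n - c1):
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    rel = Fraction(tie_tol).limit_denominator(10**12)
    cutoff = Fraction(w_obs) * (1 + rel)
    num = sum(w for w in weights.values() if w <= cutoff)
    return float(Fraction(num, math.comb(n, c1)))


# -- rank tests by full enumeration ----------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def mann_whitney_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided permutation p for U (mid-ranks, distance from the
    null mean n_x n_y / 2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * ny / 2
    hits = total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def _ks_stat(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_oracle(x, y) -> tuple[float, float]:
    """Exact permutation p for the two-sample KS distance."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    d_obs = _ks_stat(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        total += 1
        if _ks_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total


# -- exact conditional odds-ratio inference --------------------------------

def _nchg_terms(a: int, b: int, c: int, d: int, log_psi: float):
    """Noncentral hypergeometric weights over the support, as log-terms."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logs = np.array(
        [
            math.log(math.comb(r1, k)) + math.log(math.comb(r2, c1 - k)) + k * log_psi
            for k in ks
        ]
    )
    logs -= logs.max()
    probs = np.exp(logs)
    return ks, probs / probs.sum()


def nchg_tail(a: int, b: int, c: int, d: int, log_psi: float, upper: bool) -> float:
    ks, probs = _nchg_terms(a, b, c, d, log_psi)
    return float(probs[ks >= a].sum() if upper else probs[ks <= a].sum())


def conditional_mle_oracle(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio maximising the conditional likelihood: solves E[A] = a."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf

    def mean_minus_a(log_psi):
        ks, probs = _nchg_terms(a, b, c, d, log_psi)
        return float((ks * probs).sum()) - a

    return math.exp(_bisect(mean_minus_a, decreasing=False))


def exact_ci_oracle(a: int, b: int, c: int, d: int, confidence: float = 0.95):
    """Cornfield-style exact CI: invert the one-sided conditional tails."""
    alpha = (1 - confidence) / 2
    r1, r2, c1 = a + b, c + d, a + c
    lo_sup, hi_sup = max(0, c1 - r2), min(r1, c1)

    if a == lo_sup:
        low = 0.0
    else:
        low = math.exp(
            _bisect(lambda lp: nchg_tail(a, b, c, d, lp, upper=True) - alpha, decreasing=False)
        )
    if a == hi_sup:
        high = math.inf
    else:
        high = math.exp(
            _bisect(lambda lp: nchg_tail(a, b, c, d, lp, upper=False) - alpha, decreasing=True)
        )
    return low, high


def _bisect(f, decreasing: bool, lo: float = -40.0, hi: float = 40.0, tol: float = 1e-10) -> float:
    """Find the root of a monotone function of log-psi on [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    sign = -1.0 if decreasing else 1.0
    if sign * flo > 0 or sign * fhi < 0:
        raise ValueError("root not bracketed")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if sign * f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# -- quantiles --------------------------------------------------------------

def quantile_oracle(values, q: float) -> float:
    """Linear-interpolation ("type 7") empirical quantile, from scratch."""
    s = sorted(float(v) for v in values)
    if not 0 <= q <= 1:
        raise ValueError("q in [0, 1]")
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])
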
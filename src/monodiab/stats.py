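"""Exact and classical inference for 2x2 tables, proportions and score
distributions.

All routines are pure functions.  The 2x2 machinery follows the exact
conditional school: Fisher's two-tailed test by the probability-mass
convention (the p value sums every table, with the observed margins, whose
hypergeometric probability does not exceed the observed one, with a 1e-7
relative tolerance for floating-point ties), odds ratios as the conditional
maximum-likelihood estimate under the noncentral hypergeometric model with
Cornfield-style exact confidence limits, and binomial proportions with
Clopper-Pearson intervals.  Rank tests (Mann-Whitney, two-sample
Kolmogorov-Smirnov) use exact small-sample null distributions where
feasible and tie-corrected asymptotics otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

#: relative tolerance when comparing hypergeometric probabilities for ties
FISHER_TIE_TOLERANCE = 1e-7

#: largest product n_x * n_y for which rank tests attempt an exact p value
EXACT_RANK_LIMIT = 400

#: largest number of label permutations fully enumerated for tied samples
_MAX_ENUMERATION = 250_000


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = criterion present/absent, columns =
    case group / comparison group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d

    @property
    def col_margins(self) -> tuple[int, int]:
        return self.a + self.c, self.b + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable2x2(*arr.ravel().tolist())


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for a proportion via beta-quantile inversion.

    The lower limit is 0 when x = 0 and the upper limit 1 when x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    low, high = proportion_confint(x, n, alpha=1.0 - confidence, method="beta")
    return float(low), float(high)


def fisher_exact(table) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Enumerates the full hypergeometric support of the upper-left cell given
    the margins and sums the probability of every table at most as probable
    as the observed one (relative tie tolerance 1e-7).  A table with a zero
    margin carries no information about association: p = 1 by convention,
    with a warning.
    """
    t = _as_table(table)
    r1, r2 = t.row_margins
    c1, c2 = t.col_margins
    if 0 in (r1, r2, c1, c2):
        warnings.warn("2x2 table has a zero margin; Fisher p = 1 by convention", stacklevel=2)
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, t.total, r1, c1)
    p_obs = pmf[t.a - lo]
    p = pmf[pmf <= p_obs * (1.0 + FISHER_TIE_TOLERANCE)].sum()
    return float(min(p, 1.0))


@dataclass(frozen=True)
class OddsRatioExact:
    """Conditional-MLE odds ratio with exact confidence limits.

    ``sample_odds_ratio`` is the cross-product (a*d)/(b*c), reported for
    transparency; the exact CI belongs to the conditional estimate.
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    sample_odds_ratio: float
    confidence: float


def odds_ratio_exact(table, confidence: float = 0.95) -> OddsRatioExact:
    """Exact (conditional maximum likelihood) odds ratio and CI for a 2x2.

    A zero margin (two zero cells in one row or column) leaves the odds
    ratio undefined and raises; a single zero cell yields a one-sided
    interval with the other limit at 0 or infinity.
    """
    t = _as_table(table)
    if 0 in t.row_margins or 0 in t.col_margins:
        raise ValueError("odds ratio undefined: a full row or column of the table is zero")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    res = _scipy_odds_ratio(t.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    if t.b * t.c > 0:
        sample = (t.a * t.d) / (t.b * t.c)
    else:
        sample = math.inf
    return OddsRatioExact(
        float(res.statistic), float(ci.low), float(ci.high), float(sample), confidence
    )


def two_sample_proportion(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sample test for equality of proportions (pooled-variance normal
    z, no continuity correction); returns (z, two-sided p)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p = 1 by convention", stacklevel=2)
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for x, two-sided p).

    Small samples (n_x * n_y <= 400) get an exact p: via the classical
    no-ties null distribution, or by full enumeration of label permutations
    with mid-ranks when ties are present and the permutation count is
    manageable.  Larger (or intractably tied) samples use the tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    if nx * ny <= EXACT_RANK_LIMIT:
        if not _has_ties(pooled):
            res = sps.mannwhitneyu(x, y, method="exact")
            return float(res.statistic), float(res.pvalue)
        if math.comb(nx + ny, nx) <= _MAX_ENUMERATION:
            return u1, _mw_permutation_p(ranks, nx, ny, u1)
    res = sps.mannwhitneyu(x, y, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _mw_permutation_p(ranks: np.ndarray, nx: int, ny: int, u_obs: float) -> float:
    """Exact two-sided permutation p for U with mid-rank ties: the
    probability of a |U - n_x n_y / 2| at least as large as observed."""
    n = nx + ny
    combos = np.array(list(itertools.combinations(range(n), nx)))
    u_all = ranks[combos].sum(axis=1) - nx * (nx + 1) / 2
    mu = nx * ny / 2.0
    return float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test; returns (D, two-sided p).

    D is the supremum distance between the two empirical CDFs.  The p value
    is exact for small samples (see :func:`mann_whitney` for the branch
    rules) and asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    if nx * ny <= EXACT_RANK_LIMIT:
        if not _has_ties(pooled):
            res = sps.ks_2samp(x, y, method="exact")
            return float(res.statistic), float(res.pvalue)
        if math.comb(nx + ny, nx) <= _MAX_ENUMERATION:
            d_obs = float(sps.ks_2samp(x, y, method="asymp").statistic)
            return d_obs, _ks_permutation_p(pooled, nx, ny, d_obs)
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _ks_permutation_p(pooled: np.ndarray, nx: int, ny: int, d_obs: float) -> float:
    """Exact permutation p for D by full enumeration (handles ties)."""
    n = nx + ny
    uq = np.unique(pooled)
    le = pooled[None, :] <= uq[:, None]  # (n_unique, n)
    tot_le = le.sum(axis=1)
    combos = np.array(list(itertools.combinations(range(n), nx)))
    cx = le[:, combos].sum(axis=2)  # (n_unique, n_combos)
    cy = tot_le[:, None] - cx
    d_all = np.abs(cx / nx - cy / ny).max(axis=0)
    return float(np.mean(d_all >= d_obs - 1e-12))


# ---------------------------------------------------------------------------
# criterion evaluation (selection-criteria performance, forest-plot rows)
# ---------------------------------------------------------------------------

#: Built-in clinical selection criteria, as predicates over a ChildRecord.
#: Each returns True/False, or None when the underlying datum is missing
#: (the child is then excluded pairwise from that criterion's table).
BUILTIN_CRITERIA: dict[str, Callable] = {
    "non_insulin_treatment": lambda r: not r.insulin_treated,
    "parent_with_diabetes": lambda r: r.parent_with_diabetes,
    "hba1c_le_58": lambda r: None if r.hba1c is None else r.hba1c <= 58.0,
    "mody_probability_ge_10": lambda r: (
        None if r.mody_probability is None else r.mody_probability >= 0.10
    ),
    "extra_pancreatic_features": lambda r: len(r.extra_pancreatic_features) > 0,
    "parental_consanguinity": lambda r: r.parental_consanguinity,
}


@dataclass(frozen=True)
class CriterionResult:
    criterion_name: str
    target_group: str
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    sample_odds_ratio: float
    fisher_p: float
    n_excluded_missing: int


def evaluate_criterion(
    cohort: Iterable,
    diagnoses: Iterable,
    criterion: str | tuple[str, Callable],
    target_group: str,
    confidence: float = 0.95,
) -> CriterionResult:
    """Association between a clinical criterion and one inheritance class.

    Builds the 2x2 of criterion presence against membership of the target
    case group (children with a confirmed diagnosis of that inheritance
    class) versus the rest of the cohort, then applies the exact odds ratio
    and Fisher's exact test.  Children for whom the criterion cannot be
    evaluated (missing datum) are excluded pairwise and counted.
    """
    if target_group not in ("autosomal_dominant", "autosomal_recessive"):
        raise ValueError("target group must be autosomal_dominant or autosomal_recessive")
    if isinstance(criterion, str):
        if criterion not in BUILTIN_CRITERIA:
            raise KeyError(
                f"unknown criterion {criterion!r}; available: {sorted(BUILTIN_CRITERIA)}"
            )
        name, predicate = criterion, BUILTIN_CRITERIA[criterion]
    else:
        name, predicate = criterion

    target_ids = {d.child_id for d in diagnoses if d.inheritance == target_group}
    a = b = c = d = n_missing = 0
    for rec in cohort:
        value = predicate(rec)
        if value is None:
            n_missing += 1
            continue
        is_case = rec.child_id in target_ids
        if value:
            a, b = a + (1 if is_case else 0), b + (0 if is_case else 1)
        else:
            c, d = c + (1 if is_case else 0), d + (0 if is_case else 1)
    table = ContingencyTable2x2(a, b, c, d)
    orx = odds_ratio_exact(table, confidence)
    p = fisher_exact(table)
    return CriterionResult(
        name, target_group, table, orx.odds_ratio, orx.ci_low, orx.ci_high,
        orx.sample_odds_ratio, p, n_missing,
    )


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------


def format_percent(x: float) -> str:
    """Proportion (0-1) as a percentage with one decimal."""
    return f"{100.0 * x:.1f}%"


def format_p(p: float) -> str:
    """p value in the conventional clinical-journal style."""
    if p >= 0.01:
        return f"{p:.2f}"
    if p >= 0.001:
        return f"{p:.3f}"
    exponent = math.floor(math.log10(p))
    mantissa = p / 10**exponent
    return f"{mantissa:.0f}e{exponent:d}"
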
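"""Cohort-level statistics: correlations, group comparisons, and the H-score.

Correlations are Pearson or Spearman with two-sided p; two-group
comparisons are two-sided by default (exact Mann-Whitney by enumeration
for small tie-free data, normal approximation with tie correction
otherwise, matching the practice of comparing non-normal per-tumor
totals).  The IHC H-score is the weighted staining sum
1*(%weak) + 2*(%moderate) + 3*(%strong), range 0-300.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MW_MAX_N = 20


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int
    slope: float | None = None
    intercept: float | None = None


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p.

    Pairs with a missing member are dropped (pairwise-complete); at least
    3 complete pairs are required and constant vectors are an error, not a
    NaN.  Pearson results carry the fitted least-squares line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        return CorrelationResult("pearson", float(r), float(p), x.size,
                                 float(fit.slope), float(fit.intercept))
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return CorrelationResult("spearman", float(rho), float(p), x.size)
    raise ValueError(f"unknown correlation method {method!r}")


@lru_cache(maxsize=None)
def _mw_u_distribution(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of rank assignments with U statistic u (no ties).

    Classic Mann-Whitney recurrence: distributions over group sizes build
    up by either appending the largest observation to group 1 (adding n2
    to U) or to group 2.
    """
    table: dict[tuple[int, int], np.ndarray] = {}
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            if a == 0 or b == 0:
                table[(a, b)] = np.ones(1)
                continue
            top = table[(a - 1, b)]  # largest obs in group 1: U gains b
            bottom = table[(a, b - 1)]
            size = a * b + 1
            counts = np.zeros(size)
            counts[b:b + top.size] += top
            counts[:bottom.size] += bottom
            table[(a, b)] = counts
    return table[(n1, n2)]


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p via the tie-free U distribution."""
    n1, n2 = len(a), len(b)
    u = sum((x > y) for x in a for y in b)
    counts = _mw_u_distribution(n1, n2)
    u_min = min(u, n1 * n2 - u)
    p = 2 * counts[: int(u_min) + 1].sum() / counts.sum()
    return float(u), float(min(1.0, p))


def _mann_whitney_asymptotic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Normal approximation with mid-ranks and tie-corrected variance."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    exact: bool = False


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> ComparisonResult:
    """Two-group comparison: Mann-Whitney U, Fisher 2x2, or chi-square.

    Mann-Whitney uses full enumeration of the U distribution when the
    combined sample is small (<= 20) and tie-free, the tie-corrected
    normal approximation otherwise.  ``fisher_2x2`` and ``chi_square``
    expect the two rows of a contingency table.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        ties = np.unique(pooled).size < pooled.size
        if pooled.size <= EXACT_MW_MAX_N and not ties:
            stat, p = _mann_whitney_exact(a, b)
            return ComparisonResult("mann_whitney", stat, p, exact=True)
        stat, p = _mann_whitney_asymptotic(a, b)
        return ComparisonResult("mann_whitney", stat, p, exact=False)
    if test == "fisher_2x2":
        table = np.vstack([a, b]).astype(int)
        if table.shape != (2, 2):
            raise ValueError("fisher_2x2 expects two rows of two counts")
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        return ComparisonResult("fisher_2x2", float(stat), float(p), exact=True)
    if test == "chi_square":
        table = np.vstack([a, b])
        stat, p, _, _ = stats.chi2_contingency(table)
        return ComparisonResult("chi_square", float(stat), float(p))
    raise ValueError(f"unknown test {test!r}")


@dataclass
class StratifiedSvComparison:
    per_stratum: dict[str, list[float]]
    medians: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    skipped: list[str]


def es_stratified_sv_comparison(
    table: pd.DataFrame,
    sv_column: str = "sv_total",
    stratum_column: str = "stratum",
    group_column: str = "group",
    control_group: str = "WT",
) -> StratifiedSvComparison:
    """Three-way SV-burden comparison: controls vs ES_low vs ES_high.

    Control-group samples form one stratum regardless of their enrichment
    labels; the remaining samples split by the enrichment stratum.  All
    pairwise Mann-Whitney p values are reported; strata with fewer than 2
    samples are skipped with a notice rather than tested.
    """
    strata: dict[str, list[float]] = {}
    for _, row in table.iterrows():
        if pd.isna(row[sv_column]):
            continue
        if group_column in table.columns and row[group_column] == control_group:
            label = control_group
        else:
            label = str(row[stratum_column])
        strata.setdefault(label, []).append(float(row[sv_column]))
    skipped = [k for k, v in strata.items() if len(v) < 2]
    usable = [k for k in strata if k not in skipped]
    pairwise = {}
    for i, k1 in enumerate(usable):
        for k2 in usable[i + 1:]:
            res = compare_groups(strata[k1], strata[k2], "mann_whitney")
            pairwise[(k1, k2)] = res.p_value
    medians = {k: float(np.median(v)) for k, v in strata.items() if v}
    return StratifiedSvComparison(strata, medians, pairwise, skipped)


def h_score(pct_weak: float, pct_moderate: float, pct_strong: float) -> float:
    """IHC H-score: 1*(%weak) + 2*(%moderate) + 3*(%strong), in [0, 300]."""
    for name, value in (("weak", pct_weak), ("moderate", pct_moderate),
                        ("strong", pct_strong)):
        if not 0 <= value <= 100:
            raise ValueError(f"%{name}-positive must lie in [0, 100]")
    if pct_weak + pct_moderate + pct_strong > 100 + 1e-9:
        raise ValueError("staining percentages exceed 100 in total")
    return 1.0 * pct_weak + 2.0 * pct_moderate + 3.0 * pct_strong
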
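"""Statistical comparisons for per-cell focus tables.

The comparisons mirror standard practice for cytological counts:
two-tailed Mann-Whitney U tests between genotypes, Fisher's exact test
for 2x2 cell classifications, OLS regression of focus density on
synapsis extent with an F-test on the slope, fold changes of medians,
and Western-blot band densitometry ratios. No multiple-testing
adjustment is applied anywhere.

Exact small-sample paths: the Mann-Whitney p-value is exact (full
enumeration of the U null distribution) whenever the combined sample
size is at most 12 and there are no ties, otherwise a tie- and
continuity-corrected normal approximation is used. Fisher's test is
exact (sum of hypergeometric probabilities of tables at most as
probable as the observed one) for any table size used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TwoSampleResult",
    "mann_whitney_u",
    "fisher_exact",
    "linreg_slope",
    "fold_change_of_medians",
    "densitometry_ratio",
    "EXACT_MW_MAX_N",
]

EXACT_MW_MAX_N = 12  # combined n+m at or below which the exact null is enumerated


@dataclass(frozen=True)
class TwoSampleResult:
    """Outcome of a two-sample comparison.

    ``statistic`` is the U statistic, conditional odds ratio, or OLS
    slope depending on the test; ``stderr`` is NaN where a standard
    error does not apply; ``method`` records whether the p-value came
    from an exact or an approximate null.
    """

    statistic: float
    p_value: float
    method: str  # "exact" | "approximate"
    stderr: float = float("nan")


def mann_whitney_u(x, y) -> TwoSampleResult:
    """Two-tailed Mann-Whitney U test.

    Reports U for the first sample. Exact two-tailed p by enumeration of
    the permutation null when n + m <= 12 and the pooled data has no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= EXACT_MW_MAX_N and not ties
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TwoSampleResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "approximate",
    )


def fisher_exact(table) -> TwoSampleResult:
    """Two-tailed Fisher exact test on a 2x2 table of counts.

    The two-sided p-value sums hypergeometric probabilities, over all
    tables with the observed margins, that do not exceed the observed
    table's probability. A zero row or column margin makes the table
    degenerate: p = 1 by convention, odds ratio NaN.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return TwoSampleResult(float("nan"), 1.0, "exact")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    # conditional maximum-likelihood odds ratio
    odds = float(sps.contingency.odds_ratio(t, kind="conditional").statistic)
    return TwoSampleResult(statistic=odds, p_value=float(min(p, 1.0)), method="exact")


def linreg_slope(x, y) -> TwoSampleResult:
    """OLS slope with standard error and two-tailed F-test against slope 0.

    F = (slope / SE)^2 on (1, n - 2) degrees of freedom; its p-value is
    identical to the two-tailed t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return TwoSampleResult(
        statistic=float(res.slope),
        p_value=float(res.pvalue),
        method="approximate",
        stderr=float(res.stderr),
    )


def fold_change_of_medians(x, y) -> float:
    """median(x) / median(y); NaN when the denominator median is zero."""
    mx = float(np.median(np.asarray(x, dtype=float)))
    my = float(np.median(np.asarray(y, dtype=float)))
    if my == 0:
        return float("nan")
    return mx / my


def densitometry_ratio(
    band_a: float, band_b: float, background_a: float = 0.0, background_b: float = 0.0
) -> float:
    """Lane-background-corrected band intensity ratio.

    (band_a - background_a) / (band_b - background_b); NaN when the
    corrected denominator is not positive. Used for e.g. the
    slow-to-fast migrating band ratio of a phosphorylated protein.
    """
    denom = band_b - background_b
    if denom <= 0:
        return float("nan")
    return (band_a - background_a) / denom
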
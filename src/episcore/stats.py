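"""Clinicopathological association and comparison tests: exact 2x2 tests,
two-sample t tests, the paired Wilcoxon signed-rank test, and optimal
cutpoint selection for immunohistochemistry percent-positive scores.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

from .maxstat import MaxstatResult, maxstat_cutpoint
from .survival import logrank_test

__all__ = [
    "fisher_exact_two_sided",
    "two_sample_t",
    "wilcoxon_signed_rank",
    "ihc_cutpoint",
]


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Uses the sum-of-small-probabilities rule: the p-value accumulates the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (up to a tiny
    relative tolerance for floating-point ties).  A table with an empty
    margin carries no information; by convention p = 1 with a warning.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValueError("table entries must be non-negative integers")
        table = np.round(table).astype(int)
    if table.sum() < 1:
        raise ValueError("table must contain at least one observation")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def two_sample_t(x, y, pooled: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t test; pooled-variance Student by default,
    Welch with ``pooled=False``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("both samples degenerate with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=pooled)
    return float(t), float(p)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped.  The exact null distribution is used for
    up to 25 non-zero pairs (falling back to the normal approximation when
    ties among the ranks make the exact distribution unavailable); above
    that, the normal approximation with continuity correction.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method=method)
    except ValueError:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method="approx")
    return float(res.statistic), float(res.pvalue)


def ihc_cutpoint(
    percent_positive,
    times,
    events,
    minprop: float = 0.1,
    **kwargs,
) -> tuple[MaxstatResult, float]:
    """Optimal cutpoint of a percent-positive-cells IHC score for survival.

    Reuses the maximally-selected-statistic scan on the percent scale and
    additionally reports the plain two-group log-rank p at the chosen
    cutoff (descriptive — it ignores the selection of the cutpoint).
    """
    pct = np.asarray(percent_positive, dtype=float)
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("percent-positive values must lie in [0, 100]")
    res = maxstat_cutpoint(pct, times, events, minprop=minprop, **kwargs)
    groups = (pct > res.cutpoint).astype(int)
    lr = logrank_test(times, events, groups)
    return res, lr.p_value
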
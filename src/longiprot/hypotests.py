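"""Small-sample rank and exact tests used across the pipeline.

Conventions (fixed, documented here once):

* Mann-Whitney U: exact null distribution when the combined sample size is
  <= 20 and there are no ties; otherwise normal approximation with tie
  correction and continuity correction.
* Wilcoxon signed rank: zero differences are dropped (Wilcoxon's
  convention); exact distribution on the remaining n when n <= 25 and there
  are no tied ranks; p = 1 when every difference is zero.
* Fisher's exact test: two-sided by summing tables with probability <= the
  observed table's.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value; exact for small untied samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return 1.0  # no separation at all: tie convention
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def wilcoxon_signed_p(diff) -> float:
    """Two-sided signed-rank p-value on paired differences."""
    d = np.asarray(diff, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0  # degenerate: all paired differences zero
    ranks_tied = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=True)
    return float(res.pvalue)


def fisher_exact_p(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
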
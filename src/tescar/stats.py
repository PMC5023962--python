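"""Statistical primitives: 2x2 chi-square, rank-sum test, running average.

The chi-square test is the uncorrected Pearson test on a 2x2 table,
chi2 = n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), with p from the chi2(1)
survival function.  Yates continuity correction is available by flag
but off by default; note that on small tables the two versions can
differ substantially (e.g. a 25/25 vs 15/35 split of two sets of 50
gives p ~ 0.04 uncorrected but ~ 0.07 with correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class Contingency2x2:
    """Counts: rows = (test, control), columns = (with event, without)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def chi2_2x2(t: Contingency2x2, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; returns (statistic, p).

    Raises ``ValueError`` if any row or column margin is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero margin in 2x2 table")
    n = t.n
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    Returns (U for sample ``x``, two-sided p).  Degenerate input where
    all values across both samples are identical gives U = |x||y|/2,
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("rank_sum_test requires at least 2 values per sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def running_average(series, k: int) -> np.ndarray:
    """Centered running mean with a window shrinking at the edges.

    ``k`` must be odd and no longer than the series.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return series
    if k % 2 == 0 or k < 1:
        raise ValueError("window k must be odd and positive")
    if k > series.size:
        raise ValueError("window k exceeds series length")
    half = k // 2
    out = np.empty_like(series)
    for i in range(series.size):
        lo = max(0, i - half)
        hi = min(series.size, i + half + 1)
        out[i] = series[lo:hi].mean()
    return out
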
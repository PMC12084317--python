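"""Demographic/clinical group statistics and brain-behavior correlations.

Pooled-variance two-sample t from group summaries (the form consistent
with conventional df = n1 + n2 - 2 reporting), Pearson chi-square on a
2x2 contingency table without continuity correction, and Pearson
correlation with a t-distribution p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "pooled_t_from_summary", "chi2_2x2", "pearson_with_p"]


@dataclass
class GroupSummary:
    variable: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled two-sample t (group1 - group2) from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both group variances are zero")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def chi2_2x2(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (chi2, df=1, p).
    """
    O = np.asarray(counts, dtype=float)
    if O.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if np.any(row <= 0) or np.any(col <= 0):
        raise ValueError("zero marginal in contingency table")
    E = np.outer(row, col) / O.sum()
    chi2 = float(((O - E) ** 2 / E).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, 1, p


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
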
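"""Correlation of group temporal components with stimulus regressors.

Pearson correlations between every GTC time course and every
HRF-convolved annotation/feature regressor, Benjamini-Hochberg FDR over
the whole matrix, and the flagging rule used to call a GTC
content-related: |cc| above threshold (0.35) and FDR-adjusted p below
threshold (0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationTable",
    "correlate_table",
    "bh_fdr",
    "flag_table",
    "load_reference_cc_table",
]


@dataclass
class CorrelationTable:
    cc: pd.DataFrame  # GTC x regressor Pearson r (NaN where undefined)
    p: pd.DataFrame  # two-sided p (t distribution, T-2 df)
    q: Optional[pd.DataFrame] = None  # BH-FDR adjusted
    flags: Optional[pd.DataFrame] = None


def correlate_table(
    gtcs: pd.DataFrame | np.ndarray,
    regressors: pd.DataFrame | np.ndarray,
) -> CorrelationTable:
    """Pearson r and two-sided p for every GTC x regressor pair.

    Constant columns yield NaN (undefined correlation), never zero.
    """
    G = pd.DataFrame(gtcs)
    R = pd.DataFrame(regressors)
    if len(G) != len(R):
        raise ValueError("GTCs and regressors must have equal length")
    T = len(G)
    if T < 10:
        raise ValueError("need at least 10 time points")
    cc = pd.DataFrame(index=G.columns, columns=R.columns, dtype=float)
    p = pd.DataFrame(index=G.columns, columns=R.columns, dtype=float)
    for g in G.columns:
        for r in R.columns:
            x, y = G[g].to_numpy(float), R[r].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                cc.loc[g, r] = np.nan
                p.loc[g, r] = np.nan
                continue
            res = stats.pearsonr(x, y)
            cc.loc[g, r] = res.statistic
            p.loc[g, r] = res.pvalue
    return CorrelationTable(cc=cc, p=p)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone enforced).

    NaN entries (undefined tests) are excluded from the family and
    returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    valid = ~np.isnan(flat)
    if np.any((flat[valid] < 0) | (flat[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(flat, np.nan)
    if valid.sum():
        q[valid] = multipletests(flat[valid], method="fdr_bh")[1]
    return q.reshape(p.shape)


def flag_table(
    table: CorrelationTable,
    cc_thresh: float = 0.35,
    q_thresh: float = 0.05,
    use_q: bool = True,
) -> CorrelationTable:
    """Apply the significance rule: |cc| > cc_thresh and q < q_thresh.

    With ``use_q=False`` (e.g. when only a cc matrix is available) the
    rule reduces to the |cc| threshold alone.  The per-GTC summary
    (which GTCs have at least one flag) is in :func:`flag_summary`.
    """
    q = pd.DataFrame(
        bh_fdr(table.p.to_numpy()), index=table.p.index, columns=table.p.columns
    ) if use_q else None
    flags = table.cc.abs() > cc_thresh
    if use_q:
        flags &= q < q_thresh
    flags &= table.cc.notna()
    return CorrelationTable(cc=table.cc, p=table.p, q=q, flags=flags)


def flag_summary(flags: pd.DataFrame) -> dict:
    """Which GTCs carry at least one flagged correlation, and how many."""
    any_flag = flags.any(axis=1)
    flagged = [idx for idx, val in any_flag.items() if val]
    return {"flagged_gtcs": flagged, "n_flagged": len(flagged), "n_total": len(flags)}


def load_reference_cc_table() -> pd.DataFrame:
    """Published reference correlation table (15 GTCs x 8 codings).

    Regression fixture for the flagging rule; rows are indexed by GTC
    number, the first column is the component's explained variance.
    """
    with resources.files("metica.data").joinpath("reference_cc_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("gtc")
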
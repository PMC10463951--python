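"""Volcano-style two-group screening of a lipid feature table.

Input is a samples x species table of pre-quantified area ratios (analyte
peak area over its lipid-class internal standard, AUC/IS).  Per species the
screen reports the log2 fold change of group means, the two-sided t-test
p-value (computed on log2-transformed intensities by default, the
lipidomics convention), and the BH-FDR q-value.  Positive log2 fold change
means higher in the test group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = ["volcano_table", "range_norm_for_plots"]


def volcano_table(
    table: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-species volcano rows: log2_fc, p, q, -log10 p.

    ``groups`` labels each sample (row) with exactly two distinct values;
    ``reference`` names the denominator group.  With ``log_transform`` the
    t-test runs on log2 intensities (requires strictly positive values) and
    log2_fc is the difference of group mean log2 values; otherwise the test
    runs on raw intensities and log2_fc is log2 of the ratio of raw means.
    """
    groups = pd.Series(groups)
    labels = groups.unique()
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among groups {list(labels)}")
    test = [g for g in labels if g != reference][0]
    values = table.to_numpy(dtype=float)
    if log_transform:
        if np.any(values <= 0):
            raise ValueError("non-positive intensities cannot be log-transformed")
        values = np.log2(values)
    mask_ref = (groups == reference).to_numpy()
    mask_test = (groups == test).to_numpy()
    if mask_ref.sum() < 2 or mask_test.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    res = sps.ttest_ind(values[mask_test], values[mask_ref], axis=0)
    if log_transform:
        log2_fc = values[mask_test].mean(axis=0) - values[mask_ref].mean(axis=0)
    else:
        log2_fc = np.log2(
            values[mask_test].mean(axis=0) / values[mask_ref].mean(axis=0)
        )
    p = np.asarray(res.pvalue, dtype=float)
    q = bh_fdr(p)
    with np.errstate(divide="ignore"):  # p == 0 on degenerate exact shifts
        neg_log10_p = -np.log10(p)
    return pd.DataFrame(
        {
            "species": table.columns,
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "neg_log10_p": neg_log10_p,
        }
    )


def range_norm_for_plots(values) -> np.ndarray:
    """Scale a vector to [0, 1]: (x - min)/(max - min).

    Used for per-species scatter insets; constant vectors are an error.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi <= lo:
        raise ValueError("cannot range-normalize a constant vector")
    return (x - lo) / (hi - lo)
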
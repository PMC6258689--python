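"""Dual-luciferase reporter statistics.

Renilla-normalized luminescence (RNL = firefly / renilla), the two fold-change
views used for transactivation assays (with vs without transcription factor on
the same promoter, and with vs without promoter insert under the same factor),
and two-sample significance testing of RNL values (Welch t-test by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

NO_TF = "-"


def compute_rnl(table: pd.DataFrame) -> pd.DataFrame:
    """Add (or recompute) the rnl column as firefly / renilla.

    The ratio is always recomputed, never trusted from the input.
    """
    bad = table.index[table["renilla"] <= 0]
    if len(bad):
        raise ValueError(f"renilla must be positive (row {bad[0]})")
    out = table.copy()
    out["rnl"] = out["firefly"] / out["renilla"]
    return out


def _batch_means(table: pd.DataFrame, tf: str, promoter: str) -> pd.Series:
    sub = table[(table["tf"] == tf) & (table["promoter"] == promoter)]
    return sub.groupby("batch")["rnl"].mean()


def _summarize(ratios: pd.Series, method: str) -> float:
    if method == "mean":
        return float(ratios.mean())
    if method == "geometric":
        return float(np.exp(np.log(ratios).mean()))
    raise ValueError("method must be 'mean' or 'geometric'")


def fold_change_tf(
    table: pd.DataFrame, tf: str, promoter: str, ref_tf: str = NO_TF, method: str = "mean"
):
    """RNL fold change of with-TF over without-TF on the same promoter.

    Ratios are formed per batch and then summarized (arithmetic mean by
    default, geometric by flag).  Returns (fold, per_batch_ratios).
    """
    table = compute_rnl(table)
    num = _batch_means(table, tf, promoter)
    den = _batch_means(table, ref_tf, promoter)
    batches = num.index.intersection(den.index)
    if len(batches) == 0:
        raise ValueError(f"no common batches for tf={tf!r} on promoter={promoter!r}")
    ratios = num[batches] / den[batches]
    return _summarize(ratios, method), ratios


def fold_change_promoter(
    table: pd.DataFrame, tf: str, promoter: str, ref_promoter: str = "plain", method: str = "mean"
):
    """RNL fold change of insert-bearing over empty promoter under the same TF."""
    table = compute_rnl(table)
    num = _batch_means(table, tf, promoter)
    den = _batch_means(table, tf, ref_promoter)
    batches = num.index.intersection(den.index)
    if len(batches) == 0:
        raise ValueError(f"no common batches for promoter={promoter!r} under tf={tf!r}")
    ratios = num[batches] / den[batches]
    return _summarize(ratios, method), ratios


def significance_test(
    group: np.ndarray, reference: np.ndarray, alpha: float = 0.05,
    equal_var: bool = False, paired: bool = False,
):
    """Two-sided t-test of RNL values against a reference condition.

    Welch's unequal-variance test by default; Student's pooled test with
    ``equal_var=True``; ``paired=True`` pairs values by position (batch).
    Returns (p_value, significant_at_alpha).
    """
    group = np.asarray(group, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if group.size < 2 or reference.size < 2:
        raise ValueError("need at least two values per group")
    if paired:
        if group.size != reference.size:
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(group, reference)
    else:
        res = stats.ttest_ind(group, reference, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # identical constant groups
        p = 1.0
    return p, p < alpha
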
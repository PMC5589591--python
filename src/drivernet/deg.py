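"""X-vs-Y differential-expression screen and dual-feature gene selection.

Per gene: log2 fold change = mean over X samples minus mean over Y samples
(values are log2 intensities), and a two-sided Welch t-test p-value.  A gene
passes with p < 0.05 and |log2FC| > 0.585 (fold change 1.5) by default; the
passing set intersected with the consensus-module genes gives the
dual-feature genes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionError, ExpressionMatrix

logger = logging.getLogger(__name__)

#: |log2 fold change| cutoff corresponding to a 1.5-fold change
FC_LOG2_THRESHOLD = 0.585
P_THRESHOLD = 0.05


class GroupSizeError(ExpressionError):
    """Raised when a group has too few samples for a t-test."""


def _group_arrays(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    for g in ("X", "Y"):
        if not m.samples_in_group(g):
            raise ExpressionError(f"no samples labeled group {g}")
    x = m.values[m.samples_in_group("X")].to_numpy(dtype=float)
    y = m.values[m.samples_in_group("Y")].to_numpy(dtype=float)
    return x, y


def log2_fold_change(m: ExpressionMatrix) -> pd.Series:
    """Per-gene log2FC = mean(X samples) - mean(Y samples)."""
    if not m.log2_transformed:
        raise ExpressionError("matrix must be log2-transformed for log2FC")
    x, y = _group_arrays(m)
    fc = x.mean(axis=1) - y.mean(axis=1)
    return pd.Series(fc, index=m.values.index, name="log2_fc")


def welch_t(m: ExpressionMatrix) -> pd.Series:
    """Two-sided Welch t-test p-value per gene.

    Requires at least two samples per group.  Genes with zero pooled
    variance (all values equal within each group) get p = 1 with a warning.
    """
    x, y = _group_arrays(m)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise GroupSizeError(
            f"Welch t-test needs >=2 samples per group (got {x.shape[1]} X, {y.shape[1]} Y); "
            "use fold-change-only screening"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} genes with zero pooled variance; p set to 1")
        p[degenerate] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    return pd.Series(p, index=m.values.index, name="p_value")


def screen_degs(
    fc: pd.Series,
    p: pd.Series | None,
    fc_log2_thresh: float = FC_LOG2_THRESHOLD,
    p_thresh: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Apply the strict DEG thresholds; returns the full per-gene table.

    Columns: log2_fc, p_value (NaN in fold-change-only mode), direction
    (up iff log2_fc > 0), passes.  Both inequalities are strict.
    """
    if p is not None and not fc.index.equals(p.index):
        if set(fc.index) != set(p.index):
            raise ValueError("fc and p indexed by different genes")
        p = p.reindex(fc.index)
    table = pd.DataFrame({"log2_fc": fc})
    if p is None:
        logger.warning("FOLD-CHANGE-ONLY MODE: no p-values; passes uses |log2FC| alone")
        table["p_value"] = np.nan
        table["passes"] = table.log2_fc.abs() > fc_log2_thresh
    else:
        table["p_value"] = p
        table["passes"] = (table.p_value < p_thresh) & (table.log2_fc.abs() > fc_log2_thresh)
    table["direction"] = np.where(table.log2_fc > 0, "up", "down")
    n_up = int((table.passes & (table.direction == "up")).sum())
    n_down = int((table.passes & (table.direction == "down")).sum())
    logger.info("DEG screen: %d pass (%d up, %d down)", n_up + n_down, n_up, n_down)
    return table[["log2_fc", "p_value", "direction", "passes"]].rename_axis("gene")


def deg_table(
    m: ExpressionMatrix,
    fc_log2_thresh: float = FC_LOG2_THRESHOLD,
    p_thresh: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Full screen on one matrix; falls back to fold-change-only mode when a
    group has fewer than two samples."""
    fc = log2_fold_change(m)
    try:
        p = welch_t(m)
    except GroupSizeError as exc:
        logger.warning("%s", exc)
        p = None
    return screen_degs(fc, p, fc_log2_thresh=fc_log2_thresh, p_thresh=p_thresh)


def dual_feature_genes(
    degs: pd.DataFrame, consensus_gene_ids: Iterable[str]
) -> list[str]:
    """Genes that both pass the DEG screen and sit in a significant
    consensus-module overlap; stable gene-ID order."""
    passing = set(degs.index[degs["passes"]])
    return sorted(passing & set(consensus_gene_ids))


def volcano_data(degs: pd.DataFrame) -> pd.DataFrame:
    """log2FC and -log10 p table for external volcano plotting."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(degs["p_value"])
    return pd.DataFrame({"log2_fc": degs["log2_fc"], "neg_log10_p": neglog}).rename_axis("gene")
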
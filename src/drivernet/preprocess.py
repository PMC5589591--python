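"""Normalization and cross-species homolog intersection.

Both species' arrays are quantile-normalized on log2 intensities so that the
per-array value distributions are identical, then the two gene universes are
intersected through a 1:1 homolog mapping table.  Downstream module detection
runs on the shared-gene matrices only.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .expression import ExpressionError, ExpressionMatrix

logger = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    Every column is mapped onto the vector of row-wise means of the
    column-sorted matrix, so all columns share one value multiset while the
    within-column rank order is preserved.  Ties receive the mean of the
    target values over the tied ranks.

    A single-sample matrix is returned unchanged with a warning (there is
    nothing to normalize between).
    """
    X = m.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single-sample matrix returned unchanged")
        return m
    targets = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = targets
        # average target values over ties within the column
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`quantile_normalize`.

    ``fit`` records the target quantile vector (row means of the
    column-sorted training matrix); ``transform`` maps each column of the
    input onto it.  With ``X`` = the same matrix used in ``fit`` this equals
    :func:`quantile_normalize`.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D genes x samples array")
        self.n_features_in_ = X.shape[1]
        self.target_quantiles_ = np.sort(X, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "target_quantiles_")
        X = np.asarray(X, dtype=float)
        targets = self.target_quantiles_
        if X.shape[0] != targets.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows, fitted on {targets.shape[0]}"
            )
        out = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            col = X[:, j]
            order = np.argsort(col, kind="stable")
            assigned = np.empty(len(col))
            assigned[order] = targets
            out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
        return out


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); refuses to run twice."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if m.log2_transformed:
        raise ExpressionError("matrix is already log2-transformed")
    shifted = m.values + offset
    bad = shifted.index[(shifted <= 0).any(axis=1)]
    if len(bad):
        raise ExpressionError(
            f"nonpositive value with offset {offset} in genes: {list(bad[:5])}"
        )
    return m.with_values(np.log2(shifted), log2_transformed=True)


def intersect_homologs(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    homolog_map: pd.DataFrame,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Restrict both matrices to 1:1 homolog pairs present in both.

    ``homolog_map`` is a two-column table (species-A gene, species-B gene).
    Pairs referencing genes absent from either matrix are dropped with a
    logged count.  Both returned matrices are row-ordered by the shared ID
    (the species-A gene name, which also relabels the species-B rows so the
    two matrices live in one namespace).
    """
    if homolog_map.shape[1] < 2:
        raise ValueError("homolog map needs two columns")
    pairs = homolog_map.iloc[:, :2].astype(str)
    in_a = pairs.iloc[:, 0].isin(a.values.index)
    in_b = pairs.iloc[:, 1].isin(b.values.index)
    kept = pairs[in_a & in_b]
    n_dropped = len(pairs) - len(kept)
    if n_dropped:
        logger.warning("intersect_homologs: dropped %d unmatched homolog pairs", n_dropped)
    if kept.empty:
        raise ExpressionError("homolog intersection is empty")
    kept = kept.drop_duplicates(subset=kept.columns[0]).drop_duplicates(subset=kept.columns[1])
    shared_ids = list(kept.iloc[:, 0])
    a_out = a.subset_genes(shared_ids)
    b_vals = b.values.loc[list(kept.iloc[:, 1])].copy()
    b_vals.index = shared_ids
    b_out = b.with_values(b_vals)
    return a_out, b_out, shared_ids


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column homolog TSV with header ``species_a<TAB>species_b``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: homolog map must have two columns")
    return df


def write_homolog_map(df: pd.DataFrame, path: str | Path) -> None:
    out = df.iloc[:, :2].copy()
    out.columns = ["species_a", "species_b"]
    out.to_csv(path, sep="\t", index=False)
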
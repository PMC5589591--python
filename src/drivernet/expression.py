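"""Gene-by-sample expression container with group labels.

The pipeline works on log2-scale intensity matrices with genes in rows and
arrays (samples) in columns.  Each sample carries a group label — here the
two groups are the X- and Y-chromosome-bearing sperm libraries — which drives
the differential-expression screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("X", "Y")


class ExpressionError(ValueError):
    """Raised when an expression matrix violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with sample group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression intensities, index = gene IDs, columns = sample IDs.
    groups : pandas.Series
        Maps sample ID -> group label (``"X"`` or ``"Y"``).  May be empty for
        matrices where the grouping is irrelevant (e.g. a single species'
        module detection input).
    log2_transformed : bool
        Whether the values are already on log2 scale.  Guards against a
        double transform.
    """

    values: pd.DataFrame
    groups: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    log2_transformed: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(f"duplicate gene IDs: {list(dup[:5])}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise ExpressionError(f"duplicate sample IDs: {list(dup[:5])}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)]
            raise ExpressionError(f"missing values in genes: {list(bad[:5])}")
        if len(self.groups):
            unknown = set(self.groups.index) - set(self.values.columns)
            if unknown:
                raise ExpressionError(f"group labels for unknown samples: {sorted(unknown)[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if not len(self.groups):
            raise ExpressionError("matrix has no group labels")
        return [s for s in self.sample_ids if self.groups.get(s) == group]

    def with_values(self, values: pd.DataFrame, **changes) -> "ExpressionMatrix":
        """Return a copy with new values (and optional flag changes)."""
        groups = self.groups[self.groups.index.isin(values.columns)]
        return replace(self, values=values, groups=groups, **changes)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ExpressionError(f"genes absent from matrix: {missing[:5]}")
        return self.with_values(self.values.loc[genes])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path, groups_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the group table) as TSV."""
        self.values.to_csv(path, sep="\t", index_label="gene")
        if groups_path is not None:
            self.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        groups: str | Path | Mapping[str, str] | None = None,
        log2_transformed: bool = True,
    ) -> "ExpressionMatrix":
        """Read a genes-in-rows TSV; collapse duplicate gene IDs.

        Duplicate gene IDs (e.g. multiple probes per gene) are collapsed by
        keeping the row with the highest mean intensity.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            n_before = len(df)
            order = df.mean(axis=1).to_numpy()
            df = df.iloc[np.argsort(-order, kind="stable")]
            df = df[~df.index.duplicated(keep="first")]
            logger.warning(
                "collapsed %d duplicate gene rows (kept highest mean intensity)",
                n_before - len(df),
            )
        if groups is None:
            grp = pd.Series(dtype=object)
        elif isinstance(groups, Mapping):
            grp = pd.Series(dict(groups))
        else:
            grp = pd.read_csv(groups, sep="\t", index_col=0).iloc[:, 0]
        return cls(values=df, groups=grp, log2_transformed=log2_transformed)
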
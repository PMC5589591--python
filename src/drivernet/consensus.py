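"""Consensus-module cross-tabulation between two species.

Module assignments from the two datasets (over the same shared-homolog gene
universe) are cross-tabulated; each module pair's overlap is tested for
enrichment with a one-sided hypergeometric upper tail.  Pairs significant at
``alpha`` contribute their overlapping genes to the consensus gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .wgcna import UNASSIGNED, ModuleAssignment

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    N is the universe size, K the number of marked items, n the draw size and
    k the observed overlap.  Returns a p-value in (0, 1].
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible configuration N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(K, n) + 1)
    log_terms = hypergeom.logpmf(ks, N, K, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


@dataclass
class ConsensusOverlapTable:
    """Per module-pair overlap counts and enrichment p-values.

    ``table`` has one row per (module_a, module_b) pair with columns
    module_a, module_b, size_a, size_b, overlap, p_value, adjusted_p and
    overlap_genes (list, possibly empty when built from bare counts).
    ``count_matrix`` and ``neglog2p`` are module_a x module_b matrices of
    overlap counts and -log2(p) for heatmap export.
    """

    table: pd.DataFrame
    universe_size: int
    count_matrix: pd.DataFrame | None = None
    neglog2p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            bad = t[t.overlap > np.minimum(t.size_a, t.size_b)]
            if len(bad):
                raise ValueError("overlap exceeds min(size_a, size_b)")
        if "adjusted_p" not in t.columns and len(t):
            self.table = t.assign(
                adjusted_p=multipletests(t.p_value, method="fdr_bh")[1]
            )
        if "overlap_genes" not in self.table.columns:
            self.table = self.table.assign(
                overlap_genes=[[] for _ in range(len(self.table))]
            )

    @classmethod
    def from_counts(
        cls,
        rows: Sequence[tuple],
        universe_size: int,
        p_values: Sequence[float] | None = None,
    ) -> "ConsensusOverlapTable":
        """Build a table from bare (module_a, module_b, size_a, size_b,
        overlap) tuples, computing hypergeometric p-values unless explicit
        ``p_values`` are supplied (e.g. when replaying a published table)."""
        df = pd.DataFrame(
            rows, columns=["module_a", "module_b", "size_a", "size_b", "overlap"]
        )
        if p_values is None:
            df["p_value"] = [
                hypergeom_upper_tail(universe_size, r.size_a, r.size_b, r.overlap)
                for r in df.itertuples()
            ]
        else:
            if len(p_values) != len(df):
                raise ValueError("p_values length mismatch")
            df["p_value"] = list(p_values)
        return cls(table=df, universe_size=universe_size)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["overlap_genes"] = [",".join(g) for g in out["overlap_genes"]]
        out.to_csv(path, sep="\t", index=False)


def overlap_table(
    a: ModuleAssignment,
    b: ModuleAssignment,
    universe: str = "all",
) -> ConsensusOverlapTable:
    """Cross-tabulate two module assignments over the same gene universe.

    ``universe="all"`` counts every shared gene (including unassigned ones)
    in the hypergeometric universe N; ``"assigned-only"`` restricts N to
    genes assigned to a module in both species.  Unassigned genes never form
    module pairs.
    """
    genes_a, genes_b = set(a.gene_ids), set(b.gene_ids)
    if genes_a != genes_b:
        raise ValueError(
            f"assignments cover different universes "
            f"(symmetric difference of {len(genes_a ^ genes_b)} genes)"
        )
    if universe not in ("all", "assigned-only"):
        raise ValueError("universe must be 'all' or 'assigned-only'")
    genes = a.gene_ids
    la = a.labels.reindex(genes)
    lb = b.labels.reindex(genes)
    if universe == "all":
        N = len(genes)
    else:
        N = int(((la != UNASSIGNED) & (lb != UNASSIGNED)).sum())

    mods_a = a.module_names
    mods_b = b.module_names
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b, dtype=int)
    members_a = {m: set(a.members(m)) for m in mods_a}
    members_b = {m: set(b.members(m)) for m in mods_b}
    rows = []
    neglog = pd.DataFrame(0.0, index=mods_a, columns=mods_b)
    for ma in mods_a:
        for mb in mods_b:
            ov = sorted(members_a[ma] & members_b[mb])
            counts.loc[ma, mb] = len(ov)
            if not ov:
                continue
            p = hypergeom_upper_tail(N, len(members_a[ma]), len(members_b[mb]), len(ov))
            neglog.loc[ma, mb] = -np.log2(p)
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "size_a": len(members_a[ma]),
                    "size_b": len(members_b[mb]),
                    "overlap": len(ov),
                    "p_value": p,
                    "overlap_genes": ov,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["module_a", "module_b", "size_a", "size_b", "overlap", "p_value", "overlap_genes"],
    )
    return ConsensusOverlapTable(
        table=table, universe_size=N, count_matrix=counts, neglog2p=neglog
    )


def collect_consensus_genes(
    t: ConsensusOverlapTable, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str], int]:
    """Select significant module pairs and collect their overlap genes.

    Returns (selected pairs, de-duplicated union of overlap gene IDs, and the
    multiset total of per-pair overlap counts).  The multiset total may
    double-count genes that overlap in several pairs; both numbers are
    reported.
    """
    if t.table.empty:
        raise ValueError("overlap table is empty")
    sel = t.table[t.table.p_value < alpha].copy()
    if sel.empty:
        logger.warning("no module pair significant at alpha=%g", alpha)
    total = int(sel["overlap"].sum())
    union: set[str] = set()
    for genes in sel["overlap_genes"]:
        union.update(genes)
    return sel, sorted(union), total
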
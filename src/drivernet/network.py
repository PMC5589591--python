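"""Thresholded signed co-expression network on a selected gene list.

Pairwise signed Pearson correlations over all samples; pairs with
|r| >= threshold become edges (positive or negative by the sign of r), and
genes left without any retained edge are dropped from the node set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionError, ExpressionMatrix

EXPORT_FORMATS = ("sif", "graphml", "tsv")


@dataclass
class GeneNetwork:
    """Signed co-expression graph: nodes carry a regulation direction,
    edges carry the correlation r and its sign."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_i": min(u, v), "gene_j": max(u, v), "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "sign"]).sort_values(
            ["gene_i", "gene_j"], ignore_index=True
        )

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"gene": n, "direction": d.get("direction", ""), "degree": self.graph.degree[n]}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "degree"])


def build_network(
    m: ExpressionMatrix,
    genes: Iterable[str],
    deg_direction: Mapping[str, str] | None = None,
    r_thresh: float = 0.8,
) -> GeneNetwork:
    """Correlation network over ``genes`` keeping edges with |r| >= r_thresh.

    Genes with no retained edge are dropped (the node set can be smaller
    than the input list).  ``deg_direction`` maps gene -> "up"/"down" as
    produced by the DEG screen.
    """
    genes = list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build a network")
    sub = m.subset_genes(genes)
    if sub.n_samples < 3:
        raise ExpressionError("need at least 3 samples for correlations")
    X = sub.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    R = np.corrcoef(X)
    g = nx.Graph()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = float(R[i, j])
            if abs(r) >= r_thresh:
                g.add_edge(
                    genes[i], genes[j], r=r, sign="positive" if r >= 0 else "negative"
                )
    direction = deg_direction or {}
    for n in g.nodes:
        g.nodes[n]["direction"] = direction.get(n, "")
    return GeneNetwork(graph=g, threshold=r_thresh)


def export_network(net: GeneNetwork, fmt: str, out_prefix: str | Path) -> list[Path]:
    """Write the network as SIF, GraphML or edge TSV.

    SIF uses interaction types ``pos``/``neg`` and is accompanied by a node
    attribute TSV; GraphML carries node ``direction`` and edge ``r``/``sign``
    attributes.  Returns the written paths.
    """
    if net.n_edges == 0:
        raise ValueError("refusing to export an empty network")
    fmt = fmt.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "sif":
        path = out_prefix.with_suffix(".sif")
        edges = net.edge_table()
        with open(path, "w") as fh:
            for row in edges.itertuples():
                kind = "pos" if row.sign == "positive" else "neg"
                fh.write(f"{row.gene_i}\t{kind}\t{row.gene_j}\n")
        written.append(path)
        attr_path = out_prefix.parent / (out_prefix.name + ".nodes.tsv")
        net.node_table().to_csv(attr_path, sep="\t", index=False)
        written.append(attr_path)
    elif fmt == "graphml":
        path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(net.graph, path)
        written.append(path)
    else:
        path = out_prefix.with_suffix(".edges.tsv")
        net.edge_table().to_csv(path, sep="\t", index=False)
        written.append(path)
        attr_path = out_prefix.parent / (out_prefix.name + ".nodes.tsv")
        net.node_table().to_csv(attr_path, sep="\t", index=False)
        written.append(attr_path)
    return written


def read_graphml(path: str | Path) -> GeneNetwork:
    """Re-read a GraphML export (round-trip helper)."""
    g = nx.read_graphml(path)
    thresh = min((abs(d["r"]) for _, _, d in g.edges(data=True)), default=0.0)
    return GeneNetwork(graph=nx.Graph(g), threshold=thresh)
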
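"""Over-representation analysis against user-supplied term sets.

A generic hypergeometric ORA: the query gene list is tested against every
term of a GMT-style annotation collection within a stated gene universe.
Stands in for GO/KEGG/TFBS/miRNA-target lookups — the statistics are the
same, only the term source differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .consensus import hypergeom_upper_tail

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Term ID -> (description, member gene IDs)."""

    terms: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no member genes")
            if len(set(genes)) != len(genes):
                self.terms[term] = (self.terms[term][0], tuple(dict.fromkeys(genes)))

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term: str) -> tuple[str, ...]:
        return self.terms[term][1]


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: term, description, then tab-separated gene IDs."""
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term ID {term!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            terms[term] = (desc, tuple(dict.fromkeys(genes)))
    return AnnotationCollection(terms=terms)


def write_gmt(coll: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in coll.terms.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    coll: AnnotationCollection,
    p_thresh: float = 0.05,
    min_count: int = 2,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Per term with members intersected with the universe: k = |query & term|,
    p = upper-tail hypergeometric with N = |universe|, K = |term & universe|,
    n = |query|.  Rows with p < p_thresh and k >= min_count are returned,
    sorted by p; a Benjamini-Hochberg adjusted column (computed across all
    tested terms) is included.  ``ease`` applies the conservative EASE-score
    variant which tests k - 1 instead of k.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        logger.warning("ora: dropped %d query genes outside the universe", len(outside))
        query_set &= universe_set
    N, n = len(universe_set), len(query_set)
    rows = []
    for term, (desc, genes) in coll.terms.items():
        members = set(genes) & universe_set
        if not members:
            continue
        hits = sorted(query_set & members)
        k = len(hits)
        if k == 0:
            continue
        k_test = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(N, len(members), n, k_test) if k_test > 0 else 1.0
        rows.append(
            {
                "term": term,
                "description": desc,
                "count": k,
                "p_value": p,
                "genes": hits,
            }
        )
    table = pd.DataFrame(rows, columns=["term", "description", "count", "p_value", "genes"])
    if len(table):
        table["adjusted_p"] = multipletests(table.p_value, method="fdr_bh")[1]
        table = table[(table.p_value < p_thresh) & (table["count"] >= min_count)]
        table = table.sort_values("p_value", ignore_index=True)
    else:
        table["adjusted_p"] = []
    return table[["term", "description", "count", "p_value", "adjusted_p", "genes"]]


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["genes"] = [",".join(g) for g in out["genes"]]
    out.to_csv(path, sep="\t", index=False)
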
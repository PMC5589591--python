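"""End-to-end orchestration of the consensus co-expression analysis.

Stages: quantile normalization -> homolog intersection -> module detection
in each species -> consensus overlap testing -> X-vs-Y DEG screen ->
dual-feature gene selection -> thresholded co-expression network ->
optional term-set enrichment.  Every stage count is recorded in a manifest
so headline numbers (shared genes, modules per species, significant pairs,
consensus total, DEGs, dual-feature genes, network nodes/edges) map onto
one dictionary.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ConsensusOverlapTable, collect_consensus_genes, overlap_table
from .deg import FC_LOG2_THRESHOLD, P_THRESHOLD, deg_table, dual_feature_genes
from .enrichment import AnnotationCollection, read_gmt, write_enrichment
from .expression import ExpressionMatrix
from .network import GeneNetwork, build_network, export_network
from .preprocess import intersect_homologs, quantile_normalize, read_homolog_map
from .wgcna import DEFAULT_POWERS, detect_modules

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths plus all stage parameters (defaults follow the study
    protocol: candidate powers 1..20 at r2 cutoff 0.9, dendrogram cut 0.9,
    minimum module size 30, overlap alpha 0.05, fold change 1.5 with p 0.05,
    network threshold |r| >= 0.8)."""

    expr_a: str
    expr_b: str
    homologs: str
    out_dir: str
    groups_a: str | None = None
    groups_b: str | None = None
    gmt: str | None = None
    quantile: bool = True
    powers: Sequence[int] = DEFAULT_POWERS
    r2_cutoff: float = 0.9
    cut_height: float = 0.9
    min_module_size: int = 30
    alpha: float = 0.05
    fc_log2_thresh: float = FC_LOG2_THRESHOLD
    p_thresh: float = P_THRESHOLD
    r_thresh: float = 0.8
    universe: str = "all"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for p in (cfg.expr_a, cfg.expr_b, cfg.homologs):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


@dataclass
class PipelineResult:
    """In-memory results of one run plus the manifest of stage counts."""

    shared_a: ExpressionMatrix
    shared_b: ExpressionMatrix
    modules_a: object
    modules_b: object
    beta_a: int
    beta_b: int
    fit_a: pd.DataFrame
    fit_b: pd.DataFrame
    overlaps: ConsensusOverlapTable
    selected_pairs: pd.DataFrame
    consensus_genes: list[str]
    consensus_total: int
    degs: pd.DataFrame
    dual_genes: list[str]
    network: GeneNetwork | None
    enrichment: pd.DataFrame | None
    manifest: dict


def run_analysis(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    homolog_map: pd.DataFrame,
    annotations: AnnotationCollection | None = None,
    quantile: bool = True,
    powers: Sequence[int] = DEFAULT_POWERS,
    r2_cutoff: float = 0.9,
    cut_height: float = 0.9,
    min_module_size: int = 30,
    alpha: float = 0.05,
    fc_log2_thresh: float = FC_LOG2_THRESHOLD,
    p_thresh: float = P_THRESHOLD,
    r_thresh: float = 0.8,
    universe: str = "all",
    seed: int = 0,
) -> PipelineResult:
    """Run the full in-memory analysis chain on two expression matrices.

    The DEG screen runs on the full species-A matrix (the paper's training
    dataset role); module detection runs on the shared-homolog matrices of
    both species.
    """
    if quantile:
        a = quantile_normalize(a)
        b = quantile_normalize(b)
    shared_a, shared_b, shared_ids = intersect_homologs(a, b, homolog_map)

    assign_a, beta_a, fit_a = detect_modules(
        shared_a, powers=powers, r2_cutoff=r2_cutoff,
        cut_height=cut_height, min_module_size=min_module_size,
    )
    assign_b, beta_b, fit_b = detect_modules(
        shared_b, powers=powers, r2_cutoff=r2_cutoff,
        cut_height=cut_height, min_module_size=min_module_size,
    )

    overlaps = overlap_table(assign_a, assign_b, universe=universe)
    if overlaps.table.empty:
        selected = overlaps.table
        consensus_genes: list[str] = []
        consensus_total = 0
    else:
        selected, consensus_genes, consensus_total = collect_consensus_genes(
            overlaps, alpha=alpha
        )

    degs = deg_table(a, fc_log2_thresh=fc_log2_thresh, p_thresh=p_thresh)
    dual = dual_feature_genes(degs, consensus_genes)

    net = None
    if len(dual) >= 2:
        direction = degs.loc[dual, "direction"].to_dict()
        net = build_network(a, dual, deg_direction=direction, r_thresh=r_thresh)

    enr = None
    if annotations is not None and dual:
        from .enrichment import ora

        enr = ora(dual, a.gene_ids, annotations, p_thresh=p_thresh)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "parameters": {
            "quantile": quantile,
            "powers": list(powers),
            "r2_cutoff": r2_cutoff,
            "cut_height": cut_height,
            "min_module_size": min_module_size,
            "alpha": alpha,
            "fc_log2_thresh": fc_log2_thresh,
            "p_thresh": p_thresh,
            "r_thresh": r_thresh,
            "universe": universe,
            "beta_a": beta_a,
            "beta_b": beta_b,
        },
        "counts": {
            "genes_a": a.n_genes,
            "genes_b": b.n_genes,
            "shared_genes": len(shared_ids),
            "modules_a": assign_a.n_modules,
            "modules_b": assign_b.n_modules,
            "significant_pairs": int(len(selected)),
            "consensus_total_overlap": consensus_total,
            "consensus_union": len(consensus_genes),
            "degs": int(degs["passes"].sum()),
            "degs_up": int((degs["passes"] & (degs["direction"] == "up")).sum()),
            "degs_down": int((degs["passes"] & (degs["direction"] == "down")).sum()),
            "dual_feature_genes": len(dual),
            "network_nodes": net.n_nodes if net else 0,
            "network_edges": net.n_edges if net else 0,
            "enriched_terms": int(len(enr)) if enr is not None else None,
        },
    }
    return PipelineResult(
        shared_a=shared_a,
        shared_b=shared_b,
        modules_a=assign_a,
        modules_b=assign_b,
        beta_a=beta_a,
        beta_b=beta_b,
        fit_a=fit_a,
        fit_b=fit_b,
        overlaps=overlaps,
        selected_pairs=selected,
        consensus_genes=consensus_genes,
        consensus_total=consensus_total,
        degs=degs,
        dual_genes=dual,
        network=net,
        enrichment=enr,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based wrapper around :func:`run_analysis`.

    Reads the configured inputs, writes every intermediate artifact under
    ``out_dir`` and returns the manifest (also written as
    ``manifest.json``).  The manifest is reproducible for identical inputs
    apart from its ``created`` timestamp.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a = ExpressionMatrix.from_tsv(config.expr_a, groups=config.groups_a)
    b = ExpressionMatrix.from_tsv(config.expr_b, groups=config.groups_b)
    homologs = read_homolog_map(config.homologs)
    annotations = read_gmt(config.gmt) if config.gmt else None

    stage = "analysis"
    try:
        res = run_analysis(
            a,
            b,
            homologs,
            annotations=annotations,
            quantile=config.quantile,
            powers=config.powers,
            r2_cutoff=config.r2_cutoff,
            cut_height=config.cut_height,
            min_module_size=config.min_module_size,
            alpha=config.alpha,
            fc_log2_thresh=config.fc_log2_thresh,
            p_thresh=config.p_thresh,
            r_thresh=config.r_thresh,
            universe=config.universe,
            seed=config.seed,
        )
        stage = "artifact export"
        res.shared_a.to_tsv(out / "shared_a.tsv")
        res.shared_b.to_tsv(out / "shared_b.tsv")
        res.modules_a.to_tsv(out / "modules_a.tsv")
        res.modules_b.to_tsv(out / "modules_b.tsv")
        res.fit_a.to_csv(out / "power_fit_a.tsv", sep="\t", index=False)
        res.fit_b.to_csv(out / "power_fit_b.tsv", sep="\t", index=False)
        res.overlaps.to_tsv(out / "overlap_table.tsv")
        if res.overlaps.count_matrix is not None:
            res.overlaps.count_matrix.to_csv(out / "overlap_counts.tsv", sep="\t")
            res.overlaps.neglog2p.to_csv(out / "overlap_neglog2p.tsv", sep="\t")
        res.degs.to_csv(out / "deg_table.tsv", sep="\t")
        (out / "consensus_genes.txt").write_text("\n".join(res.consensus_genes) + "\n")
        (out / "dual_feature_genes.txt").write_text("\n".join(res.dual_genes) + "\n")
        if res.network is not None and res.network.n_edges:
            export_network(res.network, "tsv", out / "network")
            export_network(res.network, "sif", out / "network")
            export_network(res.network, "graphml", out / "network")
        if res.enrichment is not None:
            write_enrichment(res.enrichment, out / "enrichment.tsv")
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise
    manifest = dict(res.manifest)
    manifest["created"] = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
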
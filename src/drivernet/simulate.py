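"""Synthetic paired-species expression data with known planted structure.

The generator emulates the statistical structure the downstream analysis
assumes: block-correlated gene modules driven by one latent per-sample
factor each, a 1:1 homolog map under which a fraction of modules is shared
(same factor, homologous membership) between the two species, group-wise
mean shifts (X vs Y differential expression) on a planted gene subset, and
AT-rich DNA with planted CG-rich islands for the CpG scanner.

A gene g in module q with loading sign s_g is generated on log2 scale as

    x_gs = b_g + noise_sd * (s_g * rho * f_qs + sqrt(1 - rho^2) * eps_gs)

with rho = sqrt(within_module_cor), so two genes of one module have expected
unsigned correlation ``within_module_cor``.  Everything is bit-reproducible
from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.metrics import adjusted_rand_score

from .enrichment import AnnotationCollection
from .expression import ExpressionMatrix
from .wgcna import UNASSIGNED, ModuleAssignment

POSITIVE_CONTROL_TERM = "POS_CONTROL"


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid; names the field."""


@dataclass
class SimConfig:
    """Study conditions for the paired-species simulation.

    Defaults are the package's desk-scale study conditions: 600 genes per
    species with 400 1:1 homologs (scaled from the two arrays' ~11000/10445
    genes and 555 shared homologs), 8 X + 8 Y arrays per species, five
    modules of 40-50 genes of which three are shared, within-module
    correlation 0.8, and 100 X-vs-Y differentially expressed genes with a
    1.0 log2-unit (two-fold) shift against residual noise of SD 0.5 log2
    units, so the group shift stays subordinate to module covariance while
    remaining easily detectable at 8 vs 8 arrays.
    """

    n_genes_per_species: int = 600
    n_shared_homologs: int = 400
    n_samples_per_group: int = 8
    module_sizes: Sequence[int] = (50, 50, 50, 40, 40)
    shared_module_fraction: float = 0.6
    within_module_cor: float = 0.8
    n_de_genes: int = 100
    de_log2_effect: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_shared_modules(self) -> int:
        return int(round(self.shared_module_fraction * self.n_modules))

    def validate(self) -> None:
        if self.n_genes_per_species < 1:
            raise SimConfigError("n_genes_per_species must be >= 1")
        if not (0 <= self.n_shared_homologs <= self.n_genes_per_species):
            raise SimConfigError("n_shared_homologs exceeds n_genes_per_species")
        if self.n_samples_per_group < 1:
            raise SimConfigError("n_samples_per_group must be >= 1")
        if any(s < 1 for s in self.module_sizes):
            raise SimConfigError("module_sizes entries must be >= 1")
        if sum(self.module_sizes) > self.n_genes_per_species:
            raise SimConfigError("module_sizes sum exceeds n_genes_per_species")
        if not (0.0 <= self.shared_module_fraction <= 1.0):
            raise SimConfigError("shared_module_fraction must lie in [0, 1]")
        if not (0.0 < self.within_module_cor < 1.0):
            raise SimConfigError("within_module_cor must lie in (0, 1)")
        if not (0 <= self.n_de_genes <= self.n_genes_per_species):
            raise SimConfigError("n_de_genes exceeds n_genes_per_species")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be > 0")
        shared_span = sum(self.module_sizes[: self.n_shared_modules])
        if shared_span > self.n_shared_homologs:
            raise SimConfigError(
                "module_sizes: shared modules do not fit inside n_shared_homologs"
            )
        own_span = sum(self.module_sizes[self.n_shared_modules :])
        if self.n_shared_homologs + own_span > self.n_genes_per_species:
            raise SimConfigError(
                "module_sizes: species-specific modules do not fit outside the homolog prefix"
            )


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    module_labels_a: pd.Series
    module_labels_b: pd.Series
    homolog_map: pd.DataFrame
    de_effects: pd.Series  # gene -> signed log2 shift (X minus Y)
    island_intervals: list = field(default_factory=list)

    @property
    def de_gene_set(self) -> set[str]:
        return set(self.de_effects.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_labels_a": self.module_labels_a.to_dict(),
            "module_labels_b": self.module_labels_b.to_dict(),
            "homolog_map": self.homolog_map.values.tolist(),
            "de_effects": self.de_effects.to_dict(),
            "island_intervals": [list(t) for t in self.island_intervals],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _species_matrix(
    rng: np.random.Generator,
    cfg: SimConfig,
    prefix: str,
    module_slots: dict[str, np.ndarray],
    factors: dict[str, np.ndarray],
    signs: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    n_genes = cfg.n_genes_per_species
    n_samples = 2 * cfg.n_samples_per_group
    width = len(str(n_genes))
    genes = [f"{prefix}{i + 1:0{width}d}" for i in range(n_genes)]
    samples = [f"{prefix}_X{i + 1:02d}" for i in range(cfg.n_samples_per_group)] + [
        f"{prefix}_Y{i + 1:02d}" for i in range(cfg.n_samples_per_group)
    ]
    groups = pd.Series(
        ["X"] * cfg.n_samples_per_group + ["Y"] * cfg.n_samples_per_group, index=samples
    )
    rho = np.sqrt(cfg.within_module_cor)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_genes)
    eps = rng.standard_normal((n_genes, n_samples))
    X = baseline[:, None] + cfg.noise_sd * eps
    labels = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    for mod, idx in module_slots.items():
        f = factors[mod]
        s = signs[mod][:, None]
        X[idx] = (
            baseline[idx, None]
            + cfg.noise_sd * (s * rho * f[None, :] + np.sqrt(1 - rho**2) * eps[idx])
        )
        labels.iloc[idx] = mod
    values = pd.DataFrame(X, index=genes, columns=samples)
    return values, groups, labels


def generate_paired_datasets(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate the two species' matrices, the homolog map and the truth.

    Shared modules occupy the same positions of the homolog prefix in both
    species and reuse one latent factor; species-specific modules live
    outside the prefix.  Each module gene carries a random loading sign, so
    a module mixes positively and negatively regulated genes (detected by
    the unsigned correlation alike).

    Differential expression is planted in two ways that add up to
    ``n_de_genes``:

    * whole shared modules are marked differentially expressed, greedily in
      module order while the module still fits in the remaining count.  A DE
      module's latent factor receives a group offset of +mu/2 in X and -mu/2
      in Y with mu = de_log2_effect / (noise_sd * rho), so every member
      gene's group-mean log2 difference is +/- de_log2_effect (sign = its
      loading sign) while within-group variances and module membership are
      untouched — the group contrast rides on the co-expression factor, as
      it does when a regulatory program differs between the X and Y
      libraries;
    * any remaining count is drawn uniformly from non-module genes, which
      get a direct +/- de_log2_effect group-mean shift.

    Both mechanisms are conserved: the shared factors (including their
    offsets) and the homologous background shifts apply to species B
    whenever the genes lie in the homolog prefix.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = 2 * cfg.n_samples_per_group

    sizes = list(cfg.module_sizes)
    shared = cfg.n_shared_modules
    # species A: modules tile the front of the gene list
    slots_a: dict[str, np.ndarray] = {}
    offset = 0
    for q, size in enumerate(sizes):
        slots_a[f"M{q + 1}"] = np.arange(offset, offset + size)
        offset += size
    # species B: shared modules mirror A's positions, own modules go after
    # the homolog prefix
    slots_b: dict[str, np.ndarray] = {}
    offset_b = cfg.n_shared_homologs
    for q, size in enumerate(sizes):
        name = f"M{q + 1}"
        if q < shared:
            slots_b[name] = slots_a[name].copy()
        else:
            slots_b[name] = np.arange(offset_b, offset_b + size)
            offset_b += size

    # allocate DE: whole shared modules first (factor-borne), remainder on
    # background genes (direct shifts)
    de_modules: list[str] = []
    remaining_de = cfg.n_de_genes
    for q in range(shared):
        name = f"M{q + 1}"
        if sizes[q] <= remaining_de:
            de_modules.append(name)
            remaining_de -= sizes[q]

    rho = np.sqrt(cfg.within_module_cor)
    mu = cfg.de_log2_effect / (cfg.noise_sd * rho)
    # samples are laid out X-block then Y-block in both species
    group_contrast = np.repeat([0.5, -0.5], cfg.n_samples_per_group)

    def _draw_factor() -> np.ndarray:
        # group-centered and standardized: the X-vs-Y contrast enters only
        # via the planted offset (keeping every planted effect calibrated
        # to de_log2_effect), and the realized factor variance is fixed at
        # 1 so the realized within-module correlation stays at the target
        # instead of swinging with the factor's chance sample variance
        f = rng.standard_normal(n_samples)
        half = cfg.n_samples_per_group
        f[:half] -= f[:half].mean()
        f[half:] -= f[half:].mean()
        return f / f.std()

    factors_a: dict[str, np.ndarray] = {}
    signs_a: dict[str, np.ndarray] = {}
    for q, (name, idx) in enumerate(slots_a.items()):
        f = _draw_factor()
        if name in de_modules:
            f = f + mu * group_contrast
        factors_a[name] = f
        signs_a[name] = rng.choice([-1.0, 1.0], size=len(idx))
    factors_b = {
        name: (factors_a[name] if q < shared else _draw_factor())
        for q, name in enumerate(slots_a)
    }
    signs_b = {
        name: (signs_a[name] if q < shared else rng.choice([-1.0, 1.0], size=len(slots_b[name])))
        for q, name in enumerate(slots_a)
    }

    values_a, groups_a, labels_a = _species_matrix(
        rng, cfg, "a", slots_a, factors_a, signs_a
    )
    values_b, groups_b, labels_b = _species_matrix(
        rng, cfg, "b", slots_b, factors_b, signs_b
    )

    genes_a, genes_b = list(values_a.index), list(values_b.index)
    homolog_map = pd.DataFrame(
        {
            "species_a": genes_a[: cfg.n_shared_homologs],
            "species_b": genes_b[: cfg.n_shared_homologs],
        }
    )

    de_records: dict[str, float] = {}
    for name in de_modules:
        for pos, sign in zip(slots_a[name], signs_a[name]):
            de_records[genes_a[pos]] = float(sign * cfg.de_log2_effect)
    if remaining_de:
        module_positions = np.concatenate(list(slots_a.values())) if slots_a else np.array([], dtype=int)
        background = np.setdiff1d(np.arange(cfg.n_genes_per_species), module_positions)
        if len(background) < remaining_de:
            raise SimConfigError(
                "n_de_genes: not enough background genes for the residual DE count"
            )
        de_idx = np.sort(rng.choice(background, size=remaining_de, replace=False))
        bg_signs = rng.choice([-1.0, 1.0], size=remaining_de)
        shift = group_contrast[None, :] * (bg_signs[:, None] * cfg.de_log2_effect)
        values_a.iloc[de_idx] = values_a.iloc[de_idx] + shift
        in_prefix = de_idx < cfg.n_shared_homologs
        if in_prefix.any():
            values_b.iloc[de_idx[in_prefix]] = (
                values_b.iloc[de_idx[in_prefix]]
                + group_contrast[None, :] * (bg_signs[in_prefix][:, None] * cfg.de_log2_effect)
            )
        for pos, sign in zip(de_idx, bg_signs):
            de_records[genes_a[pos]] = float(sign * cfg.de_log2_effect)
    de_effects = pd.Series(de_records, name="log2_effect", dtype=float)
    de_effects = de_effects.reindex(sorted(de_effects.index))

    truth = SimTruth(
        module_labels_a=labels_a,
        module_labels_b=labels_b,
        homolog_map=homolog_map,
        de_effects=de_effects,
    )
    a = ExpressionMatrix(values=values_a, groups=groups_a, log2_transformed=True)
    b = ExpressionMatrix(values=values_b, groups=groups_b, log2_transformed=True)
    return a, b, homolog_map, truth


# ---------------------------------------------------------------------------
# annotation term sets


def generate_annotations(
    truth: SimTruth,
    n_terms: int = 20,
    enriched_term_overlap: float = 0.8,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 40),
) -> AnnotationCollection:
    """GMT-like term sets over the species-A gene universe.

    The first term is a positive control containing the stated fraction of
    the planted DE genes; the remaining ``n_terms - 1`` terms are uniform
    random draws.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    universe = list(truth.module_labels_a.index)
    if not universe:
        raise ValueError("empty gene universe in truth")
    rng = np.random.default_rng(seed)
    lo, hi = term_size_range
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}

    de_genes = sorted(truth.de_gene_set)
    if de_genes:
        n_pos = max(1, int(round(enriched_term_overlap * len(de_genes))))
        pos = sorted(rng.choice(de_genes, size=n_pos, replace=False))
    else:
        pos = sorted(rng.choice(universe, size=min(lo, len(universe)), replace=False))
    terms[POSITIVE_CONTROL_TERM] = ("planted DE positive control", tuple(pos))

    for t in range(n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        members = sorted(rng.choice(universe, size=size, replace=False))
        terms[f"TERM{t + 1:04d}"] = (f"random term {t + 1}", tuple(members))
    return AnnotationCollection(terms=terms)


# ---------------------------------------------------------------------------
# DNA sequences with planted CpG islands


def _background_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """AT-rich background with CG dinucleotides suppressed by rejection."""
    bases = np.array(list("ACGT"))
    probs = np.array([0.3, 0.2, 0.2, 0.3])
    out: list[str] = []
    while len(out) < length:
        c = bases[rng.choice(4, p=probs)]
        while out and out[-1] == "C" and c == "G":
            c = bases[rng.choice(4, p=probs)]
        out.append(c)
    return out


def _island_sequence(rng: np.random.Generator, length: int, gc_target: float) -> list[str]:
    """CG-rich block: frequent CG dinucleotides so Obs/Exp > 1."""
    bases = np.array(list("ACGT"))
    p_single = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    out: list[str] = []
    while len(out) < length:
        if rng.random() < 0.35:
            out.extend("CG")
        else:
            out.append(bases[rng.choice(4, p=p_single)])
    return out[:length]


def generate_sequences(
    n_seq: int,
    seq_len: int,
    island_spec: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Simulate ``n_seq`` sequences with the same planted islands each.

    ``island_spec`` lists (start, length, gc_target) intervals; islands must
    fit in ``seq_len`` and must not overlap.  Returns ({seq_id: sequence},
    truth intervals as (seq_id, start, end) 0-based half-open).
    """
    spec = sorted(island_spec)
    prev_end = 0
    for start, length, gc in spec:
        if start < 0 or start + length > seq_len:
            raise ValueError(f"island ({start}, {length}) outside sequence of {seq_len} bp")
        if start < prev_end:
            raise ValueError("planted islands overlap")
        if not (0.0 < gc <= 1.0):
            raise ValueError("island gc_target must lie in (0, 1]")
        prev_end = start + length
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    truth: list[tuple[str, int, int]] = []
    for i in range(n_seq):
        sid = f"seq{i + 1}"
        chars = _background_sequence(rng, seq_len)
        for start, length, gc in spec:
            chars[start : start + length] = _island_sequence(rng, length, gc)
            truth.append((sid, start, start + length))
        records[sid] = "".join(chars)
    return records, truth


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_island_bed(truth: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (sid, start, end) in enumerate(truth, start=1):
            fh.write(f"{sid}\t{start}\t{end}\tplanted_{i}\t0\n")


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_metrics(
    assign: ModuleAssignment | pd.Series | Mapping[str, str],
    truth_labels: pd.Series | Mapping[str, str],
) -> dict:
    """Adjusted Rand index and per-truth-module best-match Jaccard.

    Both labelings must cover the same gene universe.  ARI treats
    "unassigned" as a regular label; identical labelings give ARI = 1.
    """
    if isinstance(assign, ModuleAssignment):
        pred = assign.labels
    else:
        pred = pd.Series(dict(assign)) if not isinstance(assign, pd.Series) else assign
    truth = (
        truth_labels
        if isinstance(truth_labels, pd.Series)
        else pd.Series(dict(truth_labels))
    )
    if set(pred.index) != set(truth.index):
        raise ValueError(
            f"gene universes differ (symmetric difference of "
            f"{len(set(pred.index) ^ set(truth.index))} genes)"
        )
    truth = truth.reindex(pred.index)
    ari = float(adjusted_rand_score(truth.to_numpy(), pred.to_numpy()))
    jaccard: dict[str, float] = {}
    for t_mod in sorted(truth.unique()):
        if t_mod == UNASSIGNED:
            continue
        t_set = set(truth.index[truth == t_mod])
        best = 0.0
        for p_mod in pred.unique():
            if p_mod == UNASSIGNED:
                continue
            p_set = set(pred.index[pred == p_mod])
            j = len(t_set & p_set) / len(t_set | p_set)
            best = max(best, j)
        jaccard[str(t_mod)] = best
    return {"ari": ari, "module_jaccard": jaccard}
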
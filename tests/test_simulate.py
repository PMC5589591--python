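"""Synthetic-data generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

import drivernet as dn
from drivernet.simulate import (
    POSITIVE_CONTROL_TERM,
    SimConfigError,
    generate_sequences,
    write_fasta,
)


class TestPairedDatasets:
    def test_seed_determinism_bitwise(self):
        cfg = dn.SimConfig(n_genes_per_species=120, n_shared_homologs=100,
                           module_sizes=(30,), n_de_genes=10, seed=11)
        a1, b1, h1, t1 = dn.generate_paired_datasets(cfg)
        a2, b2, h2, t2 = dn.generate_paired_datasets(cfg)
        assert a1.values.equals(a2.values)
        assert b1.values.equals(b2.values)
        assert h1.equals(h2)
        assert t1.de_effects.equals(t2.de_effects)

    def test_within_module_correlation_exceeds_between(self):
        cfg = dn.SimConfig(
            n_genes_per_species=80, n_shared_homologs=60,
            module_sizes=(30, 30), shared_module_fraction=1.0,
            within_module_cor=0.9, n_samples_per_group=8, n_de_genes=0, seed=5,
        )
        a, *_ = dn.generate_paired_datasets(cfg)
        S = np.abs(np.corrcoef(a.values.to_numpy()))
        m1, m2 = slice(0, 30), slice(30, 60)
        within = (S[m1, m1].mean() + S[m2, m2].mean()) / 2
        between = S[m1, m2].mean()
        assert within - between > 0.3

    def test_correlation_calibration_within_tenth(self, sim_modules_only):
        cfg, a, *_ = sim_modules_only
        S = np.abs(np.corrcoef(a.values.to_numpy()))
        blocks = [slice(0, 40), slice(40, 80), slice(80, 120)]
        for blk in blocks:
            sub = S[blk, blk]
            mean_r = (sub.sum() - np.trace(sub)) / (sub.size - sub.shape[0])
            assert abs(mean_r - cfg.within_module_cor) < 0.1

    def test_no_de_genes_means_empty_truth(self):
        cfg = dn.SimConfig(n_genes_per_species=60, n_shared_homologs=40,
                           module_sizes=(30,), n_de_genes=0, seed=1)
        *_, truth = dn.generate_paired_datasets(cfg)
        assert truth.de_gene_set == set()

    def test_de_calibration(self, sim_default):
        cfg, a, b, hmap, truth = sim_default
        x = a.values[a.samples_in_group("X")].mean(axis=1)
        y = a.values[a.samples_in_group("Y")].mean(axis=1)
        realized = (x - y)[truth.de_effects.index]
        tol = 3 * cfg.noise_sd / np.sqrt(2 * cfg.n_samples_per_group)
        # sign-aligned effect, averaged over the planted genes
        aligned = realized * np.sign(truth.de_effects)
        assert abs(aligned.mean() - cfg.de_log2_effect) < tol
        # every planted gene individually shows an X-vs-Y shift of the
        # planted sign and a magnitude of the right order
        assert (np.sign(realized) == np.sign(truth.de_effects)).all()
        assert len(truth.de_effects) == cfg.n_de_genes

    def test_de_conserved_in_species_b_over_homologs(self, sim_default):
        cfg, a, b, hmap, truth = sim_default
        pair = hmap.set_index("species_a")["species_b"]
        x = b.values[b.samples_in_group("X")].mean(axis=1)
        y = b.values[b.samples_in_group("Y")].mean(axis=1)
        shared_de = [g for g in truth.de_effects.index if g in pair.index]
        assert shared_de  # default config plants DE inside the homolog prefix
        realized = (x - y)[[pair[g] for g in shared_de]].to_numpy()
        expected = truth.de_effects[shared_de].to_numpy()
        tol = 3 * cfg.noise_sd / np.sqrt(2 * cfg.n_samples_per_group)
        assert (np.abs(realized - expected) < tol).all()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(module_sizes=(50, 50), n_genes_per_species=80,
                  n_shared_homologs=60), "module_sizes"),
            (dict(n_shared_homologs=700), "n_shared_homologs"),
            (dict(n_de_genes=700), "n_de_genes"),
            (dict(within_module_cor=1.5), "within_module_cor"),
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(shared_module_fraction=2.0), "shared_module_fraction"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        cfg = dn.SimConfig(**kwargs)
        with pytest.raises(SimConfigError, match=field):
            dn.generate_paired_datasets(cfg)

    def test_homolog_count_matches_config(self, sim_default):
        cfg, a, b, hmap, truth = sim_default
        assert len(hmap) == cfg.n_shared_homologs
        assert hmap["species_a"].is_unique and hmap["species_b"].is_unique


class TestAnnotations:
    def test_term_count_and_positive_control(self):
        cfg = dn.SimConfig(n_genes_per_species=200, n_shared_homologs=150,
                           module_sizes=(30,), n_de_genes=40, seed=2)
        *_, truth = dn.generate_paired_datasets(cfg)
        coll = dn.generate_annotations(truth, n_terms=5, enriched_term_overlap=1.0, seed=2)
        assert len(coll) == 5
        # full-overlap positive control contains every planted DE gene it drew
        assert set(coll.members(POSITIVE_CONTROL_TERM)) == truth.de_gene_set

    def test_positive_control_beats_random_terms(self, sim_default):
        cfg, a, b, hmap, truth = sim_default
        coll = dn.generate_annotations(truth, n_terms=21, enriched_term_overlap=0.8, seed=9)
        table = dn.ora(sorted(truth.de_gene_set), a.gene_ids, coll, p_thresh=1.5, min_count=1)
        table = table.set_index("term")
        p_pos = table.loc[POSITIVE_CONTROL_TERM, "p_value"]
        p_random = table.drop(index=POSITIVE_CONTROL_TERM)["p_value"]
        assert p_pos < p_random.median()
        assert p_pos == table["p_value"].min()

    def test_empty_universe_rejected(self):
        truth = dn.SimTruth(
            module_labels_a=pd.Series(dtype=object),
            module_labels_b=pd.Series(dtype=object),
            homolog_map=pd.DataFrame(columns=["species_a", "species_b"]),
            de_effects=pd.Series(dtype=float),
        )
        with pytest.raises(ValueError, match="universe"):
            dn.generate_annotations(truth, n_terms=3)


class TestSequences:
    def test_no_planted_islands_scanner_finds_none(self):
        records, truth = generate_sequences(2, 1500, [], seed=0)
        assert truth == []
        for sid, seq in records.items():
            assert dn.find_cpg_islands(seq, seq_id=sid) == []

    def test_seed_determinism_fasta_bytes(self, tmp_path):
        spec = [(400, 300, 0.7)]
        paths = []
        for run in (1, 2):
            records, _ = generate_sequences(1, 2000, spec, seed=42)
            path = tmp_path / f"run{run}.fasta"
            write_fasta(records, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_overlapping_islands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_sequences(1, 2000, [(100, 300, 0.7), (250, 300, 0.7)], seed=0)

    def test_island_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_sequences(1, 500, [(400, 300, 0.7)], seed=0)


class TestRecoveryMetrics:
    def test_identity_gives_ari_one(self, sim_modules_only):
        *_, truth = sim_modules_only
        scores = dn.recovery_metrics(truth.module_labels_a, truth.module_labels_a)
        assert scores["ari"] == pytest.approx(1.0)
        assert all(j == pytest.approx(1.0) for j in scores["module_jaccard"].values())

    def test_single_cluster_gives_ari_zero(self, sim_modules_only):
        *_, truth = sim_modules_only
        flat = pd.Series("M1", index=truth.module_labels_a.index)
        assert dn.recovery_metrics(flat, truth.module_labels_a)["ari"] == pytest.approx(0.0)

    def test_random_permutation_near_zero(self):
        cfg = dn.SimConfig(module_sizes=(50, 50, 50), shared_module_fraction=1.0,
                           n_de_genes=0, seed=13)
        *_, truth = dn.generate_paired_datasets(cfg)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(
            rng.permutation(truth.module_labels_a.to_numpy()),
            index=truth.module_labels_a.index,
        )
        assert abs(dn.recovery_metrics(shuffled, truth.module_labels_a)["ari"]) < 0.05

    def test_disjoint_universes_rejected(self, sim_modules_only):
        *_, truth = sim_modules_only
        other = truth.module_labels_a.copy()
        other.index = ["z" + g for g in other.index]
        with pytest.raises(ValueError, match="universes differ"):
            dn.recovery_metrics(other, truth.module_labels_a)
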
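"""Correlation, soft-threshold adjacency, scale-free fit, TOM, module cut."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import drivernet as dn
from drivernet.expression import ExpressionError
from drivernet.wgcna import (
    AdjacencyMatrix,
    power_fit_table,
    UNASSIGNED,
)
from tests.conftest import make_expr


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop evaluation of the topological overlap."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    w = np.eye(n)
    for m in range(n):
        for q in range(n):
            if m == q:
                continue
            l_mq = sum(a[m, u] * a[u, q] for u in range(n) if u not in (m, q))
            w[m, q] = (l_mq + a[m, q]) / (min(k[m], k[q]) + 1 - a[m, q])
    return w


class TestCorrelationMatrix:
    def test_duplicated_gene_and_negation_give_unit_similarity(self):
        x = [1.0, 2.0, 4.0, 3.0]
        m = make_expr([x, x, [-v for v in x]])
        S = dn.correlation_matrix(m)
        assert S.iloc[0, 1] == pytest.approx(1.0)
        assert S.iloc[0, 2] == pytest.approx(1.0)  # unsigned

    def test_matches_pairwise_pearson(self):
        rng = np.random.default_rng(0)
        m = make_expr(rng.normal(size=(3, 4)))
        S = dn.correlation_matrix(m)
        X = m.values.to_numpy()
        for i in range(3):
            for j in range(3):
                r = stats.pearsonr(X[i], X[j]).statistic
                assert S.iloc[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ExpressionError, match="3 samples"):
            dn.correlation_matrix(make_expr([[1, 2], [2, 1]]))

    def test_zero_variance_gene_removed_with_warning(self):
        m = make_expr([[1, 2, 3], [5, 5, 5], [3, 1, 2]])
        with pytest.warns(UserWarning, match="zero-variance"):
            S = dn.correlation_matrix(m)
        assert list(S.index) == ["g1", "g3"]


class TestAdjacency:
    def test_power_arithmetic(self):
        S = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]])
        A = dn.adjacency(S, beta=2)
        assert A.values.iloc[0, 1] == pytest.approx(0.64)
        assert A.values.iloc[0, 0] == pytest.approx(1.0)

    def test_invalid_beta_rejected(self):
        S = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError, match="beta"):
            dn.adjacency(S, beta=0)

    def test_raising_beta_never_increases_offdiagonal(self):
        rng = np.random.default_rng(1)
        r = np.abs(rng.uniform(size=(6, 6)))
        S = pd.DataFrame((r + r.T) / 2)
        np.fill_diagonal(S.values, 1.0)
        prev = None
        for beta in (1, 2, 5, 12, 20):
            A = dn.adjacency(S, beta).values.to_numpy()
            if prev is not None:
                off = ~np.eye(6, dtype=bool)
                assert (A[off] <= prev[off] + 1e-15).all()
            prev = A


class TestScaleFreeFit:
    def test_power_law_connectivities_fit_well(self):
        # genes whose connectivity frequencies follow n(k) ~ k^-2
        ks = np.arange(1, 11, dtype=float)
        counts = np.round(2000 * ks**-2.0).astype(int)
        k = np.repeat(ks, counts)
        # rank-1 adjacency realizes approximately these row sums
        w = k / np.sqrt(k.sum())
        A = np.outer(w, w)
        np.fill_diagonal(A, 0.0)
        A = np.clip(A, 0.0, 1.0)
        genes = [f"g{i}" for i in range(len(k))]
        fit = dn.scale_free_fit(
            AdjacencyMatrix(pd.DataFrame(A, index=genes, columns=genes), beta=1)
        )
        assert fit.r_squared > 0.9
        assert fit.slope < 0

    def test_two_genes_rejected(self):
        A = AdjacencyMatrix(pd.DataFrame([[0.0, 0.5], [0.5, 0.0]]), beta=1)
        with pytest.raises(ValueError, match="at least"):
            dn.scale_free_fit(A)

    def test_equal_connectivities_rejected(self):
        n = 12
        A = np.full((n, n), 0.5)
        np.fill_diagonal(A, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            dn.scale_free_fit(AdjacencyMatrix(pd.DataFrame(A), beta=1))


class TestSelectPower:
    @staticmethod
    def _hub_matrix():
        # one latent factor with uniformly spread loadings gives k ~ lambda^beta,
        # i.e. a genuinely scale-free degree distribution
        rng = np.random.default_rng(17)
        lam = rng.uniform(0.2, 0.95, size=300)
        f = rng.standard_normal(20)
        X = lam[:, None] * f[None, :] + np.sqrt(1 - lam**2)[:, None] * rng.standard_normal((300, 20))
        return make_expr(X)

    def test_first_qualifying_candidate_returned(self):
        m = self._hub_matrix()
        S = dn.correlation_matrix(m)
        table = power_fit_table(S)
        ok = table[(table.r_squared >= 0.9) & (table.slope < 0)]
        assert len(ok), "hub-structured data should reach the scale-free cutoff"
        first = int(ok.iloc[0].power)
        assert dn.select_power(m) == first
        # starting the candidate grid at a qualifying power returns it directly
        assert dn.select_power(m, candidates=range(first, 21)) == first

    def test_empty_candidates_rejected(self, sim_modules_only):
        _, a, *_ = sim_modules_only
        with pytest.raises(ValueError, match="empty"):
            dn.select_power(a, candidates=[])

    def test_deterministic_between_calls(self, sim_modules_only):
        _, a, *_ = sim_modules_only
        assert dn.select_power(a) == dn.select_power(a)

    def test_fallback_warns_and_returns_best(self):
        rng = np.random.default_rng(4)
        m = make_expr(rng.normal(size=(40, 6)))
        with pytest.warns(UserWarning, match="falling back"):
            beta = dn.select_power(m, candidates=[1, 2], r2_cutoff=0.999999)
        assert beta in (1, 2)


class TestTOM:
    def test_three_gene_hand_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        res = dn.tom_similarity(AdjacencyMatrix(pd.DataFrame(a), beta=1))
        # l_12 = 0.25, k = 1.0 each: w = (0.25 + 0.5)/(1 + 1 - 0.5) = 0.5
        assert res.similarity.iloc[0, 1] == pytest.approx(0.5)
        assert np.allclose(res.connectivity, 1.0)
        assert np.allclose(res.dissimilarity, 1 - res.similarity)

    def test_isolated_gene(self):
        a = np.array([[0.0, 0.7, 0.0], [0.7, 0.0, 0.0], [0.0, 0.0, 0.0]])
        res = dn.tom_similarity(AdjacencyMatrix(pd.DataFrame(a), beta=1))
        assert np.allclose(res.similarity.iloc[2, :2], 0.0)
        assert np.allclose(res.dissimilarity.iloc[2, :2], 1.0)
        assert res.similarity.iloc[2, 2] == 1.0

    def test_entries_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.uniform(size=(8, 8))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            w = dn.tom_similarity(pd.DataFrame(a)).similarity.to_numpy()
            assert w.min() >= 0.0 and w.max() <= 1.0

    def test_asymmetric_input_rejected(self):
        a = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            dn.tom_similarity(pd.DataFrame(a))


class TestClusterModules:
    @staticmethod
    def _block_dissimilarity(sizes, within=0.1, between=0.9):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(d, index=genes, columns=genes)

    def test_two_planted_blocks_recovered_exactly(self):
        d = self._block_dissimilarity([40, 40])
        assign = dn.cluster_modules(d, cut_height=0.9, min_module_size=30)
        assert assign.n_modules == 2
        assert sorted(len(assign.members(m)) for m in assign.module_names) == [40, 40]
        # absolute-height semantics agrees on this contrast
        assign_abs = dn.cluster_modules(d, cut_height=0.9, min_module_size=30,
                                        cut_mode="absolute")
        assert assign_abs.n_modules == 2

    def test_min_size_above_gene_count_leaves_all_unassigned(self):
        d = self._block_dissimilarity([10, 10])
        assign = dn.cluster_modules(d, min_module_size=50)
        assert (assign.labels == UNASSIGNED).all()
        assert assign.n_modules == 0

    def test_labels_ordered_by_decreasing_size(self):
        d = self._block_dissimilarity([35, 60])
        assign = dn.cluster_modules(d, min_module_size=30)
        assert len(assign.members("M1")) == 60
        assert len(assign.members("M2")) == 35
        assert set(assign.colors[assign.labels == "M1"]) == {"turquoise"}

    def test_nan_rejected(self):
        d = self._block_dissimilarity([5, 5]).to_numpy()
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            dn.cluster_modules(pd.DataFrame(d), min_module_size=2)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            dn.cluster_modules(pd.DataFrame(np.zeros((3, 4))))


class TestEstimator:
    def test_permutation_equivariance(self, sim_modules_only):
        _, a, *_ = sim_modules_only
        est = dn.CoexpressionModules(power=6, min_module_size=20)
        labels = est.fit(a).labels_
        rng = np.random.default_rng(5)
        perm = rng.permutation(a.n_genes)
        shuffled = a.values.iloc[perm]
        labels_p = dn.CoexpressionModules(power=6, min_module_size=20).fit(shuffled).labels_
        scores = dn.recovery_metrics(labels_p, labels[labels_p.index])
        assert scores["ari"] == pytest.approx(1.0)

    def test_sklearn_contract(self, sim_modules_only):
        from sklearn.base import clone

        _, a, *_ = sim_modules_only
        est = dn.CoexpressionModules(power=6)
        clone(est)
        out = est.fit_predict(a.values)
        assert len(out) == a.n_genes
        assert est.beta_ == 6
        assert set(est.labels_.index) == set(a.gene_ids)

    def test_pipeline_recovers_planted_modules(self, sim_modules_only):
        cfg, a, *_ , truth = (*sim_modules_only[:2], None, None, sim_modules_only[4])
        assign, beta, fits = dn.detect_modules(a)
        scores = dn.recovery_metrics(assign, truth.module_labels_a)
        assert scores["ari"] >= 0.8
        assert assign.n_modules == len(cfg.module_sizes)
        assert {"power", "r_squared", "slope", "mean_connectivity"} <= set(fits.columns)
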
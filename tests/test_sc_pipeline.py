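"""QC filtering rules, the log-normalization formula, PCA and graph
clustering behavior, marker discovery, and the pseudotime KS comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import toy_counts
from pnatlas.config import STATES
from pnatlas.sc_pipeline import (
    ClusterAssignment,
    FilterParams,
    cluster_graph,
    embed_pca,
    filter_cells,
    find_markers,
    normalize_log,
    path_pseudotime,
    pseudotime_ks,
)


def qc_fixture():
    """Four cells around the QC thresholds over 1200 genes."""
    n_genes = 1200
    X = np.zeros((4, n_genes), dtype=int)
    X[0, :999] = 2          # 999 detected genes -> removed
    X[1, :1000] = 2         # 1000 detected genes -> kept
    X[2, :1100] = 1
    X[2, -1] = 11           # mito = 11/1110 ~ 0.0099 < 0.01 -> kept
    X[3, :1100] = 1
    X[3, -2] = 88
    X[3, -1] = 12           # mito = 12/1200 = 0.01 exactly -> removed
    return toy_counts(X, mito_genes=[n_genes - 1])


class TestFilterCells:
    def test_gene_count_and_mito_thresholds(self):
        kept = filter_cells(qc_fixture())
        assert list(kept.obs_names) == ["c1", "c2"]

    def test_all_pass_identity(self):
        a = qc_fixture()
        out = filter_cells(a, FilterParams(min_genes_per_cell=0, max_mito_fraction=1.0))
        assert out.shape == a.shape
        np.testing.assert_array_equal(out.X, a.X)

    def test_idempotent_and_monotone(self):
        a = qc_fixture()
        once = filter_cells(a)
        twice = filter_cells(once)
        assert list(once.obs_names) == list(twice.obs_names)
        looser = filter_cells(a, FilterParams(min_genes_per_cell=500))
        assert set(once.obs_names) <= set(looser.obs_names)

    def test_empty_result_is_explicit_error(self):
        with pytest.raises(ValueError, match="no cells survive"):
            filter_cells(qc_fixture(), FilterParams(min_genes_per_cell=100000))

    def test_missing_mito_flag_rejected(self):
        a = qc_fixture()
        a.var = a.var.drop(columns="is_mito")
        with pytest.raises(ValueError, match="is_mito"):
            filter_cells(a)


class TestNormalizeLog:
    def test_formula(self):
        X = np.array([[5, 0], [10, 10]])
        out = normalize_log(toy_counts(X), scale=1e4)
        assert out.X[0, 0] == pytest.approx(np.log(1 + 1e4))
        assert out.X[0, 1] == 0.0
        assert out.X[1, 0] == pytest.approx(np.log(1 + 1e4 * 0.5))

    def test_depth_invariance(self):
        X = np.array([[3, 7, 10], [6, 14, 20]])
        out = normalize_log(toy_counts(X))
        np.testing.assert_allclose(out.X[0], out.X[1])

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="zero library"):
            normalize_log(toy_counts(np.array([[0, 0], [1, 1]])))


class TestPCA:
    def test_line_captured_by_first_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.outer(t, [1.0, -2.0, 0.5, 3.0])
        emb = embed_pca(X, n_components=3, scale_genes=False)
        assert emb.variance_ratio[0] > 0.999

    def test_full_rank_preserves_distances(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        emb = embed_pca(X, n_components=5, scale_genes=False)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(emb.coords), pdist(X), rtol=1e-9)
        assert emb.variance_ratio.sum() == pytest.approx(1.0)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 8))
        a = embed_pca(X, 4)
        b = embed_pca(X, 4)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_rank_bound_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            embed_pca(np.zeros((5, 3)), n_components=4)

    def test_states_separate_in_pc_space(self):
        from pnatlas.config import SyntheticConfig
        from pnatlas.synthetic_data import simulate_counts

        cfg = SyntheticConfig(
            seed=2,
            n_cells_per_replicate=400,
            n_replicates_per_genotype=1,
            state_proportions={"control": (0.5, 0.0, 0.0, 0.0, 0.5)},
            marker_log2fc=3.0,
        )
        a = simulate_counts(cfg, "control")
        emb = embed_pca(normalize_log(a), 10)
        states = a.obs["true_state"].astype(str).to_numpy()
        prog = emb.coords[states == "progenitor"]
        diff = emb.coords[states == "differentiated"]
        between = np.linalg.norm(prog.mean(0) - diff.mean(0))
        within = np.median(np.linalg.norm(prog - prog.mean(0), axis=1))
        assert between > within


class TestClustering:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (100, 20)), rng.normal(50, 1, (100, 20))])
        cl = cluster_graph(X, seed=0)
        assert cl.n_clusters == 2
        assert adjusted_rand_score(np.repeat([0, 1], 100), cl.labels) == 1.0

    def test_duplicated_cells_get_identical_partitions(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (60, 20)), rng.normal(20, 1, (60, 20))])
        cl = cluster_graph(np.vstack([X, X]), seed=0)
        lab = cl.labels.to_numpy()
        assert adjusted_rand_score(lab[:120], lab[120:]) == 1.0

    def test_labels_contiguous_and_size_ordered(self, p5_norm):
        emb = embed_pca(p5_norm, 30)
        cl = cluster_graph(emb, seed=0)
        sizes = cl.labels.value_counts().sort_index()
        assert list(sizes.index) == list(range(cl.n_clusters))
        assert (np.diff(sizes.to_numpy()) <= 0).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k_graph"):
            cluster_graph(np.zeros((10, 2)), k_graph=0)


class TestFindMarkers:
    @staticmethod
    def _two_cluster_norm(planted: bool):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, size=(120, 60))
        if planted:
            X[:60, 0] += 30  # cluster A exclusively high in gene 0
            X[60:, 0] = 0
        a = toy_counts(X)
        return normalize_log(a)

    def test_planted_marker_ranks_first(self):
        norm = self._two_cluster_norm(planted=True)
        cl = ClusterAssignment(
            labels=pd.Series(np.repeat([0, 1], 60), index=norm.obs_names), resolution=1.0
        )
        mk = find_markers(norm, cl)
        top = mk[(mk["cluster"] == 0) & (mk["rank"] == 1)]
        assert top["gene"].iloc[0] == "g0"

    def test_identical_clusters_yield_no_markers(self):
        norm = self._two_cluster_norm(planted=False)
        # same cells duplicated into both clusters
        X = np.vstack([norm.X, norm.X])
        dup = toy_counts(np.ones((240, 60), dtype=int))
        dup.X = X
        cl = ClusterAssignment(
            labels=pd.Series(np.repeat([0, 1], 120), index=dup.obs_names), resolution=1.0
        )
        assert find_markers(dup, cl).empty

    def test_permuted_labels_rarely_pass_fdr(self):
        norm = self._two_cluster_norm(planted=False)
        rng = np.random.default_rng(0)
        n_hits = 0
        for _ in range(20):
            labels = rng.permutation(np.repeat([0, 1], 60))
            cl = ClusterAssignment(
                labels=pd.Series(labels, index=norm.obs_names), resolution=1.0
            )
            if not find_markers(norm, cl).empty:
                n_hits += 1
        assert n_hits <= 1  # >= 95% of permutations yield nothing

    def test_single_cluster_rejected(self):
        norm = self._two_cluster_norm(planted=False)
        cl = ClusterAssignment(
            labels=pd.Series(np.zeros(120, dtype=int), index=norm.obs_names),
            resolution=1.0,
        )
        with pytest.raises(ValueError, match="2 clusters"):
            find_markers(norm, cl)


class TestPseudotime:
    def test_identical_distributions_give_null_result(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100, 3))
        states = np.array(["a", "b"] * 50)
        coords[states == "b"] += 5
        # same cells duplicated under two genotype labels
        D, p = pseudotime_ks(
            np.vstack([coords, coords]),
            ["a", "b"],
            np.concatenate([states, states]),
            np.repeat(["g1", "g2"], 100),
        )
        assert D == 0.0 and p == 1.0

    def test_statistic_bounded(self, e14_norm):
        emb = embed_pca(e14_norm, 30)
        D, p = pseudotime_ks(
            emb,
            list(STATES),
            e14_norm.obs["true_state"].astype(str),
            e14_norm.obs["genotype"],
        )
        assert 0.0 <= D <= 1.0 and 0.0 <= p <= 1.0

    def test_progenitor_excess_shifts_pseudotime(self, e14_norm):
        """The mutant's progenitor accumulation (9.3% -> 31%) leaves fewer
        cells far along pseudotime; KS detects it at n = 2000/genotype."""
        emb = embed_pca(e14_norm, 30)
        states = e14_norm.obs["true_state"].astype(str).to_numpy()
        geno = e14_norm.obs["genotype"].to_numpy()
        D, p = pseudotime_ks(emb, list(STATES), states, geno)
        assert p < 0.05
        pt = path_pseudotime(emb.coords, states, list(STATES))
        assert pt[geno == "control"].mean() > pt[geno == "mutant"].mean()

    def test_pseudotime_in_unit_interval_and_ordered(self, e14_norm):
        emb = embed_pca(e14_norm, 30)
        states = e14_norm.obs["true_state"].astype(str).to_numpy()
        pt = path_pseudotime(emb.coords, states, list(STATES))
        assert pt.min() >= 0.0 and pt.max() <= 1.0
        assert pt[states == "progenitor"].mean() < pt[states == "differentiated"].mean()

    def test_tiny_genotype_rejected(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ValueError, match="at least 2 cells"):
            pseudotime_ks(
                coords,
                ["a"],
                np.array(["a"] * 5),
                np.array(["g1", "g1", "g1", "g1", "g2"]),
            )
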
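import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexmod.clustering import GeneCluster
from coexmod.consensus import (
    ConsensusParams,
    Module,
    cluster_score_correlations,
    define_modules,
    filter_recurrent_clusters,
    module_gene_sets,
    module_weights,
    score_module,
)
from coexmod.metagene import ClusterScoreMatrix
from coexmod.preprocess import Compendium, zscore_genes

from conftest import make_dataset


def _score_matrix(scores):
    scores = np.asarray(scores, dtype=float)
    return ClusterScoreMatrix(
        cluster_ids=[f"c{i}" for i in range(scores.shape[0])],
        sample_keys=[("D", f"s{j}") for j in range(scores.shape[1])],
        scores=scores,
    )


class TestCorrelations:
    def test_identical_rows_correlate_perfectly(self):
        m = _score_matrix([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        corr = cluster_score_correlations(m)
        np.testing.assert_allclose(corr, np.ones((2, 2)), atol=1e-12)

    def test_matches_pairwise_pearson_oracle(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(0)
        m = _score_matrix(rng.standard_normal((3, 4)))
        corr = cluster_score_correlations(m)
        for i in range(3):
            for j in range(3):
                assert corr[i, j] == pytest.approx(
                    pearsonr(m.scores[i], m.scores[j]).statistic, abs=1e-10
                )
        assert np.allclose(corr, corr.T, atol=1e-12)

    def test_zero_variance_row_rejected_by_name(self):
        m = _score_matrix([[1.0, 1, 1, 1], [1.0, 2, 3, 4]])
        with pytest.raises(ValueError, match="c0"):
            cluster_score_correlations(m)


def _brute_force_filter(corr, tau, k):
    kept = []
    n = corr.shape[0]
    for i in range(n):
        deg = sum(1 for j in range(n) if j != i and corr[i, j] > tau)
        if deg >= k:
            kept.append(i)
    return kept


class TestRecurrentFilter:
    def test_seven_clique_all_retained(self):
        corr = np.full((7, 7), 0.9)
        np.fill_diagonal(corr, 1.0)
        params = ConsensusParams()
        assert filter_recurrent_clusters(corr, params) == list(range(7))

    def test_isolated_cluster_dropped(self):
        corr = np.full((8, 8), 0.9)
        np.fill_diagonal(corr, 1.0)
        corr[7, :] = corr[:, 7] = 0.65
        corr[7, 7] = 1.0
        params = ConsensusParams()
        assert filter_recurrent_clusters(corr, params) == list(range(7))

    def test_pendant_cluster_with_one_strong_link_dropped(self):
        corr = np.full((8, 8), -0.1)
        corr[:7, :7] = 0.8
        corr[0, 7] = corr[7, 0] = 0.75
        np.fill_diagonal(corr, 1.0)
        params = ConsensusParams()
        assert filter_recurrent_clusters(corr, params) == list(range(7))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        A = rng.uniform(-1, 1, size=(n, n))
        corr = (A + A.T) / 2
        np.fill_diagonal(corr, 1.0)
        tau = float(rng.uniform(0.1, 0.9))
        k = int(rng.integers(1, 8))
        params = ConsensusParams(r_threshold=tau, min_neighbors=k)
        assert filter_recurrent_clusters(corr, params) == _brute_force_filter(corr, tau, k)


class TestDefineModules:
    def _block_corr(self, sizes, within=0.9, between=-0.2):
        n = sum(sizes)
        corr = np.full((n, n), between)
        start = 0
        for s in sizes:
            corr[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(corr, 1.0)
        return corr

    def test_two_blocks_recovered(self):
        corr = self._block_corr([5, 4])
        assignment = define_modules(corr, ConsensusParams())
        labels = [assignment[str(i)] for i in range(9)]
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_degenerate_silhouette_falls_back_to_two(self, caplog):
        corr = np.full((6, 6), 0.5)
        np.fill_diagonal(corr, 1.0)
        assignment = define_modules(corr, ConsensusParams())
        assert len(set(assignment.values())) == 2

    def test_invariant_under_cluster_relabeling(self):
        corr = self._block_corr([4, 3, 5])
        rng = np.random.default_rng(1)
        perm = rng.permutation(12)
        ids = [f"c{i}" for i in range(12)]
        a1 = define_modules(corr, ConsensusParams(), ids)
        a2 = define_modules(
            corr[np.ix_(perm, perm)], ConsensusParams(), [ids[i] for i in perm]
        )
        groups1 = {}
        groups2 = {}
        for cid, m in a1.items():
            groups1.setdefault(m, set()).add(cid)
        for cid, m in a2.items():
            groups2.setdefault(m, set()).add(cid)
        assert set(map(frozenset, groups1.values())) == set(map(frozenset, groups2.values()))

    def test_fixed_k_override(self):
        corr = self._block_corr([4, 4, 4])
        assignment = define_modules(corr, ConsensusParams(n_modules=3))
        assert len(set(assignment.values())) == 3

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            define_modules(np.array([[1.0]]), ConsensusParams())


class TestModuleGeneSets:
    def _clusters(self, gene_lists):
        return [
            GeneCluster(cluster_id=f"c{i}", source_dataset_id="D", gene_ids=gl)
            for i, gl in enumerate(gene_lists)
        ]

    def test_strictly_above_third_included(self):
        clusters = self._clusters(
            [["a", "b"], ["a", "b"], ["b"], ["b", "c"], ["b"]]
        )
        assignment = {f"c{i}": "mod1" for i in range(5)}
        genes = module_gene_sets(assignment, clusters, ConsensusParams())
        # a in 2/5 = 0.4 > 1/3 included; c in 1/5 excluded
        assert genes["mod1"] == ["a", "b"]

    def test_exactly_one_third_excluded(self):
        clusters = self._clusters([["a", "b"], ["b"], ["b"]])
        assignment = {f"c{i}": "mod1" for i in range(3)}
        genes = module_gene_sets(assignment, clusters, ConsensusParams())
        assert genes["mod1"] == ["b"]

    def test_empty_gene_set_raises_with_diagnostic(self):
        clusters = self._clusters([["a"], ["b"], ["c"], ["d"]])
        assignment = {f"c{i}": "mod1" for i in range(4)}
        with pytest.raises(ValueError, match="top gene frequencies"):
            module_gene_sets(assignment, clusters, ConsensusParams())


class TestModuleWeightsAndScoring:
    def test_single_cluster_module_weights_equal_metagene(self, small_bimodal_dataset):
        from coexmod.metagene import compute_metagene

        ds = small_bimodal_dataset
        genes = sorted([f"g{i}" for i in range(10)])
        cl = compute_metagene(
            GeneCluster("c1", ds.dataset_id, genes), ds
        )
        comp = Compendium([ds], list(ds.gene_ids))
        mod = Module(
            module_id="mod1", member_cluster_ids=["c1"], gene_ids=genes,
            contributing_datasets=[ds.dataset_id],
        )
        module_weights(mod, comp)
        np.testing.assert_allclose(mod.weights, cl.metagene, atol=1e-8)
        scores = score_module(mod, ds)
        from coexmod.metagene import score_samples

        np.testing.assert_allclose(scores, score_samples(cl, ds), atol=1e-8)

    def test_one_hot_weights_reproduce_single_gene_row(self, small_bimodal_dataset):
        ds = small_bimodal_dataset
        mod = Module(
            module_id="m", member_cluster_ids=[], gene_ids=["g3"],
            weights=np.array([1.0]),
        )
        np.testing.assert_allclose(score_module(mod, ds), ds.values[ds.gene_index(["g3"])][0])

    def test_two_perfectly_correlated_genes_weights(self):
        base = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.25])
        ds = zscore_genes(make_dataset(np.vstack([base, 2 * base])))
        comp = Compendium([ds], list(ds.gene_ids))
        mod = Module(
            module_id="m", member_cluster_ids=[], gene_ids=["g0", "g1"],
            contributing_datasets=["T"],
        )
        module_weights(mod, comp)
        np.testing.assert_allclose(np.abs(mod.weights), [0.70710678, 0.70710678], atol=1e-10)

    def test_missing_module_gene_rejected(self):
        ds = zscore_genes(make_dataset(np.random.default_rng(0).standard_normal((3, 10))))
        comp = Compendium([ds], list(ds.gene_ids))
        mod = Module(module_id="m", member_cluster_ids=[], gene_ids=["nope", "g0"])
        with pytest.raises(ValueError, match="missing from universe"):
            module_weights(mod, comp)
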
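import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexmod.associations import (
    classify_intrinsic_extrinsic,
    coherence_stats,
    compare_coherence,
    compare_score_variance,
    cox_association,
    dichotomize,
    group_mean_difference,
    logistic_response,
    module_signature_correlation,
    pool_datasets,
    signature_score,
    subtype_auc,
    SignatureDef,
    CoherenceRecord,
)
from coexmod.bimodality import bh_fdr
from coexmod.consensus import Module
from coexmod.preprocess import zscore_genes

from conftest import make_dataset


def _record(module_id="m", context="tumor", rs=(0.0,) * 6, score_var=1.0):
    r = np.asarray(rs, dtype=float)
    z = np.arctanh(np.clip(r, -(1 - 1e-12), 1 - 1e-12))
    return CoherenceRecord(
        module_id=module_id,
        context=context,
        pairwise_r=r,
        mean_fisher_z=float(z.mean()),
        mean_r_back=float(np.tanh(z.mean())),
        median_r=float(np.median(r)),
        score_variance=score_var,
    )


def _module(genes, weights=None):
    genes = list(genes)
    w = np.asarray(weights) if weights is not None else np.ones(len(genes)) / np.sqrt(len(genes))
    return Module(module_id="m", member_cluster_ids=[], gene_ids=genes, weights=w)


class TestCoherence:
    def test_fisher_z_closed_forms(self):
        assert np.arctanh(0.0) == 0.0
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_coherent_module_statistics(self):
        rng = np.random.default_rng(0)
        lat = rng.binomial(1, 0.4, 100)
        rows = [3.0 * lat + rng.standard_normal(100) for _ in range(6)]
        ds = zscore_genes(make_dataset(np.array(rows)))
        rec = coherence_stats(_module(ds.gene_ids), ds)
        assert rec.median_r > 0.35
        assert len(rec.pairwise_r) == 15  # C(6,2)
        assert rec.score_variance > 0

    def test_identical_records_compare_null(self):
        a = _record(rs=np.linspace(0.1, 0.6, 10))
        b = _record(rs=np.linspace(0.1, 0.6, 10), context="cell_line")
        rec = compare_coherence(a, b)
        assert rec.estimate == pytest.approx(0.0, abs=1e-12)
        assert rec.p == pytest.approx(1.0)

    def test_swapped_order_negates_estimate(self):
        a = _record(rs=np.linspace(0.3, 0.7, 8))
        b = _record(rs=np.linspace(0.0, 0.2, 8), context="cell_line")
        r1 = compare_coherence(a, b)
        r2 = compare_coherence(b, a)
        assert r1.estimate == pytest.approx(-r2.estimate)
        assert r1.p == pytest.approx(r2.p)

    def test_different_modules_rejected(self):
        with pytest.raises(ValueError):
            compare_coherence(_record(module_id="x"), _record(module_id="y"))


class TestScoreVarianceFtest:
    def test_equal_variances_give_f_near_one(self):
        rng = np.random.default_rng(2)
        mod = _module(["g0"], weights=[1.0])
        a = make_dataset(rng.standard_normal((1, 50)), dataset_id="A")
        b = make_dataset(rng.permutation(a.values[0])[None, :], dataset_id="B")
        rec = compare_score_variance(mod, a, b)
        assert rec.estimate == pytest.approx(1.0, abs=1e-9)
        assert rec.p == pytest.approx(1.0, abs=1e-9)

    def test_fourfold_variance_detected(self):
        rng = np.random.default_rng(3)
        mod = _module(["g0"], weights=[1.0])
        x = rng.standard_normal(200)
        a = make_dataset((2.0 * x)[None, :], dataset_id="A")
        b = make_dataset(rng.standard_normal(200)[None, :], dataset_id="B")
        rec = compare_score_variance(mod, a, b)
        assert rec.estimate == pytest.approx(4.0, rel=0.3)
        assert rec.p < 1e-5

    def test_swap_inverts_f_keeps_p(self):
        rng = np.random.default_rng(4)
        mod = _module(["g0"], weights=[1.0])
        a = make_dataset((2.0 * rng.standard_normal(80))[None, :], dataset_id="A")
        b = make_dataset(rng.standard_normal(80)[None, :], dataset_id="B")
        r1 = compare_score_variance(mod, a, b)
        r2 = compare_score_variance(mod, b, a)
        assert r1.estimate == pytest.approx(1.0 / r2.estimate)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)


class TestIntrinsicExtrinsicRule:
    def test_rule_cases(self):
        tum_coh = _record(context="tumor", rs=(0.6,) * 6)
        cl_inc = _record(context="cell_line", rs=(0.05,) * 6)
        cl_coh = _record(context="cell_line", rs=(0.6,) * 6)
        tum_weak = _record(context="tumor", rs=(0.2,) * 6)
        assert classify_intrinsic_extrinsic(tum_coh, cl_inc) == "extrinsic"
        assert classify_intrinsic_extrinsic(tum_coh, cl_coh) == "intrinsic"
        assert classify_intrinsic_extrinsic(tum_weak, cl_inc) == "indeterminate"


class TestAuc:
    def test_perfect_separation(self):
        rec = subtype_auc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert rec.auc == 1.0
        assert rec.sensitivity == 1.0 and rec.specificity == 1.0

    def test_tied_pair_counts_half(self):
        rec = subtype_auc(np.array([2.0, 1, 3, 1]), np.array([0, 0, 1, 1]))
        assert rec.auc == pytest.approx(0.625)

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError):
            subtype_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.standard_normal(n), 1)  # force ties
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1
        rec = subtype_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert rec.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_youden_threshold_maximizes_j(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.9, 0.7])
        labels = np.array([0, 0, 0, 1, 1, 1])
        rec = subtype_auc(scores, labels)
        assert rec.youden_threshold == pytest.approx(0.7)
        assert rec.sensitivity == 1.0 and rec.specificity == 1.0


class TestSignatures:
    def test_all_positive_weights_give_plain_mean(self):
        ds = zscore_genes(make_dataset(np.random.default_rng(5).standard_normal((4, 30))))
        sig = SignatureDef(name="s", type="weighted_mean",
                           gene_weights={g: 1.0 for g in ds.gene_ids})
        np.testing.assert_allclose(signature_score(ds, sig), ds.values.mean(axis=0))

    def test_mixed_signs_cancel(self):
        ds = make_dataset(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]))
        sig = SignatureDef(name="s", type="weighted_mean",
                           gene_weights={"g0": 1.0, "g1": -1.0})
        np.testing.assert_allclose(signature_score(ds, sig), np.zeros(3))

    def test_centroid_equal_to_profile_gives_unit_correlation(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((5, 3))
        ds = make_dataset(vals)
        sig = SignatureDef(name="c", type="centroid",
                           centroid={f"g{i}": vals[i, 0] for i in range(5)})
        assert signature_score(ds, sig)[0] == pytest.approx(1.0)

    def test_module_signature_correlation_oracle(self):
        from scipy.stats import pearsonr

        a = np.array([0.3, -1.2, 0.5, 2.0, -0.7])
        b = np.array([1.0, -0.5, 0.2, 1.5, 0.0])
        assert module_signature_correlation(a, b) == pytest.approx(
            pearsonr(a, b).statistic, abs=1e-10
        )
        assert module_signature_correlation(a, a) == pytest.approx(1.0)
        assert module_signature_correlation(a, -a) == pytest.approx(-1.0)


class TestDichotomize:
    def test_median_rule(self):
        np.testing.assert_array_equal(
            dichotomize(np.array([1.0, 2, 3, 4]), "median"), [0, 0, 1, 1]
        )

    def test_all_equal_scores_all_low(self):
        np.testing.assert_array_equal(dichotomize(np.ones(5), "median"), np.zeros(5))

    def test_lower_tertile_flags_bottom_third(self):
        flags = dichotomize(np.arange(1.0, 10.0), "lower_tertile")
        np.testing.assert_array_equal(flags, [1, 1, 1, 0, 0, 0, 0, 0, 0])


class TestClinicalModels:
    def _survival_data(self, beta=0.7, n=600, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.binomial(1, 0.3, n).astype(float)
        t_event = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
        t_cens = rng.exponential(5.0, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return pd.DataFrame({"m1": x}), time, event

    def test_cox_recovers_positive_log_hr(self):
        scores, time, event = self._survival_data()
        recs = cox_association(scores, time, event)
        assert recs[0].estimate == pytest.approx(0.7, abs=0.3)
        assert recs[0].q < 0.05

    def test_cox_zero_variance_rejected(self):
        scores, time, event = self._survival_data()
        scores["flat"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            cox_association(scores, time, event)

    def test_cox_q_uses_shared_bh(self):
        rng = np.random.default_rng(1)
        scores, time, event = self._survival_data()
        scores["m2"] = rng.standard_normal(len(time))
        scores["m3"] = rng.standard_normal(len(time))
        recs = cox_association(scores, time, event)
        qs = bh_fdr(np.array([r.p for r in recs]))
        for r, q in zip(recs, qs):
            assert r.q == pytest.approx(max(q, r.p))

    def test_logistic_recovers_sign(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        p = 1 / (1 + np.exp(-(x - 0.3)))
        y = rng.binomial(1, p)
        recs = logistic_response(pd.DataFrame({"m1": x}), y)
        assert recs[0].estimate > 0
        assert recs[0].q < 0.05

    def test_logistic_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_response(pd.DataFrame({"m1": np.arange(20.0)}), np.ones(20))

    def test_group_difference_symmetry_and_null(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        g = np.array([0, 1] * 20)
        r1 = group_mean_difference(x, g)
        r2 = group_mean_difference(x, 1 - g)
        assert r1.estimate == pytest.approx(-r2.estimate)
        same = group_mean_difference(np.concatenate([x, x]), np.r_[np.zeros(40), np.ones(40)])
        assert same.p == pytest.approx(1.0)

    def test_group_shift_detected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.standard_normal(30), rng.standard_normal(30) + 2.0])
        g = np.r_[np.zeros(30), np.ones(30)]
        assert group_mean_difference(x, g).p < 1e-5


class TestPoolDatasets:
    def test_single_dataset_mean_centered(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.standard_normal((4, 10)) + 5.0)
        pooled = pool_datasets([ds])
        np.testing.assert_allclose(pooled.values.mean(axis=1), 0.0, atol=1e-12)

    def test_each_source_centered_after_pooling(self):
        rng = np.random.default_rng(6)
        a = make_dataset(rng.standard_normal((3, 8)) + 2.0, dataset_id="A")
        b = make_dataset(rng.standard_normal((3, 12)) - 7.0, dataset_id="B")
        pooled = pool_datasets([a, b])
        np.testing.assert_allclose(pooled.values[:, :8].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(pooled.values[:, 8:].mean(axis=1), 0.0, atol=1e-12)
        assert pooled.n_samples == 20

    def test_universe_mismatch_rejected(self):
        a = make_dataset(np.zeros((2, 4)) + [[0, 1, 2, 3]], gene_ids=["a", "b"])
        b = make_dataset(np.zeros((2, 4)) + [[0, 1, 2, 3]], gene_ids=["a", "c"])
        with pytest.raises(ValueError, match="mismatch"):
            pool_datasets([a, b])
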
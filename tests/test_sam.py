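import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import agnomap as ag
from agnomap.sam import (
    FESConfig,
    fit_svm_resub,
    hoeffding_delta,
    pls_extract,
    region_significance,
    sam_region,
    select_voxels,
    vapnik_delta,
    welch_t,
    worst_case_accuracy,
)


def _two_group_data(rng, n_per_group, n_vox, shift_voxel=None, shift=0.0):
    X = rng.normal(size=(2 * n_per_group, n_vox))
    y = np.array([-1.0] * n_per_group + [1.0] * n_per_group)
    if shift_voxel is not None:
        X[y > 0, shift_voxel] += shift
    return X, y


class TestSelectVoxels:
    def test_small_region_returns_all(self):
        rng = np.random.default_rng(0)
        X, y = _two_group_data(rng, 10, 30)
        assert len(select_voxels(X, y, k=50)) == 30

    def test_shifted_voxel_ranks_first(self):
        # oracle: brute-force Welch t per voxel via scipy
        rng = np.random.default_rng(1)
        X, y = _two_group_data(rng, 12, 5, shift_voxel=3, shift=4.0)
        sel = select_voxels(X, y, k=5)
        t_ref = np.array([
            stats.ttest_ind(X[y > 0, j], X[y <= 0, j], equal_var=False).statistic
            for j in range(5)
        ])
        assert sel[0] == 3
        assert list(sel) == list(np.argsort(-np.abs(t_ref), kind="stable"))

    def test_default_k_returns_50(self):
        rng = np.random.default_rng(2)
        X, y = _two_group_data(rng, 10, 120)
        assert len(select_voxels(X, y)) == 50

    def test_welch_t_matches_scipy(self):
        rng = np.random.default_rng(3)
        X, y = _two_group_data(rng, 8, 40)
        ref = stats.ttest_ind(X[y > 0], X[y <= 0], axis=0, equal_var=False).statistic
        assert np.allclose(welch_t(X, y), ref, atol=1e-12)

    def test_tiny_group_raises(self):
        X = np.ones((3, 4))
        y = np.array([1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="degenerate t-test"):
            select_voxels(X, y, 2)

    def test_label_swap_keeps_ranking(self):
        rng = np.random.default_rng(4)
        X, y = _two_group_data(rng, 9, 25, shift_voxel=5, shift=2.0)
        assert np.array_equal(select_voxels(X, y, 10), select_voxels(X, -y, 10))


class TestPLS:
    def test_single_feature_scores_are_centered_feature(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 1))
        y = np.array([-1.0] * 6 + [1.0] * 6)
        s = pls_extract(x, y, 1)
        xc = x[:, 0] - x[:, 0].mean()
        assert np.allclose(np.abs(s[:, 0]), np.abs(xc), atol=1e-12)

    def test_weights_match_cross_covariance_toy(self):
        # oracle: direct Xc^T y computation on a 4x2 matrix
        X = np.array([[1.0, 2.0], [2.0, 0.0], [3.0, 1.0], [4.0, 5.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        Xc = X - X.mean(axis=0)
        w = Xc.T @ y
        w /= np.linalg.norm(w)
        s = pls_extract(X, y, 1)
        assert np.allclose(s[:, 0], Xc @ w, atol=1e-10)

    def test_matches_sklearn_first_component(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(5)
        X, y = _two_group_data(rng, 15, 8, shift_voxel=0, shift=1.0)
        ours = pls_extract(X, y, 1)[:, 0]
        theirs = PLSRegression(n_components=1, scale=False).fit(X, y).x_scores_[:, 0]
        assert np.allclose(np.abs(ours), np.abs(theirs), atol=1e-8)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate features"):
            pls_extract(np.ones((6, 3)), np.array([-1, -1, -1, 1, 1, 1.0]), 1)


class TestSVMResub:
    def test_separable_scores_give_perfect_accuracy(self):
        s = np.array([-3.0, -2.0, -1.5, 1.0, 2.0, 3.0])
        y = np.array([-1, -1, -1, 1, 1, 1.0])
        assert fit_svm_resub(s, y) == 1.0

    def test_matches_best_threshold_oracle(self):
        # oracle: exhaustive search over all 1-D thresholds and orientations
        s = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([-1.0, 1.0, -1.0, 1.0])
        cuts = np.concatenate([[-np.inf], (s[:-1] + s[1:]) / 2, [np.inf]])
        best = max(
            max(np.mean(np.where(s > c, o, -o) == y) for c in cuts)
            for o in (1.0, -1.0)
        )
        emp = fit_svm_resub(s, y)
        assert best - 1.0 / len(y) <= emp <= best

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=400)
        y = rng.choice([-1.0, 1.0], size=400)
        assert abs(fit_svm_resub(s, y) - 0.5) < 0.08

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_svm_resub(np.arange(4.0), np.ones(4))


class TestWorstCase:
    def test_hoeffding_closed_form(self):
        # emp=1, n=50, alpha=0.05 -> delta = sqrt(ln(40)/100)
        delta = np.sqrt(np.log(40.0) / 100.0)
        assert worst_case_accuracy(1.0, 50, 0.05, bound="hoeffding") == \
            pytest.approx(1.0 - delta, abs=1e-12)

    def test_asymptotic_identity(self):
        assert hoeffding_delta(19000, 0.05) < 0.01
        assert worst_case_accuracy(0.9, 19000, 0.05, bound="hoeffding") > 0.89

    def test_never_exceeds_empirical(self):
        for bound in ("hoeffding", "vapnik"):
            for n in (10, 100, 1000):
                assert worst_case_accuracy(0.8, n, 0.05, bound) <= 0.8

    @given(st.integers(2, 5000), st.integers(2, 5000), st.floats(0.01, 0.3))
    @settings(max_examples=60, deadline=None)
    def test_delta_decreasing_in_n(self, n1, n2, alpha):
        lo, hi = sorted((n1, n2))
        if lo < hi:
            assert hoeffding_delta(hi, alpha) < hoeffding_delta(lo, alpha)
            assert vapnik_delta(hi, alpha) < vapnik_delta(lo, alpha) or hi < 8

    @given(st.integers(5, 5000), st.floats(0.01, 0.2), st.floats(0.21, 0.4))
    @settings(max_examples=60, deadline=None)
    def test_delta_increasing_as_alpha_shrinks(self, n, a_small, a_big):
        assert hoeffding_delta(n, a_small) > hoeffding_delta(n, a_big)
        assert vapnik_delta(n, a_small) > vapnik_delta(n, a_big)


class TestRegionSignificance:
    def test_chance_level_not_significant(self):
        z, sig = region_significance(0.5, 100)
        assert z == 0.0 and not sig

    def test_hand_computed_z(self):
        # (0.6 - 0.5)/sqrt(0.25/100) = 2.0 > 1.645
        z, sig = region_significance(0.6, 100, alpha=0.05)
        assert z == pytest.approx(2.0, abs=1e-12)
        assert sig

    def test_below_chance_never_significant(self):
        for w in (0.0, 0.2, 0.49, 0.5):
            _, sig = region_significance(w, 10000)
            assert not sig


class TestSamMap:
    def test_one_result_per_region(self, atlas116):
        spec = ag.EffectSpec(noise_sd=0.05)
        cohort, vols = ag.generate_cohort(atlas116, {"A": (10, 10)}, spec, seed=51)
        labels = np.where(cohort["group"] == "ASC", 1.0, -1.0)
        results = ag.sam_map(vols, labels, atlas116)
        assert len(results) == 116
        assert all(r.worst_accuracy <= r.emp_accuracy for r in results)

    def test_label_swap_leaves_decisions_unchanged(self, tiny_atlas):
        spec = ag.EffectSpec(noise_sd=0.05)
        cohort, vols = ag.generate_cohort(tiny_atlas, {"A": (8, 8)}, spec, seed=52)
        labels = np.where(cohort["group"] == "ASC", 1.0, -1.0)
        a = ag.sam_map(vols, labels, tiny_atlas)
        b = ag.sam_map(vols, -labels, tiny_atlas)
        for ra, rb in zip(a, b):
            assert ra.emp_accuracy == pytest.approx(rb.emp_accuracy, abs=1e-9)
            assert ra.significant == rb.significant

    def test_null_small_n_flags_nothing(self, tiny_atlas):
        # at n=40 the worst-case correction exceeds any attainable accuracy
        # excess, so the bound-corrected arm is fully conservative
        spec = ag.EffectSpec(noise_sd=0.05)
        cohort, vols = ag.generate_cohort(tiny_atlas, {"A": (20, 20)}, spec, seed=53)
        labels = np.where(cohort["group"] == "ASC", 1.0, -1.0)
        results = ag.sam_map(vols, labels, tiny_atlas)
        assert not any(r.significant for r in results)

    def test_planted_region_detected(self, tiny_atlas):
        rid = int(tiny_atlas.region_ids[2])
        spec = ag.EffectSpec(effect_regions=frozenset({rid}), effect_size_d=1.5,
                             noise_sd=0.05)
        cohort, vols = ag.generate_cohort(tiny_atlas, {"A": (100, 100)}, spec, seed=54)
        labels = np.where(cohort["group"] == "ASC", 1.0, -1.0)
        results = {r.region_id: r for r in ag.sam_map(vols, labels, tiny_atlas)}
        assert results[rid].significant
        assert results[rid].worst_accuracy == max(r.worst_accuracy for r in results.values())

    def test_chain_matches_manual_composition(self, tiny_atlas):
        spec = ag.EffectSpec(noise_sd=0.05)
        cohort, vols = ag.generate_cohort(tiny_atlas, {"A": (10, 10)}, spec, seed=55)
        labels = np.where(cohort["group"] == "ASC", 1.0, -1.0)
        rid = int(tiny_atlas.region_ids[0])
        region = vols.reshape(20, -1)[:, tiny_atlas.labels.ravel() == rid]
        fes = FESConfig()
        sel = select_voxels(region, labels, fes.k_voxels)
        scores = pls_extract(region[:, sel], labels, 1)
        emp = fit_svm_resub(scores, labels)
        got = sam_region(region, labels, fes)
        assert got[0] == pytest.approx(emp)
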
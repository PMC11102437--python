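"""Preprocessing, nested-CV decoding, and descriptive statistics."""

import numpy as np
import pytest
from scipy import stats as sps

import sdmd


class TestCommonAverageReference:
    def test_hand_example(self):
        sig = sdmd.TrialSignal(np.array([[1.0, 3.0, 0.0], [3.0, 5.0, 0.0]]), dt=1.0)
        out = sdmd.common_average_reference(sig)
        np.testing.assert_array_equal(out.values[:, :2], [[-1, -1], [1, 1]])

    def test_zero_mean_columns_unchanged(self):
        v = np.array([[1.0, -2.0, 0.5], [-1.0, 2.0, -0.5]])
        out = sdmd.common_average_reference(sdmd.TrialSignal(v, dt=1.0))
        np.testing.assert_allclose(out.values, v)

    def test_column_sums_vanish(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(5, 40))
        out = sdmd.common_average_reference(sdmd.TrialSignal(v, dt=1.0))
        assert np.max(np.abs(out.values.sum(axis=0))) <= 1e-12 * np.max(np.abs(v))

    def test_single_channel_rejected(self):
        with pytest.raises(sdmd.InvalidInputError):
            sdmd.common_average_reference(sdmd.TrialSignal(np.ones((1, 5)) + np.arange(5.0), dt=1.0))


class TestCrop:
    def test_500ms_window_at_1khz(self):
        sig = sdmd.TrialSignal(np.arange(2000.0).reshape(2, 1000), dt=1e-3)
        out = sdmd.crop(sig, 0.0, 0.5)
        assert out.n_samples == 500

    def test_full_window_is_identity(self):
        rng = np.random.default_rng(1)
        sig = sdmd.TrialSignal(rng.normal(size=(3, 100)), dt=1e-3)
        out = sdmd.crop(sig, 0.0, 0.1)
        np.testing.assert_array_equal(out.values, sig.values)

    def test_interior_window_index_arithmetic(self):
        sig = sdmd.TrialSignal(np.arange(1000.0)[None, :], dt=1e-3)
        out = sdmd.crop(sig, 0.1, 0.3)
        assert out.n_samples == 200
        assert out.values[0, 0] == 100.0

    def test_empty_window_rejected(self):
        sig = sdmd.TrialSignal(np.zeros((2, 100)) + np.arange(100.0), dt=1e-3)
        with pytest.raises(sdmd.InvalidInputError):
            sdmd.crop(sig, 0.09, 0.05)


class TestOversampleBalance:
    def test_counts_equalized(self):
        labels = np.array([0] * 10 + [1] * 5 + [2] * 5)
        idx = sdmd.oversample_balance(labels)
        np.testing.assert_array_equal(np.bincount(labels[idx]), [10, 10, 10])
        # all original indices retained
        assert set(range(20)) <= set(idx.tolist())

    def test_balanced_is_identity(self):
        labels = np.array([0, 1, 0, 1])
        np.testing.assert_array_equal(sdmd.oversample_balance(labels), np.arange(4))

    def test_cycling_repetition(self):
        labels = np.array([0, 0, 0, 1])
        idx = sdmd.oversample_balance(labels)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3, 3, 3])

    def test_empty_rejected(self):
        with pytest.raises(sdmd.InvalidInputError):
            sdmd.oversample_balance([])


class TestBalancedAccuracy:
    def test_perfect(self):
        assert sdmd.balanced_accuracy([0, 1, 2], [0, 1, 2]) == 1.0

    def test_constant_predictor_two_classes(self):
        assert sdmd.balanced_accuracy([0, 0, 1, 1], [0, 0, 0, 0]) == 0.5

    def test_per_class_recall_mean(self):
        assert sdmd.balanced_accuracy(list("AABB"), list("ABBB")) == pytest.approx(0.75)

    def test_matches_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 3, 50)
        pred = rng.integers(0, 3, 50)
        assert sdmd.balanced_accuracy(truth, pred) == pytest.approx(
            balanced_accuracy_score(truth, pred)
        )

    def test_unseen_class_rejected(self):
        with pytest.raises(sdmd.InvalidInputError):
            sdmd.balanced_accuracy([0, 0], [0, 5])


class TestFoldConstruction:
    def test_outer_partition_property(self):
        labels = np.repeat([0, 1, 2], 12)
        splits = sdmd.decoding.kfold_splits(labels, 4, seed=3)
        seen = np.concatenate([te for _, te in splits])
        assert sorted(seen.tolist()) == list(range(36))
        for tr, te in splits:
            assert set(tr) | set(te) == set(range(36))
            assert not set(tr) & set(te)
            # stratification keeps per-fold class counts balanced
            np.testing.assert_array_equal(np.bincount(labels[te]), [3, 3, 3])

    def test_sequential_blocks_are_contiguous(self):
        splits = sdmd.decoding.kfold_splits(np.zeros(10), 3, mode="sequential-blocks")
        tests = [te for _, te in splits]
        for te in tests:
            np.testing.assert_array_equal(te, np.arange(te[0], te[-1] + 1))
        assert sorted(np.concatenate(tests).tolist()) == list(range(10))


class TestNestedCVClassification:
    def test_separable_set_decodes_above_90(self, small_trialset, small_scheme):
        pipe = sdmd.FeaturePipeline(small_trialset, feature="sndm")
        model = sdmd.ModelSpec(kind="linear-svm", cost_grid=(1.0, 100.0), rank_grid=(4,))
        res = sdmd.nested_cv_classify(pipe, model, small_scheme)
        assert res.mean_score > 0.9
        assert np.all((res.scores >= 0) & (res.scores <= 1))
        assert set(res.selected("cost")) <= {1.0, 100.0}
        assert "balanced accuracy" in res.summary()

    def test_logistic_l1_also_separates(self, small_trialset, small_scheme):
        pipe = sdmd.FeaturePipeline(small_trialset, feature="sndm")
        model = sdmd.ModelSpec(kind="logistic-l1", cost_grid=(1.0, 100.0), rank_grid=(4,))
        res = sdmd.nested_cv_classify(pipe, model, small_scheme)
        assert res.mean_score > 0.9

    def test_kernel_and_linear_svm_predict_identically(self, small_trialset, small_scheme):
        """Kernel SVM on the Gram matrix and linear SVM on the explicit
        feature map are the same classifier: labels agree on every fold."""
        pipe = sdmd.FeaturePipeline(small_trialset, feature="sdm")
        mk = sdmd.ModelSpec(kind="kernel-svm", cost_grid=(10.0,), rank_grid=(4,))
        ml = sdmd.ModelSpec(kind="linear-svm", cost_grid=(10.0,), rank_grid=(4,))
        rk = sdmd.nested_cv_classify(pipe, mk, small_scheme)
        rl = sdmd.nested_cv_classify(pipe, ml, small_scheme)
        for a, b in zip(rk.fold_predictions, rl.fold_predictions):
            np.testing.assert_array_equal(a["test_idx"], b["test_idx"])
            np.testing.assert_array_equal(a["predicted"], b["predicted"])
        assert rk.mean_score == rl.mean_score

    def test_permuted_labels_sit_at_chance(self, small_trialset, small_scheme):
        rng = np.random.default_rng(4)
        perm = sdmd.TrialSet(
            trials=small_trialset.trials,
            labels=rng.permutation(small_trialset.labels),
        )
        pipe = sdmd.FeaturePipeline(perm, feature="sndm")
        model = sdmd.ModelSpec(kind="linear-svm", cost_grid=(1.0,), rank_grid=(4,))
        res = sdmd.nested_cv_classify(pipe, model, small_scheme)
        assert 0.25 <= res.mean_score <= 0.42  # chance for 3 classes

    def test_degenerate_folds_rejected(self):
        spec = sdmd.TrialSetSpec(n_classes=2, trials_per_class=3,
                                 n_channels=4, n_samples=50, seed=0)
        ts = sdmd.make_trial_set(spec)
        pipe = sdmd.FeaturePipeline(ts)
        with pytest.raises(sdmd.InvalidInputError):
            sdmd.nested_cv_classify(
                pipe,
                sdmd.ModelSpec(cost_grid=(1.0,), rank_grid=(2,)),
                sdmd.CVScheme(n_outer=5, outer_repeats=1, n_inner=2,
                              inner_repeats=1),
            )


@pytest.fixture(scope="module")
def planted(small_trialset):
    """Targets generated linearly from snDM features plus small noise."""
    base = sdmd.FeaturePipeline(small_trialset, feature="sndm")
    F = base.features(4)
    rng = np.random.default_rng(7)
    w = rng.normal(size=F.shape[1])
    y = F @ w
    y = y + 0.05 * y.std() * rng.normal(size=len(y))
    return sdmd.TrialSet(trials=small_trialset.trials, targets=y[:, None]), rng


class TestNestedCVRegression:
    def test_planted_linear_model_recovered(self, planted):
        ts, _ = planted
        pipe = sdmd.FeaturePipeline(ts, feature="sndm")
        model = sdmd.ModelSpec(kind="ridge", lambda_grid=(1e-4, 1e-2, 1.0, 100.0),
                               rank_grid=(4,))
        scheme = sdmd.CVScheme(n_outer=3, outer_repeats=1, n_inner=2, inner_repeats=1)
        res = sdmd.nested_cv_regress(pipe, model, scheme)
        assert res.mean_correlation > 0.9
        assert "Fisher-z" in res.summary()

    def test_independent_targets_near_zero(self, small_trialset):
        rng = np.random.default_rng(8)
        ts = sdmd.TrialSet(trials=small_trialset.trials,
                           targets=rng.normal(size=(small_trialset.n_trials, 2)))
        pipe = sdmd.FeaturePipeline(ts, feature="sndm")
        model = sdmd.ModelSpec(kind="ridge", lambda_grid=(1e-2, 1.0, 100.0),
                               rank_grid=(4,))
        scheme = sdmd.CVScheme(n_outer=3, outer_repeats=1, n_inner=2, inner_repeats=1)
        res = sdmd.nested_cv_regress(pipe, model, scheme)
        assert abs(res.mean_score) < 0.25

    def test_lambda_grid_default_cardinality(self):
        assert len(sdmd.ModelSpec(kind="ridge").lambda_grid) == 17

    def test_ridge_infinite_penalty_predicts_training_mean(self):
        from sklearn.linear_model import Ridge
        rng = np.random.default_rng(9)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        reg = Ridge(alpha=1e12).fit(X, y)
        np.testing.assert_allclose(reg.predict(X), y.mean(), atol=1e-6)


class TestReproducibility:
    def test_scaled_copies_give_clipped_large_z(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        F = np.vstack([base, 2 * base, 5 * base])
        z = sdmd.reproducibility(F, [0, 0, 0])
        assert z > 10.0  # r = 1 pairs, clipped atanh

    def test_anticorrelated_pair(self):
        z = sdmd.reproducibility(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]), [0, 0])
        assert z == pytest.approx(sdmd.fisher_z(-1.0))

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(10)
        F = rng.normal(size=(30, 256))  # 435 same-class pairs
        z = sdmd.reproducibility(F, np.zeros(30))
        assert abs(z) < 0.05

    def test_zero_variance_rows_skipped_with_warning(self):
        F = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [2.0, 4.0, 7.0]])
        with pytest.warns(RuntimeWarning):
            z = sdmd.reproducibility(F, [0, 0, 0])
        # only the pair (1, 2) survives
        expected = sdmd.fisher_z(np.corrcoef([1, 2, 3], [2, 4, 7])[0, 1])
        assert z == pytest.approx(expected)


class TestAnovaFMap:
    def test_equal_group_means_give_zero(self):
        F = np.array([[1.0], [2.0], [1.0], [2.0]])
        np.testing.assert_allclose(sdmd.anova_f_map(F, [0, 0, 1, 1]), [0.0], atol=1e-12)

    def test_textbook_two_group_example(self):
        F = np.array([[1.0], [2.0], [5.0], [6.0]])
        np.testing.assert_allclose(sdmd.anova_f_map(F, [0, 0, 1, 1]), [32.0])

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(11)
        F = rng.normal(size=(24, 7))
        labels = np.repeat([0, 1, 2], 8)
        ours = sdmd.anova_f_map(F, labels)
        ref = sps.f_oneway(F[:8], F[8:16], F[16:]).statistic
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_null_mean_near_one(self):
        rng = np.random.default_rng(12)
        F = rng.normal(size=(60, 2000))
        labels = np.repeat([0, 1, 2], 20)
        fmap = sdmd.anova_f_map(F, labels)
        # E[F] = dfW / (dfW - 2) = 57/55 under the null
        assert abs(fmap.mean() - 1.0) < 0.2

    def test_zero_within_group_variance_inf(self):
        F = np.array([[1.0], [1.0], [2.0], [2.0]])
        with pytest.warns(RuntimeWarning):
            out = sdmd.anova_f_map(F, [0, 0, 1, 1])
        assert np.isinf(out[0])


class TestFeaturePSDCorrelation:
    def test_identical_broadcast_gives_r_one(self):
        rng = np.random.default_rng(13)
        sndm = rng.normal(size=(10, 4))
        S = np.repeat(sndm[:, :, None], 6, axis=2)
        z = sdmd.feature_psd_correlation(sndm, S)
        assert np.all(z > 10.0)  # r = 1 at every bin, clipped

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(14)
        sndm = rng.normal(size=(40, 16))
        S = rng.normal(size=(40, 16, 20)) ** 2
        z = sdmd.feature_psd_correlation(sndm, S)
        assert np.max(np.abs(z)) < 0.15
        assert abs(np.mean(z)) < 0.05

    def test_class_structure_peaks_in_its_band(self, small_trialset):
        """Trials whose class structure lives in a 110-Hz component show the
        strongest snDM-PSD coupling inside the high-gamma band."""
        pipe = sdmd.FeaturePipeline(small_trialset, feature="sndm")
        sndm = pipe.features(4)
        powers = [sdmd.psd(t) for t in small_trialset.trials]
        S = np.stack([p.psd for p in powers])
        freqs = powers[0].frequencies
        z = sdmd.feature_psd_correlation(sndm, S)
        gamma = (freqs >= 80) & (freqs < 150)
        assert z[gamma].max() == z[np.isfinite(z)].max()
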
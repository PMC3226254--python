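import numpy as np
import pytest

from cnvnet import (DataError, LRRMatrix, cross_validate, fit_centroids,
                    predict, predict_matrix, rank_features, shrink)


def random_matrix(seed, n_per_class=(8, 8, 8), p=20):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(c, k + 1)
                             for k, c in enumerate(n_per_class)])
    values = rng.normal(size=(labels.size, p))
    return LRRMatrix(values=values, labels=labels,
                     sample_ids=[f"s{i}" for i in range(labels.size)],
                     feature_ids=[f"f{j}" for j in range(p)])


class TestFitCentroids:
    def test_hand_computed_two_class_example(self):
        # classes (2,2), one feature: independent scalar arithmetic below
        # re-executes the defining formulas step by step.
        m = LRRMatrix(values=np.array([[0.0], [0.2], [1.0], [1.2]]),
                      labels=np.array([1, 1, 2, 2]),
                      sample_ids=list("abcd"), feature_ids=["f"])
        fit = fit_centroids(m)
        n, k = 4, 2
        mk = np.sqrt(1 / 2 + 1 / 4)
        xbar_1, xbar_2, xbar = 0.1, 1.1, 0.6
        ss = (0.1 ** 2 + 0.1 ** 2) * 2  # within-class squared deviations
        s = np.sqrt(ss / (n - k))
        s0 = s  # single feature -> median of {s} is s itself
        d1 = (xbar_1 - xbar) / (mk * (s + s0))
        d2 = (xbar_2 - xbar) / (mk * (s + s0))
        np.testing.assert_allclose(fit.class_centroids,
                                   [[xbar_1], [xbar_2]])
        assert fit.overall_centroid == pytest.approx([xbar])
        assert fit.pooled_sd == pytest.approx([s], abs=1e-12)
        np.testing.assert_allclose(fit.d, [[d1], [d2]], atol=1e-12)

    def test_constant_feature_has_zero_d(self, toy_lrr_frame):
        values = toy_lrr_frame.values.copy()
        values[:, 0] = 0.7
        m = LRRMatrix(values=values, labels=toy_lrr_frame.labels,
                      sample_ids=toy_lrr_frame.sample_ids,
                      feature_ids=toy_lrr_frame.feature_ids)
        fit = fit_centroids(m)
        assert fit.d[:, 0] == pytest.approx([0.0, 0.0])

    def test_class_relabeling_permutes_d_rows(self):
        m = random_matrix(0)
        fit = fit_centroids(m)
        # swap class codes 1 <-> 3
        relabeled = np.select([m.labels == 1, m.labels == 3],
                              [3, 1], m.labels)
        m2 = LRRMatrix(values=m.values, labels=relabeled,
                       sample_ids=m.sample_ids, feature_ids=m.feature_ids)
        fit2 = fit_centroids(m2)
        np.testing.assert_allclose(fit2.d, fit.d[[2, 1, 0]])

    def test_location_invariance_of_d(self):
        m = random_matrix(1)
        fit = fit_centroids(m)
        shifted = m.values.copy()
        shifted[:, 3] += 17.5
        fit2 = fit_centroids(LRRMatrix(values=shifted, labels=m.labels,
                                       sample_ids=m.sample_ids,
                                       feature_ids=m.feature_ids))
        np.testing.assert_allclose(fit2.d, fit.d, atol=1e-10)

    def test_small_class_rejected(self):
        m = LRRMatrix(values=np.zeros((3, 2)), labels=np.array([1, 1, 2]),
                      sample_ids=list("abc"), feature_ids=["f1", "f2"])
        with pytest.raises(DataError, match="class 2"):
            fit_centroids(m)

    def test_mk_variants(self):
        m = random_matrix(2, n_per_class=(10, 6))
        plus = fit_centroids(m, mk_variant="plus")
        minus = fit_centroids(m, mk_variant="minus")
        n = 16
        np.testing.assert_allclose(plus.mk,
                                   np.sqrt([1 / 10 + 1 / n, 1 / 6 + 1 / n]))
        np.testing.assert_allclose(minus.mk,
                                   np.sqrt([1 / 10 - 1 / n, 1 / 6 - 1 / n]))


class TestShrink:
    def test_zero_delta_is_identity(self):
        fit = fit_centroids(random_matrix(3))
        sfit = shrink(fit, 0.0)
        np.testing.assert_allclose(sfit.d_shrunk, fit.d)
        np.testing.assert_allclose(sfit.shrunken_centroids,
                                   fit.class_centroids, atol=1e-12)

    def test_full_shrinkage_collapses_to_overall(self):
        fit = fit_centroids(random_matrix(4))
        sfit = shrink(fit, float(np.abs(fit.d).max()) + 0.1)
        assert (sfit.d_shrunk == 0).all()
        for row in sfit.shrunken_centroids:
            np.testing.assert_allclose(row, fit.overall_centroid)
        assert sfit.selected_features == []

    @pytest.mark.parametrize("d, delta, expected", [
        (2.0, 0.5, 1.5),
        (-0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
    ])
    def test_soft_threshold_definition(self, d, delta, expected):
        assert np.sign(d) * max(abs(d) - delta, 0) == pytest.approx(expected)
        fit = fit_centroids(random_matrix(5))
        sfit = shrink(fit, delta)
        manual = np.sign(fit.d) * np.maximum(np.abs(fit.d) - delta, 0)
        np.testing.assert_allclose(sfit.d_shrunk, manual)

    def test_negative_delta_rejected(self):
        with pytest.raises(DataError):
            shrink(fit_centroids(random_matrix(6)), -0.1)

    def test_selected_count_non_increasing_along_grid(self):
        # 50 random instances x ascending grids
        for seed in range(50):
            fit = fit_centroids(random_matrix(seed, n_per_class=(6, 6), p=15))
            grid = np.linspace(0, np.abs(fit.d).max() * 1.1, 12)
            counts = [int(shrink(fit, d).selected_mask.sum()) for d in grid]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPredict:
    def test_sample_at_class_centroid_wins(self):
        fit = fit_centroids(random_matrix(7))
        sfit = shrink(fit, 0.0)
        label, scores = predict(sfit, sfit.shrunken_centroids[0])
        assert label == fit.class_labels[0]
        assert scores[0] == min(scores)

    def test_fully_shrunk_model_decides_by_prior(self):
        m = random_matrix(8, n_per_class=(18, 2))
        fit = fit_centroids(m)
        sfit = shrink(fit, float(np.abs(fit.d).max()) + 1)
        rng = np.random.default_rng(0)
        for _ in range(5):
            label, _ = predict(sfit, rng.normal(size=m.n_features))
            assert label == 1  # majority-prior class

    def test_matches_bruteforce_score_enumeration(self):
        m = random_matrix(9, n_per_class=(7, 7, 7), p=20)
        fit = fit_centroids(m)
        sfit = shrink(fit, 0.4)
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.normal(size=20)
            label, scores = predict(sfit, t)
            # independent loop re-evaluation of the discriminant
            expected = []
            for k in range(3):
                s = sum((t[i] - sfit.shrunken_centroids[k, i]) ** 2
                        / (fit.pooled_sd[i] + fit.s0) ** 2
                        for i in range(20)) - 2 * np.log(fit.priors[k])
                expected.append(s)
            assert scores == pytest.approx(expected, rel=1e-10)
            assert label == fit.class_labels[int(np.argmin(expected))]

    def test_zero_delta_equals_plain_nearest_centroid(self):
        # shrink(fit, 0) + predict == unshrunken-centroid discriminant
        m = random_matrix(10, n_per_class=(8, 8), p=10)
        fit = fit_centroids(m)
        sfit = shrink(fit, 0.0)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 10))
        pred = predict_matrix(sfit, x)
        denom = (fit.pooled_sd + fit.s0) ** 2
        oracle = []
        for row in x:
            scores = [((row - fit.class_centroids[k]) ** 2 / denom).sum()
                      - 2 * np.log(fit.priors[k]) for k in range(2)]
            oracle.append(fit.class_labels[int(np.argmin(scores))])
        np.testing.assert_array_equal(pred, oracle)

    def test_shape_mismatch_rejected(self):
        sfit = shrink(fit_centroids(random_matrix(11)), 0.0)
        with pytest.raises(DataError):
            predict(sfit, np.zeros(3))


class TestCrossValidate:
    def test_deterministic_under_fixed_seed(self, strong_cohort):
        m = strong_cohort.to_lrr_matrix()
        c1 = cross_validate(m, n_folds=5, seed=42)
        c2 = cross_validate(m, n_folds=5, seed=42)
        np.testing.assert_array_equal(c1.delta_grid, c2.delta_grid)
        np.testing.assert_array_equal(c1.accuracy, c2.accuracy)
        np.testing.assert_array_equal(c1.n_selected, c2.n_selected)
        assert c1.best_delta == c2.best_delta

    def test_zero_signal_accuracy_near_chance(self, null_cohort):
        m = null_cohort.to_lrr_matrix()
        curve = cross_validate(m, n_folds=10, seed=0)
        # binomial noise around max prior 0.5 at n = 120
        assert (np.abs(curve.accuracy - 0.5)
                < 4 * np.sqrt(0.25 / m.n_samples) + 1e-9).all()

    def test_strong_signal_reaches_high_accuracy(self, strong_cohort):
        m = strong_cohort.to_lrr_matrix()
        curve = cross_validate(m, n_folds=10, seed=0)
        assert curve.accuracy.max() >= 0.95

    def test_n_selected_non_increasing(self, strong_cohort):
        curve = cross_validate(strong_cohort.to_lrr_matrix(), n_folds=5,
                               seed=1)
        assert (np.diff(curve.n_selected) <= 0).all()

    def test_class_too_small_to_stratify(self):
        m = random_matrix(12, n_per_class=(3, 12))
        with pytest.raises(DataError, match="class 1"):
            cross_validate(m, n_folds=5, seed=0)


class TestRankFeatures:
    def test_fully_shrunk_gives_empty_ranking(self):
        fit = fit_centroids(random_matrix(13))
        sfit = shrink(fit, float(np.abs(fit.d).max()) + 1)
        assert rank_features(sfit) == []

    def test_descending_order_matches_resort_oracle(self):
        fit = fit_centroids(random_matrix(14, p=30))
        sfit = shrink(fit, 0.3)
        ranking = rank_features(sfit)
        scores = {f: s for f, s in ranking}
        oracle = np.abs(sfit.d_shrunk).max(axis=0)
        for (f, s) in ranking:
            j = fit.feature_ids.index(f)
            assert s == pytest.approx(oracle[j])
        vals = [s for _, s in ranking]
        assert vals == sorted(vals, reverse=True)
        # only selected features listed
        assert set(scores) == set(sfit.selected_features)
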
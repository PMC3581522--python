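import numpy as np
import pandas as pd
import pytest

from refclust import (CohortManifest, MaskVolume, VolumeImage,
                      compare_distributions, extract_pattern_means, fit_logistic,
                      pattern_overlap, split_half_cv)
from refclust.classify import ClassificationError, compare_sens_spec


def manifest(n0, n1):
    n = n0 + n1
    return CohortManifest(pd.DataFrame(
        {"id": [f"s{i}" for i in range(n)],
         "group": ["control"] * n0 + ["patient"] * n1,
         "age": 60.0 + np.arange(n), "sex": [i % 2 for i in range(n)],
         "path": [""] * n}))


class TestExtractPatternMeans:
    def test_constant_volumes(self):
        m = manifest(2, 2)
        vols = [VolumeImage(np.ones((3, 3, 3))) for _ in range(4)]
        pattern = MaskVolume(np.ones((3, 3, 3), bool))
        feats = extract_pattern_means(vols, pattern, m)
        np.testing.assert_allclose(feats["mean_uptake"], 1.0)

    def test_single_voxel_pattern(self, rng):
        m = manifest(2, 2)
        vols = [VolumeImage(rng.normal(size=(3, 3, 3))) for _ in range(4)]
        pat = np.zeros((3, 3, 3), bool)
        pat[1, 2, 0] = True
        feats = extract_pattern_means(vols, MaskVolume(pat), m)
        for v, f in zip(vols, feats["mean_uptake"]):
            assert f == v.data[1, 2, 0]

    def test_empty_pattern_rejected(self):
        with pytest.raises(ClassificationError, match="empty"):
            extract_pattern_means([VolumeImage(np.ones((3, 3, 3)))] * 4,
                                  MaskVolume(np.zeros((3, 3, 3), bool)), manifest(2, 2))


class TestPatternOverlap:
    def test_identical_masks(self, rng):
        m = MaskVolume(rng.random((4, 4, 4)) > 0.5)
        np.testing.assert_array_equal(pattern_overlap([m, m]).data, m.data)

    def test_disjoint_masks_rejected(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        with pytest.raises(ClassificationError, match="intersection"):
            pattern_overlap([MaskVolume(a), MaskVolume(b)])

    def test_subset_returns_smaller(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :2] = True
        b[0] = True
        np.testing.assert_array_equal(pattern_overlap([MaskVolume(a), MaskVolume(b)]).data, a)


class TestFitLogistic:
    def test_separable_training_is_perfect(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        y = x.astype(int)
        model = fit_logistic(x, y)
        np.testing.assert_array_equal(model.predict(x), y)

    def test_constant_feature_predicts_majority(self):
        x = np.zeros(10)
        y = np.array([1] * 7 + [0] * 3)
        model = fit_logistic(x, y)
        assert (model.predict(x) == 1).all()
        # intercept is the log-odds of the majority class
        assert model.intercept == pytest.approx(np.log(7 / 3), abs=1e-6)

    def test_symmetric_data_centers_boundary(self):
        x = np.array([-1.0, -1.1, -0.9, 1.0, 1.1, 0.9])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(x, y)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        assert model.slope > 0

    def test_single_class_rejected(self):
        with pytest.raises(ClassificationError, match="both classes"):
            fit_logistic(np.arange(4.0), np.ones(4, int))


class TestSplitHalfCV:
    def test_perfect_separation_every_repetition(self):
        x = np.r_[np.zeros(6), np.ones(6)]
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        dist = split_half_cv(x, y, n_rep=50, seed=0)
        np.testing.assert_allclose(dist.accuracy, 1.0)
        np.testing.assert_allclose(dist.sensitivity, 1.0)
        np.testing.assert_allclose(dist.specificity, 1.0)

    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.normal(size=20)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        a = split_half_cv(x, y, n_rep=100, seed=5)
        b = split_half_cv(x, y, n_rep=100, seed=5)
        np.testing.assert_array_equal(a.accuracy, b.accuracy)
        np.testing.assert_array_equal(a.sensitivity, b.sensitivity)

    def test_accuracy_identity_per_repetition(self, rng):
        """accuracy == (sens * n_pat_test + spec * n_ctl_test) / n_test, exactly;
        odd class counts send the extra subject to training."""
        n0, n1 = 7, 5  # test halves: 3 controls, 2 patients
        x = rng.normal(size=n0 + n1) + np.r_[np.zeros(n0), np.ones(n1)]
        y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        dist = split_half_cv(x, y, n_rep=200, seed=1)
        recomputed = (dist.sensitivity * 2 + dist.specificity * 3) / 5
        np.testing.assert_allclose(dist.accuracy, recomputed, atol=1e-12)

    def test_label_swap_exchanges_sensitivity_and_specificity(self, rng):
        x = rng.normal(size=24) + np.r_[np.zeros(12), np.ones(12)]
        y = np.r_[np.zeros(12, int), np.ones(12, int)]
        a = split_half_cv(x, y, n_rep=3000, seed=2)
        b = split_half_cv(x, 1 - y, n_rep=3000, seed=2)
        assert a.sensitivity.mean() == pytest.approx(b.specificity.mean(), abs=0.02)
        assert a.specificity.mean() == pytest.approx(b.sensitivity.mean(), abs=0.02)

    def test_small_class_rejected(self):
        with pytest.raises(ClassificationError, match="2 subjects"):
            split_half_cv(np.arange(4.0), np.array([0, 0, 0, 1]), n_rep=10, seed=0)


class TestCompareDistributions:
    def _dist(self, values, name):
        from refclust import AccuracyDistribution
        v = np.asarray(values, float)
        return AccuracyDistribution(v, v, v, len(v), 0, name)

    def test_self_comparison_not_significant(self, rng):
        a = self._dist(0.8 + 0.02 * rng.standard_normal(500), "a")
        out = compare_distributions([a, a])
        assert out.loc[0, "p"] == 1.0 and not out.loc[0, "significant"]

    def test_large_offset_significant(self, rng):
        a = self._dist(0.70 + 0.01 * rng.standard_normal(500), "a")
        b = self._dist(0.90 + 0.01 * rng.standard_normal(500), "b")
        out = compare_distributions([a, b])
        assert out.loc[0, "significant"]

    def test_bonferroni_counts_pairs(self, rng):
        dists = [self._dist(0.8 + 0.02 * rng.standard_normal(100), s)
                 for s in ("cgm", "cbl", "smc", "rc")]
        out = compare_distributions(dists)
        assert len(out) == 6
        ok = out["p"] < 1.0 / 6
        np.testing.assert_allclose(out.loc[ok, "p_bonferroni"], out.loc[ok, "p"] * 6)

    def test_mismatched_n_rep_rejected(self, rng):
        a = self._dist(rng.random(100), "a")
        b = self._dist(rng.random(99), "b")
        with pytest.raises(ClassificationError, match="n_rep"):
            compare_distributions([a, b])

    def test_sens_vs_spec_within_scheme(self, rng):
        from refclust import AccuracyDistribution
        sens = 0.7 + 0.01 * rng.standard_normal(500)
        spec = 0.9 + 0.01 * rng.standard_normal(500)
        d = AccuracyDistribution((sens + spec) / 2, sens, spec, 500, 0, "rc")
        out = compare_sens_spec(d)
        assert out["significant"] and out["t"] < 0
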
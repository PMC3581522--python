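import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refclust import (CohortManifest, MaskVolume, VolumeImage, build_design,
                      connected_components, fit_glm, voxel_fwe_threshold)
from refclust.glm import (DesignError, InferenceError, _group_relabelings,
                          _null_distributions, _t_from_Y, filter_clusters,
                          permutation_threshold, stack_cohort)


def manifest(groups, ages=None, sexes=None):
    n = len(groups)
    ages = list(ages) if ages is not None else list(60.0 + np.arange(n))
    sexes = list(sexes) if sexes is not None else [i % 2 for i in range(n)]
    return CohortManifest(pd.DataFrame(
        {"id": [f"s{i}" for i in range(n)], "group": groups,
         "age": ages, "sex": sexes, "path": [""] * n}))


def volumes_from_matrix(Y, shape):
    """One subject volume per row of Y, values laid out over the first voxels."""
    vols = []
    for row in Y:
        data = np.full(shape, np.nan)
        data.ravel()[: row.size] = row
        vols.append(VolumeImage(data))
    return vols


class TestBuildDesign:
    def test_full_design(self):
        m = manifest(["control"] * 3 + ["patient"] * 3)
        d = build_design(m)
        assert d.matrix.shape == (6, 4)
        assert d.columns == ["intercept", "group", "age", "sex"]
        assert np.allclose(d.matrix[:, d.columns.index("age")].mean(), 0.0)
        np.testing.assert_array_equal(d.contrast("decrease"), [0, -1, 0, 0])
        np.testing.assert_array_equal(d.contrast("increase"), [0, 1, 0, 0])

    def test_constant_sex_dropped(self):
        m = manifest(["control"] * 3 + ["patient"] * 3, sexes=[1] * 6)
        d = build_design(m)
        assert d.matrix.shape == (6, 3) and d.dropped == ["sex"]

    def test_single_group_rejected(self):
        with pytest.raises(Exception):
            manifest(["control"] * 6)


class TestFitGlm:
    def test_pooled_two_sample_t(self):
        """{1,2,3} vs {4,5,6}: pooled t = 3.674..., df = 4."""
        m = manifest(["control"] * 3 + ["patient"] * 3,
                     ages=[60.0] * 6, sexes=[0] * 6)  # covariates drop
        vols = volumes_from_matrix(np.array([[1], [2], [3], [4], [5], [6]], float),
                                   (2, 2, 2))
        res = fit_glm(vols, build_design(m), "increase")
        t = res.t_map[0, 0, 0]
        assert res.df == 4
        assert t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert round(t, 3) == 3.674

    def test_identical_groups_give_zero(self):
        m = manifest(["control"] * 3 + ["patient"] * 3, ages=[60.0] * 6, sexes=[0] * 6)
        Y = np.tile(np.array([[1.0, 2.0, 5.0]]), (6, 1))
        Y[3:] = Y[:3]
        res = fit_glm(volumes_from_matrix(Y, (2, 2, 2)), build_design(m), "increase")
        np.testing.assert_allclose(res.t_values, 0.0, atol=1e-12)

    def test_matches_statsmodels_per_voxel(self, rng):
        """Independent oracle: statsmodels OLS voxel by voxel."""
        sm = pytest.importorskip("statsmodels.api")
        n, V = 20, 20
        m = manifest(["control"] * 10 + ["patient"] * 10,
                     ages=rng.normal(62, 8, n), sexes=rng.integers(0, 2, n))
        d = build_design(m)
        Y = rng.normal(size=(n, V))
        res = fit_glm(volumes_from_matrix(Y, (3, 3, 3)), d, "increase")
        c = d.contrast("increase")
        for v in range(V):
            fit = sm.OLS(Y[:, v], d.matrix).fit()
            tt = fit.t_test(c)
            assert res.t_values[v] == pytest.approx(
                float(np.asarray(tt.tvalue).squeeze()), abs=1e-8)

    def test_zero_variance_sentinel(self):
        m = manifest(["control"] * 3 + ["patient"] * 3, ages=[60.0] * 6, sexes=[0] * 6)
        Y = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        res = fit_glm(volumes_from_matrix(Y, (2, 2, 2)), build_design(m), "increase")
        assert res.t_map[0, 0, 0] == np.inf
        assert res.zero_variance_mask[0, 0, 0]

    def test_row_mismatch_rejected(self, rng):
        m = manifest(["control"] * 3 + ["patient"] * 3, ages=[60.0] * 6, sexes=[0] * 6)
        vols = volumes_from_matrix(rng.normal(size=(5, 4)), (2, 2, 2))
        with pytest.raises(DesignError, match="rows"):
            fit_glm(vols, build_design(m), "increase")

    def test_analysis_mask_excludes_nonfinite(self, rng):
        Y = rng.normal(size=(6, 8))
        vols = volumes_from_matrix(Y, (2, 2, 2))
        vols[2].data[1, 1, 1] = np.nan
        _, analysis = stack_cohort(vols)
        assert not analysis.data[1, 1, 1]
        assert analysis.data.sum() == 7


class TestConnectedComponents:
    def test_solid_block(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        cs = connected_components(m, 18)
        assert len(cs.clusters) == 1 and cs.clusters[0].size == 27

    def test_edge_neighbors(self):
        # (0,0,0) and (0,1,1) share an edge: one cluster at 18, two at 6
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[0, 1, 1] = True
        assert len(connected_components(m, 18).clusters) == 1
        assert len(connected_components(m, 6).clusters) == 2

    def test_corner_neighbors(self):
        # (0,0,0) and (1,1,1) share only a corner: two at 18, one at 26
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        assert len(connected_components(m, 18).clusters) == 2
        assert len(connected_components(m, 26).clusters) == 1

    def test_sizes_sorted_descending_with_peaks(self, rng):
        m = np.zeros((10, 10, 10), bool)
        m[:2, :2, :2] = True   # 8 voxels
        m[6:9, 6:9, 6:9] = True  # 27 voxels
        t_map = rng.normal(size=(10, 10, 10))
        cs = connected_components(m, 6, t_map=t_map)
        assert [c.size for c in cs.clusters] == [27, 8]
        big = cs.clusters[0]
        assert t_map[big.peak_ijk] == big.peak_t
        assert abs(big.peak_t) == np.abs(t_map[6:9, 6:9, 6:9]).max()

    def test_extent_filter_respects_k_min(self):
        """A true cluster of 99 voxels is excluded at k_min=100."""
        m = np.zeros((12, 12, 12), bool)
        m.ravel()[:99] = True  # contiguous 99-voxel slab
        cs = connected_components(m, 26)
        assert cs.clusters[0].size == 99
        assert filter_clusters(cs, k_min=100).clusters == []
        assert len(filter_clusters(cs, k_min=99).clusters) == 1
        assert filter_clusters(cs, k_min=99, strict_extent=True).clusters == []


class TestPermutations:
    def test_exhaustive_relabelings_3v3(self):
        group = np.array([0, 0, 0, 1, 1, 1], float)
        labelings, exhaustive = _group_relabelings(group, 1000, np.random.default_rng(0))
        assert exhaustive and len(labelings) == 20
        assert {tuple(g) for g in labelings} == {
            tuple(1.0 if i in c else 0.0 for i in range(6))
            for c in itertools.combinations(range(6), 3)}

    def test_permutation_pvalues_match_enumeration(self, rng):
        """3v3 single-voxel problem: the permutation null equals the exact
        enumeration of all 20 relabelings computed with the textbook pooled t."""
        y = np.array([3.1, 0.2, -1.4, 4.9, 5.3, 2.8])
        m = manifest(["control"] * 3 + ["patient"] * 3, ages=[60.0] * 6, sexes=[0] * 6)
        d = build_design(m)
        null = _null_distributions(y[:, None], d, d.contrast("increase"),
                                   n_perm=1000, rng=np.random.default_rng(0))
        assert null.exhaustive and null.n == 20

        def pooled_t(y, idx_pat):
            a = y[[i for i in range(6) if i not in idx_pat]]
            b = y[list(idx_pat)]
            sp2 = ((a - a.mean()) ** 2).sum() / 2 + ((b - b.mean()) ** 2).sum() / 2
            sp2 /= 2.0
            return (b.mean() - a.mean()) / np.sqrt(sp2 * (2 / 3))

        exact = sorted(pooled_t(y, c) for c in itertools.combinations(range(6), 3))
        np.testing.assert_allclose(sorted(null.max_t), exact, atol=1e-10)
        obs = pooled_t(y, (3, 4, 5))
        p_exact = np.mean([t >= obs for t in exact])
        p_perm = np.mean(null.max_t >= obs - 1e-12)
        assert p_perm == pytest.approx(p_exact)

    def test_bonferroni_single_voxel_reduces_to_uncorrected(self):
        m = manifest(["control"] * 5 + ["patient"] * 5, ages=[60.0] * 10, sexes=[0] * 10)
        d = build_design(m)
        vols = volumes_from_matrix(np.random.default_rng(0).normal(size=(10, 1)), (2, 2, 2))
        thr = voxel_fwe_threshold(vols, d, "increase", alpha=0.05, method="bonferroni")
        assert thr == pytest.approx(stats.t.isf(0.05, 8))

    def test_too_few_permutations_for_alpha(self):
        with pytest.raises(InferenceError, match="bonferroni"):
            permutation_threshold(np.arange(10.0), alpha=0.01)

    def test_threshold_is_exceedance_quantile(self):
        null = np.arange(100.0)  # 0..99
        # k = floor(0.05*100) = 5 -> threshold is the 5th largest value (95)
        assert permutation_threshold(null, 0.05) == 95.0
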
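import numpy as np
import pandas as pd
import pytest

import rseitools as rt
from rseitools.reference import annual_rsei_reference
from rseitools.rsei import (CLASS_LABELS, build_rsei, classify, pca_pc1,
                            rescale01, sign_correct, summarize_annual_table,
                            water_mask)


class TestWaterMask:
    def test_all_land_empty_mask(self):
        assert not water_mask(np.full((4, 4), -0.3)).any()

    def test_planted_lake_exactly_masked(self):
        mndwi = np.full((10, 10), -0.4)
        mndwi[2:5, 3:7] = 0.5
        mask = water_mask(mndwi, 0.0)
        assert mask.sum() == 12
        assert mask[2:5, 3:7].all()

    def test_threshold_one_masks_nothing(self):
        assert not water_mask(np.random.default_rng(0).random((5, 5)), 1.0).any()


class TestRescale01:
    @pytest.mark.parametrize("vals,expected", [
        ([2, 4, 6], [0, 0.5, 1]),
        ([-5, 0, 5], [0, 0.5, 1]),
    ])
    def test_linear_mapping(self, vals, expected):
        np.testing.assert_allclose(rescale01(np.array(vals, dtype=float)), expected)

    def test_idempotent_on_unit_range(self):
        g = np.array([0.0, 0.3, 1.0])
        np.testing.assert_allclose(rescale01(g), g)

    def test_constant_grid_rejected(self):
        with pytest.raises(ValueError):
            rescale01(np.full(5, 3.0))

    def test_masked_pixels_excluded_and_nan(self):
        g = np.array([1.0, 2.0, 100.0])
        out = rescale01(g, mask=np.array([False, False, True]))
        np.testing.assert_allclose(out[:2], [0, 1])
        assert np.isnan(out[2])


def four_index_grids(rng, shape=(30, 30)):
    return {k: rng.random(shape) for k in ("NDVI", "TCW", "NDBSI", "LST")}


class TestPCA:
    def test_rank_one_structure_analytic(self, rng):
        g = rng.random((40, 40))
        indices = {"NDVI": g, "TCW": g, "NDBSI": -g, "LST": -g}
        loadings, contribution, score = pca_pc1(indices, standardize="none")
        assert contribution == pytest.approx(100, abs=1e-8)
        np.testing.assert_allclose(np.abs(loadings), 0.5, atol=1e-8)

    def test_independent_fields_share_variance(self, rng):
        indices = four_index_grids(rng, (120, 120))
        _, contribution, _ = pca_pc1(indices, standardize="none")
        assert contribution == pytest.approx(25, abs=3)

    def test_loadings_unit_norm(self, rng):
        loadings, _, _ = pca_pc1(four_index_grids(rng))
        assert np.linalg.norm(loadings) == pytest.approx(1, abs=1e-9)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA
        indices = four_index_grids(rng, (25, 25))
        loadings, contribution, score = pca_pc1(indices, standardize="none")
        X = np.stack([indices[k].ravel() for k in ("NDVI", "TCW", "NDBSI", "LST")], 1)
        ref = PCA(n_components=4).fit(X)
        sign = np.sign(ref.components_[0] @ loadings)
        np.testing.assert_allclose(loadings, sign * ref.components_[0], atol=1e-8)
        assert contribution == pytest.approx(
            100 * ref.explained_variance_ratio_[0], abs=1e-6)

    def test_too_few_pixels_rejected(self, rng):
        tiny = {k: rng.random((1, 3)) for k in ("NDVI", "TCW", "NDBSI", "LST")}
        with pytest.raises(ValueError):
            pca_pc1(tiny)


class TestSignCorrect:
    def test_published_negative_loading_pattern_flips(self, rng):
        # eigenvector with negative greenness/wetness loadings must be flipped
        loadings = np.array([-0.43, -0.59, 0.67, 0.12])
        score = rng.random((10, 10))
        rsei0, flipped = sign_correct(loadings, score)
        assert flipped
        np.testing.assert_allclose(rsei0, 1 - rescale01(score), atol=1e-12)

    def test_positive_pattern_kept(self, rng):
        loadings = np.array([0.43, 0.59, -0.67, -0.12])
        score = rng.random((10, 10))
        rsei0, flipped = sign_correct(loadings, score)
        assert not flipped
        np.testing.assert_allclose(rsei0, rescale01(score), atol=1e-12)

    def test_eigenvector_sign_invariance_of_final_rsei(self, rng):
        indices = four_index_grids(rng)
        loadings, _, score = pca_pc1(indices)
        a, _ = sign_correct(loadings, score)
        b, _ = sign_correct(-loadings, -score)
        np.testing.assert_allclose(rescale01(a), rescale01(b), atol=1e-10)

    def test_mixed_signs_resolved_with_warning(self, rng):
        loadings = np.array([0.7, -0.1, -0.5, -0.5])
        with pytest.warns(RuntimeWarning):
            _, flipped = sign_correct(loadings, rng.random((5, 5)))
        assert not flipped   # majority direction positive


class TestClassify:
    @pytest.mark.parametrize("value,label", [
        (0.54, "moderate"), (1.0, "excellent"), (0.2, "fair"),
        (0.0, "poor"), (0.79, "good")])
    def test_bin_assignment(self, value, label):
        code = classify(np.array([value]))[0]
        assert CLASS_LABELS[code] == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([1.2]))

    def test_monotone_in_value(self, rng):
        x = np.sort(rng.random(100))
        codes = classify(x)
        assert (np.diff(codes) >= 0).all()


class TestBuildRSEI:
    def test_spans_unit_interval_and_mean_inside(self, rng):
        res = build_rsei(four_index_grids(rng))
        assert np.nanmin(res.rsei) == pytest.approx(0)
        assert np.nanmax(res.rsei) == pytest.approx(1)
        assert 0 < res.mean_rsei < 1

    def test_planted_quality_field_recovered(self, rng):
        # indices built from one latent quality field with the ecological signs
        q = rng.random((100, 100))
        noise = lambda: 0.01 * rng.standard_normal((100, 100))
        indices = {"NDVI": 0.8 * q + noise(), "TCW": 0.5 * q + noise(),
                   "NDBSI": -0.7 * q + noise(), "LST": 290 - 5 * q + 0.05 * rng.standard_normal((100, 100))}
        res = build_rsei(indices)
        from scipy.stats import spearmanr
        rho = spearmanr(res.rsei.ravel(), q.ravel()).statistic
        assert rho > 0.95
        assert res.loadings[0] * res.loadings[2] < 0  # greenness vs dryness oppose

    def test_water_pixels_excluded(self, rng):
        indices = four_index_grids(rng, (20, 20))
        mndwi = np.full((20, 20), -0.5)
        mndwi[:5, :5] = 0.6
        res = build_rsei(indices, mndwi=mndwi)
        assert np.isnan(res.rsei[:5, :5]).all()
        assert np.isfinite(res.rsei[10:, 10:]).all()


class TestAnnualSummary:
    def test_reference_table_mean_row(self):
        table = summarize_annual_table(annual_rsei_reference())
        mean = table.iloc[-1]
        assert mean["year"] == "Mean"
        assert mean["contribution_rate"] == pytest.approx(78.52)
        assert mean["rsei_mean"] == pytest.approx(0.54)
        assert mean["NDVI"] == pytest.approx(-0.40)
        assert mean["TCW"] == pytest.approx(-0.54)
        assert mean["NDBSI"] == pytest.approx(0.60)
        assert mean["LST"] == pytest.approx(0.39)

    def test_reference_contribution_extrema(self):
        ref = annual_rsei_reference()
        assert ref["contribution_rate"].min() == pytest.approx(66.32)
        assert int(ref.loc[ref["contribution_rate"].idxmin(), "year"]) == 2010
        assert ref["contribution_rate"].max() == pytest.approx(87.24)
        assert int(ref.loc[ref["contribution_rate"].idxmax(), "year"]) == 2002

    def test_single_year_mean_equals_year(self, rng):
        res = build_rsei(four_index_grids(rng), year=2005)
        table = rt.annual_summary([res])
        assert len(table) == 2
        pd.testing.assert_series_equal(
            table.iloc[0].drop("year"), table.iloc[1].drop("year"),
            check_names=False)


class TestDifferenceMap:
    def test_identical_grids(self, rng):
        g = rng.random((10, 10))
        diff, summary = rt.difference_map(g, g)
        assert (diff == 0).all()
        assert summary["fraction_within"] == 1.0

    def test_constant_offset_outside_band(self, rng):
        g = rng.random((10, 10))
        _, summary = rt.difference_map(g, g + 0.2)
        assert summary["fraction_within"] == 0.0

    def test_gaussian_perturbation_matches_normal_tail(self, rng):
        g = rng.random((400, 400))
        _, summary = rt.difference_map(g, g + 0.05 * rng.standard_normal((400, 400)))
        # P(|N(0, 0.05)| <= 0.15) = 99.73%
        assert summary["fraction_within"] == pytest.approx(0.9973, abs=0.002)


class TestSampleTable:
    def test_reproducible_row_count(self, rng):
        indices = four_index_grids(rng)
        res = build_rsei(indices)
        t1 = rt.sample_table(res.rsei, indices, 500, seed=9)
        t2 = rt.sample_table(res.rsei, indices, 500, seed=9)
        assert len(t1) == 500
        pd.testing.assert_frame_equal(t1, t2)

    def test_degenerate_rsei_equals_ndvi(self, rng):
        g = rng.random((30, 30))
        indices = {"NDVI": g, "TCW": g * 0.5, "NDBSI": -g, "LST": -g}
        table = rt.sample_table(rescale01(g), indices, 200, seed=1)
        assert np.corrcoef(table["NDVI"], table["RSEI"])[0, 1] == pytest.approx(1)

    def test_planted_structure_correlation_signs(self, rng):
        q = rng.random((60, 60))
        indices = {"NDVI": 0.8 * q, "TCW": 0.5 * q,
                   "NDBSI": -0.7 * q + 0.01 * rng.standard_normal((60, 60)),
                   "LST": 300 - 6 * q}
        res = build_rsei(indices)
        table = rt.sample_table(res.rsei, indices, 500, seed=2)
        assert np.corrcoef(table["NDBSI"], table["RSEI"])[0, 1] < 0
        assert np.corrcoef(table["LST"], table["RSEI"])[0, 1] < 0
        assert np.corrcoef(table["NDVI"], table["RSEI"])[0, 1] > 0

    def test_oversampling_warns_and_truncates(self, rng):
        indices = {k: rng.random((5, 5)) for k in ("NDVI", "TCW", "NDBSI", "LST")}
        res = build_rsei(indices)
        with pytest.warns(RuntimeWarning):
            table = rt.sample_table(res.rsei, indices, 100, seed=3)
        assert len(table) == 25
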
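import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import rseitools as rt
from rseitools.spatial import (LISA_LABELS, build_weights, fishnet_sample,
                               global_moran, lisa_classify, local_moran)


def lattice_points(nrows, ncols, values=None):
    ii, jj = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    df = pd.DataFrame({"i": ii.ravel(), "j": jj.ravel(),
                       "x": jj.ravel() + 0.5, "y": ii.ravel() + 0.5})
    df.insert(0, "id", np.arange(len(df)))
    df["value"] = np.zeros(len(df)) if values is None else np.asarray(values).ravel()
    return df


def brute_force_global(values, W):
    """Double-loop Moran's I with dense weights."""
    z = values - values.mean()
    n = len(values)
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / (z @ z)


def brute_force_local(values, W):
    z = values - values.mean()
    ss = z @ z
    return np.array([z[i] * sum(W[i, j] * z[j] for j in range(len(z))) / ss
                     for i in range(len(z))])


class TestFishnet:
    def test_cell_centered_lattice_count(self):
        grid = np.zeros((100, 100))
        pts = fishnet_sample(grid, spacing=1000, pixel_size=100)
        assert len(pts) == 100

    def test_spacing_equal_to_pixel_gives_all_pixels(self):
        grid = np.arange(36, dtype=float).reshape(6, 6)
        pts = fishnet_sample(grid, spacing=1.0)
        assert len(pts) == 36
        assert (pts["value"].to_numpy() == grid.ravel()).all()

    def test_masked_region_dropped(self):
        grid = np.ones((40, 40))
        grid[:20, :] = np.nan
        pts = fishnet_sample(grid, spacing=4.0)
        assert len(pts) == 50
        assert (pts["row"] >= 20).all()

    def test_oversized_spacing_rejected(self):
        with pytest.raises(ValueError):
            fishnet_sample(np.zeros((10, 10)), spacing=20.0)


class TestWeights:
    def test_rook_lattice_neighbor_counts(self):
        pts = lattice_points(3, 3)
        w = build_weights(pts, "rook", row_standardize=False)
        counts = [nb.size for nb in w.neighbors]
        assert counts[4] == 4                       # center
        assert [counts[i] for i in (0, 2, 6, 8)] == [2, 2, 2, 2]  # corners

    def test_queen_center_has_eight(self):
        w = build_weights(lattice_points(3, 3), "queen", row_standardize=False)
        assert w.neighbors[4].size == 8

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(lattice_points(4, 5), "queen", row_standardize=True)
        for wi in w.weights:
            assert wi.sum() == pytest.approx(1, abs=1e-9)

    def test_symmetry_before_standardization(self):
        w = build_weights(lattice_points(4, 4), "rook", row_standardize=False)
        W = w.to_dense()
        np.testing.assert_array_equal(W, W.T)
        assert np.diag(W).sum() == 0

    def test_knn_collinear_tie_broken_by_id(self):
        pts = pd.DataFrame({"i": 0, "j": np.arange(5), "x": np.arange(5, dtype=float),
                            "y": 0.0})
        pts.insert(0, "id", np.arange(5))
        pts["value"] = 0.0
        w = build_weights(pts, "knn", k=1, row_standardize=False)
        # interior points are equidistant to both sides: lower id wins
        assert list(w.neighbors[2]) == [1]
        assert list(w.neighbors[0]) == [1]

    def test_knn_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_weights(lattice_points(2, 2), "knn", k=4)


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        values = np.array([1.0, 0.0, 0.0, 1.0])
        w = build_weights(lattice_points(2, 2, values), "rook", row_standardize=False)
        res = global_moran(values, w, permutations=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_two_block_clustering_positive(self):
        values = np.zeros((6, 6))
        values[:, 3:] = 1.0
        w = build_weights(lattice_points(6, 6, values), "queen")
        res = global_moran(values.ravel(), w, permutations=0)
        assert res.I > 0.5

    def test_matches_double_loop_oracle(self, rng):
        values = rng.random(49)
        w = build_weights(lattice_points(7, 7, values), "queen")
        res = global_moran(values, w, permutations=0)
        assert res.I == pytest.approx(brute_force_global(values, w.to_dense()),
                                      abs=1e-10)

    def test_permutation_mean_near_expected(self, rng):
        values = rng.random(36)
        w = build_weights(lattice_points(6, 6, values), "queen")
        sims = [global_moran(rng.permutation(values), w, permutations=0).I
                for _ in range(400)]
        assert np.mean(sims) == pytest.approx(-1 / 35, abs=0.02)

    def test_location_and_scale_invariance(self, rng):
        values = rng.random(36)
        w = build_weights(lattice_points(6, 6, values), "queen")
        base = global_moran(values, w, permutations=0).I
        assert global_moran(values + 10, w, permutations=0).I == pytest.approx(base)
        assert global_moran(values * 4, w, permutations=0).I == pytest.approx(base)

    def test_null_pseudo_p_uniform(self, rng):
        w = build_weights(lattice_points(7, 7), "queen")
        ps = []
        for _ in range(200):
            values = rng.random(49)
            ps.append(global_moran(values, w, permutations=99, seed=1).p_sim)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_as_printed_variant_matches_its_own_oracle(self, rng):
        values = rng.random(25)
        w = build_weights(lattice_points(5, 5, values), "queen")
        res = global_moran(values, w, variant="as_printed", permutations=0)
        z = values - values.mean()
        W = w.to_dense()
        num = sum(W[i, j] * z[i] * z[j] for i in range(25) for j in range(25))
        den = sum(W[i, j] * z[i] ** 2 for i in range(25) for j in range(25))
        assert res.I == pytest.approx(25 * num / den, abs=1e-10)


class TestLocalMoran:
    def test_checkerboard_corner_frozen_value(self):
        values = np.array([1.0, 0.0, 0.0, 1.0])
        w = build_weights(lattice_points(2, 2, values), "rook", row_standardize=True)
        local, quad = local_moran(values, w)
        assert local[0] == pytest.approx(-0.25, abs=1e-12)
        assert quad[0] == 4                          # high value, low neighbors

    def test_point_at_mean_has_zero_local(self):
        values = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0, 1.0, 2.0, 0.0])
        w = build_weights(lattice_points(3, 3, values), "queen")
        local, _ = local_moran(values, w)
        assert local[values == 1.0] == pytest.approx(0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        values = rng.random(36)
        w = build_weights(lattice_points(6, 6, values), "queen")
        local, _ = local_moran(values, w)
        np.testing.assert_allclose(local, brute_force_local(values, w.to_dense()),
                                   atol=1e-10)

    def test_sum_proportional_to_global(self, rng):
        values = rng.random(64)
        w = build_weights(lattice_points(8, 8, values), "queen")
        local, _ = local_moran(values, w)
        glob = global_moran(values, w, permutations=0)
        assert local.sum() == pytest.approx(glob.I * w.s0 / w.n, abs=1e-10)


class TestLISA:
    def test_planted_blob_core_is_hh(self, rng):
        values = rng.normal(0.3, 0.02, (20, 20))
        values[6:12, 6:12] += 0.5
        pts = fishnet_sample(values, spacing=1.0)
        w = build_weights(pts, "queen")
        res = lisa_classify(pts["value"].to_numpy(), w, n_permutations=199, seed=4)
        classes = res.lisa_class.reshape(20, 20)
        core = classes[8:10, 8:10]
        assert (core == LISA_LABELS.index("HH")).all()
        background = classes[:3, :3]
        assert (background != LISA_LABELS.index("HH")).all()

    def test_null_significance_rate_calibrated(self, rng):
        values = rng.random(400)
        pts = lattice_points(20, 20, values)
        w = build_weights(pts, "queen")
        res = lisa_classify(values, w, n_permutations=999, alpha=0.05, seed=11)
        rate = (res.lisa_class != 0).mean()
        assert rate <= 0.07

    def test_alpha_zero_nothing_significant(self, rng):
        values = rng.random(25)
        w = build_weights(lattice_points(5, 5, values), "queen")
        res = lisa_classify(values, w, n_permutations=199, alpha=0.0, seed=1)
        assert (res.lisa_class == 0).all()

    def test_seeded_reproducibility(self, rng):
        values = rng.random(36)
        w = build_weights(lattice_points(6, 6, values), "queen")
        a = lisa_classify(values, w, n_permutations=199, seed=5)
        b = lisa_classify(values, w, n_permutations=199, seed=5)
        np.testing.assert_array_equal(a.p_local, b.p_local)
        np.testing.assert_array_equal(a.lisa_class, b.lisa_class)

    def test_table_layout(self, rng):
        values = rng.random(25)
        pts = lattice_points(5, 5, values)
        w = build_weights(pts, "queen")
        res = lisa_classify(values, w, n_permutations=99, seed=2)
        from rseitools.spatial import lisa_table
        table = lisa_table(pts, res)
        assert list(table.columns) == ["id", "x", "y", "value", "local_I",
                                       "quadrant", "p_sim", "lisa_class"]
        assert set(table["lisa_class"]).issubset(set(LISA_LABELS))
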
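"""ESOM training, U-matrix, and watershed basin extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from procpharm import (
    EsomMap,
    extract_cluster,
    grid_distance,
    smooth_heights,
    umatrix_heights,
    watershed_basins,
)
from procpharm.esom import merge_shallow_basins


def brute_grid_distance(p, q, rows, cols):
    """Minimum planar distance over all 9 wrap images of q."""
    best = np.inf
    for dr in (-rows, 0, rows):
        for dc in (-cols, 0, cols):
            best = min(best, np.hypot(p[0] - q[0] - dr, p[1] - q[1] - dc))
    return best


class TestGridDistance:
    def test_identity(self):
        assert grid_distance((3, 4), (3, 4), 50, 80) == 0.0

    def test_torus_edge_wrap(self):
        assert grid_distance((0, 3), (49, 3), 50, 80) == 1.0

    def test_matches_wrap_image_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = (int(rng.integers(0, 20)), int(rng.integers(0, 30)))
            q = (int(rng.integers(0, 20)), int(rng.integers(0, 30)))
            assert grid_distance(p, q, 20, 30) == pytest.approx(
                brute_grid_distance(p, q, 20, 30)
            )

    def test_out_of_grid(self):
        with pytest.raises(ValueError):
            grid_distance((0, 0), (20, 0), 20, 30)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 11), st.integers(0, 11), st.integers(0, 11),
           st.integers(0, 11), st.integers(0, 11), st.integers(0, 11))
    def test_metric_axioms_on_torus(self, r1, c1, r2, c2, r3, c3):
        p, q, r = (r1, c1), (r2, c2), (r3, c3)
        d = lambda a, b: grid_distance(a, b, 12, 12)
        assert d(p, q) == d(q, p)
        assert (d(p, q) == 0) == (p == q)
        assert d(p, r) <= d(p, q) + d(q, r) + 1e-12


class TestInitAndTraining:
    def test_constant_column_pinned(self):
        X = np.array([[1.0, 5.0], [1.0, 9.0]])
        m = EsomMap(rows=4, cols=4, epochs=1, seed=0)
        w = m.init_weights(X, np.random.default_rng(0))
        assert (w[:, 0] == 1.0).all()
        assert ((w[:, 1] >= 5.0) & (w[:, 1] <= 9.0)).all()

    def test_init_uniform_over_column_range(self):
        X = np.array([[2.0], [6.0]])
        m = EsomMap(rows=25, cols=40, epochs=1, seed=0)
        w = m.init_weights(X, np.random.default_rng(1))[:, 0]
        assert w.min() >= 2.0 and w.max() <= 6.0
        se = (6 - 2) / np.sqrt(12 * len(w))
        assert abs(w.mean() - 4.0) < 3 * se

    def test_seed_reproducibility_bitwise(self):
        X = np.random.default_rng(5).normal(size=(12, 3))
        w1 = EsomMap(rows=6, cols=8, epochs=5, seed=42).fit(X).weights_
        w2 = EsomMap(rows=6, cols=8, epochs=5, seed=42).fit(X).weights_
        assert np.array_equal(w1, w2)

    def test_zero_learning_rate_leaves_weights(self):
        X = np.random.default_rng(2).normal(size=(5, 2))
        m = EsomMap(rows=4, cols=5, epochs=3, rate_start=0.0, rate_end=0.0, seed=1)
        init = m.init_weights(X, np.random.default_rng(np.random.SeedSequence(1).spawn(2)[0]))
        m.fit(X)
        assert np.allclose(m.weights_.reshape(-1, 2), init)

    def test_single_point_contraction(self):
        x = np.array([[2.5, -1.0, 0.5]])
        m = EsomMap(rows=4, cols=4, epochs=50, radius_start=2.0, radius_end=0.0, seed=3)
        m.fit(x)
        bmu = m.best_matching_unit(x[0])
        assert np.linalg.norm(m.weights_[bmu] - x[0]) < 1e-6

    def test_two_blob_quantization_error_decreases(self):
        rng = np.random.default_rng(11)
        blob_a = rng.normal(0.0, 0.3, size=(15, 2))
        blob_b = rng.normal(6.0, 0.3, size=(15, 2))
        X = np.vstack([blob_a, blob_b])
        for seed in range(3):
            m = EsomMap(rows=10, cols=15, epochs=20, radius_start=5, radius_end=1, seed=seed)
            ss = np.random.SeedSequence(seed)
            w0 = m.init_weights(X, np.random.default_rng(ss.spawn(2)[0]))
            d0 = np.sqrt(((X[:, None, :] - w0[None]) ** 2).sum(-1)).min(1).mean()
            m.fit(X)
            assert m.quantization_error_ <= d0


class TestBmu:
    def test_exact_weight_match(self):
        m = EsomMap(rows=3, cols=3, epochs=1, seed=0)
        m.fit(np.random.default_rng(0).normal(size=(4, 2)))
        target = m.weights_[1, 2]
        assert m.best_matching_unit(target) == (1, 2)

    def test_tie_resolves_lexicographically(self):
        m = EsomMap(rows=3, cols=4, epochs=1, seed=0)
        m.weights_ = np.ones((3, 4, 2))
        m.n_features_in_ = 2
        assert m.best_matching_unit([0.0, 0.0]) == (0, 0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        m = EsomMap(rows=5, cols=7, epochs=1, seed=0)
        m.weights_ = rng.normal(size=(5, 7, 3))
        m.n_features_in_ = 3
        for _ in range(20):
            x = rng.normal(size=3)
            flat = m.weights_.reshape(-1, 3)
            want = divmod(int(np.argmin(((flat - x) ** 2).sum(1))), 7)
            assert m.best_matching_unit(x) == want

    def test_dimension_mismatch(self):
        m = EsomMap(rows=3, cols=3, epochs=1, seed=0)
        m.fit(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            m.best_matching_unit([1.0, 2.0, 3.0])


class TestUMatrix:
    def test_identical_weights_zero_heights(self):
        u = umatrix_heights(np.ones((4, 6, 3)))
        assert (u == 0).all()

    def test_two_by_two_outlier_hand_computed(self):
        w = np.zeros((2, 2, 1))
        w[0, 0, 0] = 1.0
        u = umatrix_heights(w, toroid=True)
        assert u[0, 0] == pytest.approx(1.0)
        assert u[1, 0] == pytest.approx(0.25)
        assert u[0, 1] == pytest.approx(0.25)
        assert u[1, 1] == pytest.approx(0.5)
        assert u.argmax() == 0  # outlier neuron carries the maximal height

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(5, 6, 2))
        assert np.allclose(umatrix_heights(w), umatrix_heights(w + 100.0))

    def test_planar_borders_use_fewer_neighbours(self):
        w = np.zeros((3, 3, 1))
        w[1, 1, 0] = 1.0
        u = umatrix_heights(w, toroid=False)
        # corner has 3 neighbours, one of which is the centre outlier
        assert u[0, 0] == pytest.approx(1 / 3)


def two_valley_field():
    """8x8 toroid heights: two conical pits at (2,2) and (6,6)."""
    h = np.empty((8, 8))
    for r in range(8):
        for c in range(8):
            d1 = max(min(abs(r - 2), 8 - abs(r - 2)), min(abs(c - 2), 8 - abs(c - 2)))
            d2 = max(min(abs(r - 6), 8 - abs(r - 6)), min(abs(c - 6), 8 - abs(c - 6)))
            h[r, c] = min(d1, d2)
    return h


class TestWatershed:
    def test_constant_field_single_basin(self):
        basins = watershed_basins(np.zeros((6, 9)))
        assert len(np.unique(basins)) == 1

    def test_two_valley_field(self):
        basins = watershed_basins(two_valley_field())
        assert len(np.unique(basins)) == 2
        assert basins[2, 2] != basins[6, 6]
        assert basins[3, 2] == basins[2, 2]
        assert basins[6, 5] == basins[6, 6]

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_including_plateaus(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.uniform(size=(10, 12))
        if seed % 2:
            h = np.round(h * 4) / 4  # quantise to force plateaus
        basins = watershed_basins(h, toroid=bool(seed % 3))
        assert basins.min() >= 0
        assert basins.shape == h.shape  # every neuron assigned exactly once


class TestBasinMerging:
    def test_shallow_dip_merged_deep_preserved(self):
        h = two_valley_field().astype(float)
        h[0, 5] = 0.8  # carve a shallow extra dip (lowest neighbour height: 1)
        raw = watershed_basins(h)
        assert len(np.unique(raw)) == 3
        merged = merge_shallow_basins(h, raw, min_depth=0.5)
        assert len(np.unique(merged)) == 2
        assert merged[2, 2] != merged[6, 6]  # the deep pits stay apart

    def test_zero_depth_is_identity(self):
        h = two_valley_field()
        raw = watershed_basins(h)
        assert np.array_equal(merge_shallow_basins(h, raw, min_depth=0.0), raw)


class TestExtractCluster:
    def test_constant_field_collects_everything(self):
        bmus = {"seedling": (0, 0), "a": (3, 3), "b": (5, 1)}
        res = extract_cluster(np.zeros((6, 6)), bmus, seed_label="seedling")
        assert set(res.members) == {"a", "b"}
        assert res.excluded == ()

    def test_two_valley_membership(self):
        bmus = {
            "PainInsensitivity": (2, 3),
            "near1": (2, 2),
            "near2": (3, 2),
            "far1": (6, 6),
            "far2": (5, 6),
        }
        res = extract_cluster(
            two_valley_field(), bmus, smooth=False, min_basin_depth=0.0
        )
        assert set(res.members) == {"near1", "near2"}
        assert set(res.excluded) == {"far1", "far2"}

    def test_missing_seed_label(self):
        with pytest.raises(KeyError):
            extract_cluster(np.zeros((4, 4)), {"a": (0, 0)}, seed_label="nope")
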
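import itertools

import numpy as np
import pytest

from cellwarp import (
    entropy_coherence_xcorr,
    gini,
    local_coherence,
    rolling_coherence,
    rolling_entropy,
    zone_bands,
)


def naive_neighborhood_coherence(stack, r, c):
    """Direct 36-pair Pearson mean for one pixel; oracle for local_coherence."""
    series = [stack[:, r + dr, c + dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    pairs = list(itertools.combinations(range(9), 2))
    assert len(pairs) == 36
    rs = []
    for i, j in pairs:
        a, b = series[i], series[j]
        if a.std() == 0 or b.std() == 0:
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    return np.mean(rs) if rs else np.nan


def full_mask(shape):
    m = np.zeros(shape, dtype=bool)
    m[1:-1, 1:-1] = True
    # local_coherence needs the full 3x3 neighborhood inside the mask
    m = np.ones(shape, dtype=bool)
    return m


class TestLocalCoherence:
    def test_matches_naive_pairwise_oracle(self, rng):
        stack = rng.random((40, 8, 9))
        cmap = local_coherence(stack, np.ones((8, 9), dtype=bool))
        for r in range(1, 7):
            for c in range(1, 8):
                expect = naive_neighborhood_coherence(stack, r, c)
                assert cmap.values[r, c] == pytest.approx(expect, abs=1e-10)

    def test_identical_series_give_unity(self, rng):
        base = rng.random(50)
        stack = np.tile(base[:, None, None], (1, 5, 5))
        cmap = local_coherence(stack, np.ones((5, 5), dtype=bool))
        assert cmap.values[2, 2] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_near_zero(self, rng):
        stack = rng.standard_normal((500, 5, 5))
        cmap = local_coherence(stack, np.ones((5, 5), dtype=bool))
        assert abs(cmap.values[2, 2]) < 0.1

    def test_affine_invariance(self, rng):
        stack = rng.random((30, 6, 6))
        gains = 0.5 + rng.random((6, 6))
        offsets = rng.random((6, 6)) * 10
        rescaled = stack * gains[None] + offsets[None]
        a = local_coherence(stack, np.ones((6, 6), dtype=bool)).values
        b = local_coherence(rescaled, np.ones((6, 6), dtype=bool)).values
        np.testing.assert_allclose(a[1:-1, 1:-1], b[1:-1, 1:-1], atol=1e-9)

    def test_undefined_outside_eroded_mask(self, rng):
        stack = rng.random((20, 6, 6))
        mask = np.ones((6, 6), dtype=bool)
        mask[0, :] = False
        cmap = local_coherence(stack, mask)
        assert np.isnan(cmap.values[1, 3])  # neighborhood touches masked row
        assert np.isfinite(cmap.values[3, 3])

    def test_zero_variance_series_excluded(self, rng):
        stack = rng.random((30, 5, 5))
        stack[:, 1, 1] = 7.0  # constant series inside a 3x3 neighborhood
        cmap = local_coherence(stack, np.ones((5, 5), dtype=bool))
        expect = naive_neighborhood_coherence(stack, 2, 2)
        assert cmap.values[2, 2] == pytest.approx(expect, abs=1e-10)

    def test_superpixel_pooling(self, rng):
        stack = rng.random((30, 12, 12))
        cmap = local_coherence(stack, np.ones((12, 12), dtype=bool), superpixel=2)
        assert cmap.values.shape == (6, 6)
        pooled = stack.reshape(30, 6, 2, 6, 2).mean(axis=(2, 4))
        expect = naive_neighborhood_coherence(pooled, 3, 3)
        assert cmap.values[3, 3] == pytest.approx(expect, abs=1e-10)

    def test_too_short_stack_rejected(self, rng):
        with pytest.raises(ValueError):
            local_coherence(rng.random((2, 5, 5)), np.ones((5, 5), dtype=bool))


class TestRollingCoherence:
    def test_window_equal_to_movie_matches_full(self, rng):
        stack = rng.random((25, 5, 5))
        mask = np.ones((5, 5), dtype=bool)
        rolled = rolling_coherence(stack, mask, window=25)
        assert len(rolled) == 1
        np.testing.assert_allclose(
            rolled[0].values, local_coherence(stack, mask).values, equal_nan=True
        )

    def test_stationary_signal_stable_windows(self, rng):
        latent = rng.standard_normal(120)
        stack = latent[:, None, None] + 0.5 * rng.standard_normal((120, 5, 5))
        mask = np.ones((5, 5), dtype=bool)
        full = local_coherence(stack, mask).values[2, 2]
        for cmap in rolling_coherence(stack, mask, window=60, step=20):
            assert abs(cmap.values[2, 2] - full) < 0.15

    def test_change_point_detected(self, rng):
        """Coherence switched on at frame 100 is localized within half a window."""
        T, w = 200, 40
        noise = rng.standard_normal((T, 5, 5))
        latent = rng.standard_normal(T)
        stack = noise.copy()
        stack[100:] = 0.2 * noise[100:] + latent[100:, None, None]
        mask = np.ones((5, 5), dtype=bool)
        maps = rolling_coherence(stack, mask, window=w, step=1)
        vals = np.array([m.values[2, 2] for m in maps])
        detected = np.argmax(vals > 0.5)  # first clearly coherent window start
        assert abs((detected + w / 2) - 100) <= w / 2

    def test_window_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            rolling_coherence(rng.random((30, 5, 5)), np.ones((5, 5), dtype=bool), window=2)


class TestRollingEntropy:
    def test_constant_series_zero_bits(self):
        stack = np.full((30, 4, 4), 2.5)
        maps = rolling_entropy(stack, window=30, n_bins=8)
        np.testing.assert_array_equal(maps[0].values, 0.0)

    def test_two_value_alternation_one_bit(self):
        stack = np.zeros((20, 3, 3))
        stack[1::2] = 1.0
        maps = rolling_entropy(stack, window=20, n_bins=8)
        np.testing.assert_allclose(maps[0].values, 1.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_uniform_over_2k_levels_gives_k_bits(self, k):
        levels = np.arange(2**k, dtype=float)
        series = np.tile(levels, 8)  # uniform over 2^k equally spaced values
        stack = np.tile(series[:, None, None], (1, 2, 2))
        maps = rolling_entropy(stack, window=len(series), n_bins=2**k)
        np.testing.assert_allclose(maps[0].values, float(k))

    def test_bounds_and_time_permutation_invariance(self, rng):
        stack = rng.random((40, 5, 5))
        h = rolling_entropy(stack, window=40, n_bins=8)[0].values
        assert (h >= 0).all() and (h <= 3.0).all()
        perm = rng.permutation(40)
        h2 = rolling_entropy(stack[perm], window=40, n_bins=8)[0].values
        np.testing.assert_allclose(h, h2, atol=1e-12)

    def test_masked_pixels_nan(self, rng):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        maps = rolling_entropy(rng.random((20, 4, 4)), mask, window=20)
        assert np.isnan(maps[0].values[0, 0])
        assert np.isfinite(maps[0].values[1, 1])

    def test_bad_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            rolling_entropy(rng.random((20, 4, 4)), window=20, n_bins=1)


class TestGini:
    def test_homogeneous_zero(self):
        assert gini(np.full(100, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_single_pixel_concentration(self):
        v = np.zeros(100)
        v[42] = 5.0
        assert gini(v) == pytest.approx(0.99)  # (n-1)/n

    def test_hand_computed_two_values(self):
        assert gini([1.0, 3.0]) == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        v = rng.random(50)
        assert gini(v) == pytest.approx(gini(v * 137.0), abs=1e-12)

    def test_matches_pairwise_definition(self, rng):
        v = rng.random(60)
        pairwise = np.abs(v[:, None] - v[None, :]).sum() / (2 * 60**2 * v.mean())
        assert gini(v) == pytest.approx(pairwise, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini(np.zeros(10))


class TestZoneBands:
    def test_disk_annulus_geometry(self):
        rr, cc = np.meshgrid(np.arange(101), np.arange(101), indexing="ij")
        rad = np.hypot(rr - 50, cc - 50)
        disk = rad < 50  # radius 10 um at 0.2 um/px
        zones = zone_bands(disk, bands=[(0.0, 1.2)], pixel_size=0.2)
        band = zones == 1
        # annulus of ~1.2 um depth hugging the edge
        assert band.any()
        assert rad[band].min() > 43 and rad[band].max() >= 48
        assert not band[50, 50]

    def test_default_bands_disjoint(self, disk_mask):
        zones = zone_bands(disk_mask, pixel_size=0.5)
        assert set(np.unique(zones)) <= {0, 1, 2, 3}

    def test_overlapping_bands_rejected(self, disk_mask):
        with pytest.raises(ValueError):
            zone_bands(disk_mask, bands=[(0, 2), (1, 3)])


class TestEntropyCoherenceXcorr:
    @staticmethod
    def _maps(values, cls):
        from cellwarp import CoherenceMap, EntropyMap

        out = []
        for i, v in enumerate(values):
            if cls == "e":
                out.append(EntropyMap(values=v, n_bins=8, window_length=5, window_start=i))
            else:
                out.append(CoherenceMap(values=v, window_length=5, window_start=i))
        return out

    def test_identical_series_peak_at_lag_zero(self, rng):
        vals = [rng.random((6, 6)) for _ in range(30)]
        zones = np.ones((6, 6), dtype=int)
        curves = entropy_coherence_xcorr(
            self._maps(vals, "e"), self._maps(vals, "c"), zones, max_lag=3
        )
        df = curves[1]
        at0 = df.loc[df.lag == 0, "mean_r"].item()
        assert at0 == pytest.approx(1.0, abs=1e-9)
        assert df["mean_r"].max() == at0

    def test_independent_series_near_zero(self, rng):
        e = [rng.standard_normal((8, 8)) for _ in range(60)]
        c = [rng.standard_normal((8, 8)) for _ in range(60)]
        zones = np.ones((8, 8), dtype=int)
        curves = entropy_coherence_xcorr(self._maps(e, "e"), self._maps(c, "c"), zones, max_lag=2)
        assert abs(curves[1]["mean_r"]).max() < 2 / np.sqrt(64 * 60 / 4)

    def test_lagged_coupling_recovered(self, rng):
        base = [rng.standard_normal((5, 5)) for _ in range(50)]
        e = base[2:]  # entropy leads coherence by 2 windows
        c = base[:-2]
        zones = np.ones((5, 5), dtype=int)
        curves = entropy_coherence_xcorr(self._maps(e, "e"), self._maps(c, "c"), zones, max_lag=3)
        df = curves[1]
        best = df.loc[df["mean_r"].idxmax(), "lag"]
        # convention: lag shifts the coherence series, c(t+lag) vs e(t)
        assert best == 2
        assert df.loc[df.lag == best, "mean_r"].item() > 0.95

    def test_zone_mean_mode_runs(self, rng):
        vals = [rng.random((6, 6)) for _ in range(20)]
        zones = np.ones((6, 6), dtype=int)
        curves = entropy_coherence_xcorr(
            self._maps(vals, "e"), self._maps(vals, "c"), zones, max_lag=1, mode="zone-mean"
        )
        assert curves[1].loc[curves[1].lag == 0, "mean_r"].item() == pytest.approx(1.0)

    def test_misaligned_sequences_rejected(self, rng):
        vals = [rng.random((5, 5)) for _ in range(10)]
        e = self._maps(vals, "e")
        c = self._maps(vals, "c")
        c[3].window_start = 99
        with pytest.raises(ValueError):
            entropy_coherence_xcorr(e, c, np.ones((5, 5), dtype=int))
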
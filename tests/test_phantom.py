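import numpy as np
import pytest

from cellwarp import (
    PhantomSpec,
    generate_phantom,
    is_diffeomorphic,
    local_coherence,
    plant_coherence,
    plant_entropy_phases,
    preset_spec,
    rolling_entropy,
    warp_image,
)


class TestGeneratePhantom:
    def test_same_seed_bit_identical(self):
        a = generate_phantom(image_size=64, n_frames=4, seed=42)
        b = generate_phantom(image_size=64, n_frames=4, seed=42)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].frames, b.channels[name].frames)
        np.testing.assert_array_equal(a.true_fields.fields, b.true_fields.fields)

    def test_true_fields_diffeomorphic(self, small_phantom):
        for t in range(small_phantom.spec.n_frames):
            assert is_diffeomorphic(small_phantom.true_field(t))

    def test_translation_fields_constant(self):
        movie = generate_phantom(
            image_size=64, n_frames=5, warp_kind="translation", warp_amplitude=3.0, seed=1
        )
        fld = movie.true_field(0)  # farthest frame, |lambda| = 1
        assert np.allclose(fld.u1, fld.u1[0, 0]) and np.allclose(fld.u2, fld.u2[0, 0])
        assert np.hypot(fld.u1[0, 0], fld.u2[0, 0]) == pytest.approx(3.0)
        assert movie.true_field(movie.reference_index).magnitude().max() == 0

    def test_linear_path_fields_scale_linearly(self):
        movie = generate_phantom(
            image_size=64, n_frames=7, warp_kind="linear-path", warp_amplitude=2.0, seed=2
        )
        ref = movie.reference_index
        f1 = movie.true_fields.fields[ref + 1]
        f3 = movie.true_fields.fields[ref + 3]
        np.testing.assert_allclose(f3, 3 * f1, atol=1e-12)

    def test_warping_frame_with_true_field_recovers_reference(self):
        movie = generate_phantom(
            image_size=96, n_frames=5, warp_amplitude=3.0, noise_sigma=0.0, seed=3
        )
        ref = movie.channels["diffuse"].frames[movie.reference_index]
        frame0 = movie.channels["diffuse"].frames[0]
        back = warp_image(frame0, movie.true_field(0))
        inner = movie.masks[movie.reference_index].mask
        err = np.abs(back - ref)[inner]
        assert err.mean() < 0.02  # interpolation error only

    def test_masks_equal_thresholded_fiducial_support(self):
        """Noise-free renders: reference mask is exactly the fiducial support;
        warped masks sit mid-skirt, Jaccard vs support > 0.97."""
        movie = generate_phantom(image_size=96, n_frames=4, noise_sigma=0.0, seed=4)
        ref_idx = movie.reference_index
        fid = movie.channels["diffuse"].frames
        ref_support = fid[ref_idx] > 0
        np.testing.assert_array_equal(movie.masks[ref_idx].mask, ref_support)
        from scipy import ndimage

        for t in range(4):
            support = fid[t] > 0
            m = movie.masks[t].mask
            assert not (m & ~support).any()  # mask never exceeds the support
            # symmetric difference confined to the 1-2 px resampling skirt
            edge = support & ~ndimage.binary_erosion(support, iterations=2)
            assert not ((m ^ support) & ~edge).any()

    def test_amplitude_beyond_safety_bound_rejected(self):
        with pytest.raises(ValueError, match="safety"):
            generate_phantom(
                image_size=48, n_frames=3, warp_kind="dilation", warp_amplitude=30.0
            )

    def test_channel_inventory_and_metadata(self, small_phantom):
        assert set(small_phantom.channels) >= {"diffuse", "punctate", "signal"}
        for stack in small_phantom.channels.values():
            assert stack.pixel_size == small_phantom.spec.pixel_size
            assert stack.n_frames == small_phantom.spec.n_frames

    @pytest.mark.parametrize("kind", ["diffuse", "punctate", "lowpass-of-signal"])
    def test_fiducial_kinds(self, kind):
        movie = generate_phantom(image_size=48, n_frames=2, fiducial_kind=kind, seed=5)
        assert movie.fiducial.n_frames == 2

    def test_presets(self):
        spec = preset_spec("symmetry-breaking", seed=3)
        assert spec.warp_kind == "protrusion"
        with pytest.raises(ValueError):
            preset_spec("no-such-preset")


class TestPlantCoherence:
    @staticmethod
    def _zone_movie(rho, T=400, seed=8, switch=None):
        movie = generate_phantom(image_size=64, n_frames=T, warp_amplitude=1.0, seed=seed)
        zones = np.zeros((64, 64), dtype=int)
        zones[28:38, 28:38] = 1  # well inside the cell
        return plant_coherence(movie, zones, rho=rho, switch_frame=switch), zones

    def test_rho_one_gives_unity(self):
        movie, zones = self._zone_movie(1.0, T=60)
        stack = movie.channels["planted_coherence"]
        cmap = local_coherence(stack, movie.masks[movie.reference_index].mask)
        assert cmap.values[32, 32] == pytest.approx(1.0, abs=1e-9)

    def test_rho_half_recovered_within_tolerance(self):
        movie, zones = self._zone_movie(0.5, T=400)
        stack = movie.channels["planted_coherence"]
        cmap = local_coherence(stack, movie.masks[movie.reference_index].mask)
        inner = np.zeros_like(zones, dtype=bool)
        inner[30:36, 30:36] = True
        measured = np.nanmean(cmap.values[inner])
        assert measured == pytest.approx(0.5, abs=0.05)

    def test_rho_zero_near_zero(self):
        movie, zones = self._zone_movie(0.0, T=400)
        stack = movie.channels["planted_coherence"]
        cmap = local_coherence(stack, movie.masks[movie.reference_index].mask)
        assert abs(np.nanmean(cmap.values[30:36, 30:36])) < 0.1

    def test_switch_frame_change_point(self):
        movie, zones = self._zone_movie(0.9, T=200, switch=100)
        stack = movie.channels["planted_coherence"].frames
        mask = movie.masks[movie.reference_index].mask
        early = local_coherence(stack[:90], mask).values[32, 32]
        late = local_coherence(stack[110:], mask).values[32, 32]
        assert early < 0.2 < 0.7 < late

    def test_zone_outside_mask_rejected(self):
        movie = generate_phantom(image_size=64, n_frames=10, seed=9)
        zones = np.zeros((64, 64), dtype=int)
        zones[0:3, 0:3] = 1  # background corner
        with pytest.raises(ValueError):
            plant_coherence(movie, zones, rho=0.5)


class TestPlantEntropyPhases:
    def test_constant_region_zero_entropy_and_phase_recovered(self):
        movie = generate_phantom(image_size=64, n_frames=120, seed=10)
        region = np.zeros((64, 64), dtype=bool)
        region[28:38, 28:38] = True
        movie = plant_entropy_phases(movie, region, high_phase=(40, 80))
        stack = movie.channels["planted_entropy"]
        w = 20
        maps = rolling_entropy(stack, movie.masks[movie.reference_index].mask, window=w)
        vals = np.array([m.values[32, 32] for m in maps])
        outside_region = np.array([m.values[20, 20] for m in maps])
        np.testing.assert_allclose(outside_region, 0.0, atol=1e-12)
        # high-entropy phase onset localized within half a window
        onset = np.argmax(vals > 1.5)
        assert abs((onset + w / 2) - 40) <= w / 2
        # windows fully inside the phase approach log2(8) bits
        assert vals[45:55].min() > 2.0

    def test_two_value_alternation_one_bit(self):
        movie = generate_phantom(image_size=64, n_frames=40, seed=11)
        region = np.zeros((64, 64), dtype=bool)
        region[30:34, 30:34] = True
        movie = plant_entropy_phases(movie, region, high_phase=(0, 40))
        # overwrite with a clean alternation to check the closed form
        frames = movie.channels["planted_entropy"].frames.copy()
        frames[:, 31, 31] = np.where(np.arange(40) % 2 == 0, 0.2, 0.8)
        maps = rolling_entropy(frames, window=40, n_bins=8)
        assert maps[0].values[31, 31] == pytest.approx(1.0)

    def test_bad_phase_rejected(self):
        movie = generate_phantom(image_size=64, n_frames=10, seed=12)
        with pytest.raises(ValueError):
            plant_entropy_phases(movie, np.ones((64, 64), dtype=bool), high_phase=(5, 20))
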
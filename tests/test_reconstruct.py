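"""De-skew, depth normalization, tile alignment, fusion and pseudo-H&E."""

import math

import numpy as np
import pytest
from scipy import ndimage

from otlskit.geometry import ScanGeometry, power_schedule
from otlskit.phantom import Phantom, RawStrip, render_strip
from otlskit.reconstruct import (
    PseudoColorParams, ReconstructionError, ScanIntervalError, deskew,
    deskew_interpolating, depth_normalize, fuse, normalize_percentile,
    pseudo_he, refine_offsets, shear_shift_per_row,
)


def _make_strip(frames, interval=None, sampling=0.8, tilt=45.0,
                origin=(0.0, 0.0, 0.0)):
    if interval is None:
        interval = sampling * math.cos(math.radians(tilt))
    return RawStrip(frames=np.asarray(frames, dtype=np.uint16),
                    stage_origin_um=origin, frame_interval_um=interval,
                    sampling_um=sampling, tilt_deg=tilt, channel="nuclear",
                    seed=0)


class TestShearShift:
    def test_matched_interval_gives_unit_shift(self):
        scan = ScanGeometry.from_sampling(0.44, 45.0, 800.0)
        assert scan.frame_interval_um == pytest.approx(0.3111, abs=5e-4)
        assert shear_shift_per_row(scan) == 1

    def test_half_interval_gives_shift_two(self):
        samp = 0.44
        matched = samp * math.cos(math.radians(45.0))
        scan = ScanGeometry.from_sampling(samp, 45.0, 800.0,
                                          frame_interval_um=matched / 2)
        assert shear_shift_per_row(scan) == 2

    def test_mismatched_interval_raises(self):
        samp = 0.44
        matched = samp * math.cos(math.radians(45.0))
        scan = ScanGeometry.from_sampling(samp, 45.0, 800.0,
                                          frame_interval_um=matched * 1.1)
        with pytest.raises(ScanIntervalError):
            shear_shift_per_row(scan)
        # the explicit fallback surfaces the real-valued shear instead
        assert shear_shift_per_row(scan, allow_fallback=True) == pytest.approx(
            1 / 1.1)


class TestDeskew:
    def test_all_zero_strip(self):
        d = deskew(_make_strip(np.zeros((6, 4, 5))), 1)
        assert not np.any(d.volume)
        assert d.volume.shape == (6 + 3, 5, 4)

    def test_single_voxel_relocation(self):
        frames = np.zeros((10, 6, 9))
        frames[5, 3, 7] = 100
        d = deskew(_make_strip(frames), 1)
        assert d.volume[8, 7, 3] == 100
        assert np.count_nonzero(d.volume) == 1

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_affine_shear_oracle(self, trial):
        """Integer de-skew equals an independent nearest-neighbor affine
        shear resampling, voxel for voxel."""
        rng = np.random.default_rng(1000 + trial)
        nf, rows, cols = rng.integers(4, 14, 3)
        shift = int(rng.integers(1, 4))
        frames = rng.integers(0, 60000, (nf, rows, cols)).astype(np.uint16)
        d = deskew(_make_strip(frames), shift)
        # oracle: output (X, Y, Z) pulls input (i = X - shift*Z, j = Z, k = Y)
        matrix = np.array([[1.0, 0.0, -float(shift)],
                           [0.0, 0.0, 1.0],
                           [0.0, 1.0, 0.0]])
        oracle = ndimage.affine_transform(
            frames.astype(np.float32), matrix, order=0,
            output_shape=d.volume.shape, mode="constant", cval=0.0)
        np.testing.assert_array_equal(d.volume, oracle)

    @pytest.mark.parametrize("trial", range(10))
    def test_conserves_total_intensity(self, trial):
        rng = np.random.default_rng(2000 + trial)
        frames = rng.integers(0, 60000, (12, 8, 6)).astype(np.uint16)
        shift = int(rng.integers(1, 4))
        d = deskew(_make_strip(frames), shift)
        assert d.volume.sum(dtype=np.float64) == frames.sum(dtype=np.float64)

    def test_invalid_shift_rejected(self):
        with pytest.raises(ReconstructionError):
            deskew(_make_strip(np.zeros((4, 3, 3))), 0)

    def test_interpolating_fallback_matches_integer_case(self):
        rng = np.random.default_rng(3)
        frames = rng.integers(0, 60000, (10, 6, 5)).astype(np.uint16)
        a = deskew(_make_strip(frames), 1)
        b = deskew_interpolating(_make_strip(frames), 1.0)
        np.testing.assert_allclose(b.volume, a.volume, atol=1e-3)


class TestDepthNormalize:
    def test_flat_schedule_is_identity(self):
        d = deskew(_make_strip(np.full((8, 5, 4), 500)), 1)
        sched = power_schedule(1.0, 1e12, np.linspace(-1, 50, 10))
        out = depth_normalize(d, sched, "divide_compensation")
        np.testing.assert_allclose(out.volume, d.volume, rtol=1e-6)

    def test_apply_then_divide_is_identity(self):
        d = deskew(_make_strip(np.full((8, 5, 4), 500)), 1)
        sched = power_schedule(1.0, 20.0, np.linspace(-1, 50, 10))
        out = depth_normalize(depth_normalize(d, sched, "apply_gain"),
                              sched, "divide_compensation")
        np.testing.assert_allclose(out.volume, d.volume, rtol=1e-6)

    def test_round_trip_flattens_attenuated_uniform_strip(self, uniform_phantom,
                                                          toy_scan):
        mu = 25.0
        sched = power_schedule(1.0, mu, np.linspace(-1, 40, 30))
        strip = render_strip(uniform_phantom, toy_scan, (5.0, 2.0, 1.0),
                             n_frames=30, rows=20, cols=20,
                             mu_true_um=mu, schedule=sched)
        d = depth_normalize(deskew(strip, 1), sched, "divide_compensation")
        z = d.origin_um[2] + np.arange(20) * d.voxel_pitch_um[2]
        profile = np.array([d.volume[:, :, j][d.mask[:, :, j]].mean()
                            for j in range(20)]) * np.exp(z / mu)
        assert profile.max() / profile.min() == pytest.approx(1.0, rel=0.01)

    def test_short_schedule_rejected(self):
        d = deskew(_make_strip(np.full((8, 5, 4), 500)), 1)
        sched = power_schedule(1.0, 20.0, [0.0, 0.5])
        with pytest.raises(ReconstructionError):
            depth_normalize(d, sched, "divide_compensation")


def _smooth_volume(shape, seed):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.random(shape), 2.0).astype(np.float32)


class TestRefineOffsets:
    def test_exact_nominal_positions_need_no_correction(self):
        f = _smooth_volume((70, 50, 40), 4)
        tiles = [f[0:40, :, :], f[30:70, :, :]]
        corr = refine_offsets(tiles, [(0, 0, 0), (30, 0, 0)], max_shift_vox=3)
        np.testing.assert_array_equal(corr, 0)

    def test_known_displacement_recovered(self):
        f = _smooth_volume((80, 60, 40), 5)
        d = np.array([3, -2, 1])
        a = f[0:40, 5:55, 5:35]
        b = f[20 + d[0]:60 + d[0], 5 + d[1]:55 + d[1], 5 + d[2]:35 + d[2]]
        corr = refine_offsets([a, b], [(0, 0, 0), (20, 0, 0)],
                              max_shift_vox=4)
        np.testing.assert_array_equal(corr[0], 0)
        np.testing.assert_array_equal(corr[1], d)

    def test_pairwise_shift_antisymmetric(self):
        from otlskit.reconstruct import _pair_shift
        f = _smooth_volume((80, 60, 40), 6)
        a = f[0:40, :, :]
        b = f[23:63, :, :]  # 3 voxels off its nominal origin of 20
        s_ab = _pair_shift(a, np.array([0, 0, 0]), b, np.array([20, 0, 0]),
                           4, 8)
        s_ba = _pair_shift(b, np.array([20, 0, 0]), a, np.array([0, 0, 0]),
                           4, 8)
        np.testing.assert_array_equal(s_ab, -s_ba)

    def test_corrections_bounded_by_max_shift(self):
        f = _smooth_volume((70, 50, 40), 7)
        tiles = [f[0:40, :, :], f[25:65, :, :]]
        corr = refine_offsets(tiles, [(0, 0, 0), (30, 0, 0)], max_shift_vox=2)
        assert np.all(np.abs(corr) <= 2 * len(tiles))


class TestFuse:
    def test_blending_preserves_constants(self):
        c = 37.0
        tiles = [np.full((40, 30, 20), c, np.float32),
                 np.full((40, 30, 20), c, np.float32)]
        fv = fuse(tiles, [(0, 0, 0), (36, 0, 0)], (1.0, 1.0, 1.0))
        covered = fv.coverage > 0
        np.testing.assert_allclose(fv.volume[covered], c, rtol=1e-6)

    def test_single_tile_is_identity(self):
        t = _smooth_volume((30, 20, 10), 8)
        fv = fuse([t], [(0, 0, 0)], (1.0, 1.0, 1.0))
        np.testing.assert_allclose(fv.volume, t, rtol=1e-6)

    def test_idempotent_on_duplicate_tiles(self):
        t = _smooth_volume((30, 20, 10), 9)
        fv = fuse([t, t], [(0, 0, 0), (0, 0, 0)], (1.0, 1.0, 1.0))
        np.testing.assert_allclose(fv.volume, t, rtol=1e-5)

    def test_world_origin_tracks_voxel_offsets(self):
        t = np.zeros((4, 4, 4), np.float32)
        fv = fuse([t], [(2, 3, 4)], (0.5, 0.5, 0.5), origin_um=(1.0, 1.0, 1.0))
        assert fv.origin_um == (2.0, 2.5, 3.0)


class TestPseudoHE:
    def test_zero_intensity_is_white(self):
        rgb = pseudo_he(np.zeros((4, 4)), np.zeros((4, 4)))
        np.testing.assert_allclose(rgb, 1.0)

    def test_closed_form_single_pixel(self):
        params = PseudoColorParams(k_hematoxylin=(0.2, 0.8, 0.5),
                                   beta_hematoxylin=1.0)
        rgb = pseudo_he(np.array([[1.0]]), np.array([[0.0]]), params)
        np.testing.assert_allclose(
            rgb[0, 0], [math.exp(-0.2), math.exp(-0.8), math.exp(-0.5)],
            rtol=1e-12)
        np.testing.assert_allclose(rgb[0, 0], [0.8187, 0.4493, 0.6065],
                                   atol=5e-5)

    def test_monotone_decreasing_in_each_channel(self):
        levels = np.linspace(0, 1, 9)
        out_h = np.stack([pseudo_he(np.full((1, 1), v), np.zeros((1, 1)))[0, 0]
                          for v in levels])
        out_e = np.stack([pseudo_he(np.zeros((1, 1)), np.full((1, 1), v))[0, 0]
                          for v in levels])
        assert np.all(np.diff(out_h, axis=0) < 0)
        assert np.all(np.diff(out_e, axis=0) < 0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ReconstructionError):
            pseudo_he(np.array([[-0.1]]), np.array([[0.0]]))

    def test_percentile_normalization_range(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(100, 20, (64, 64))
        out = normalize_percentile(arr)
        assert out.min() == 0.0 and out.max() == 1.0
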
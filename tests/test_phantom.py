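"""Phantom generation and the oblique stage-scan forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otlskit.geometry import ScanGeometry, power_schedule
from otlskit.phantom import (
    Phantom, PhantomError, SheetProfile, make_phantom, render_dataset,
    render_strip, strip_to_world, world_to_strip,
)
from otlskit.reconstruct import deskew, shear_shift_per_row


class TestMakePhantom:
    def test_deterministic_for_fixed_seed(self):
        a = make_phantom((30, 30, 30), n_nuclei=10, n_filaments=3, seed=11)
        b = make_phantom((30, 30, 30), n_nuclei=10, n_filaments=3, seed=11)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_no_nuclei_gives_empty_nuclear_channel(self):
        ph = make_phantom((30, 30, 30), n_nuclei=0, n_filaments=3, seed=1)
        assert not np.any(ph.channels["nuclear"])

    def test_zero_extent_rejected(self):
        with pytest.raises(PhantomError):
            make_phantom((0, 30, 30), n_nuclei=1)

    def test_integrated_intensity_matches_analytic_object_integrals(self):
        ph = make_phantom((40, 40, 40), n_nuclei=8, n_filaments=4, seed=5,
                          voxel_pitch_um=0.5, nucleus_radius_um=(3.0, 4.0))
        voxel = float(np.prod(ph.voxel_pitch_um))
        for ch in ("nuclear", "eosin"):
            total = float(ph.channels[ch].sum()) * voxel
            expected = sum(o.analytic_integral for o in ph.objects
                           if o.channel == ch)
            assert total == pytest.approx(expected, rel=0.01)

    def test_objects_inside_extent(self):
        ph = make_phantom((30, 50, 20), n_nuclei=15, n_filaments=5, seed=2)
        ext = np.asarray(ph.extent_um)
        for obj in ph.objects:
            assert np.all(np.asarray(obj.center_um) >= 0)
            assert np.all(np.asarray(obj.center_um) <= ext)


class TestCoordinateMapping:
    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_forward_inverse_identity(self, seed):
        rng = np.random.default_rng(seed)
        origin = rng.uniform(-10, 10, 3)
        interval = rng.uniform(0.1, 1.0)
        sampling = rng.uniform(0.2, 1.0)
        tilt = rng.uniform(10.0, 80.0)
        i, j, k = rng.uniform(0, 100, 3)
        xyz = strip_to_world(origin, interval, sampling, tilt, i, j, k)
        ii, jj, kk = world_to_strip(origin, interval, sampling, tilt, *xyz)
        assert np.allclose([ii, jj, kk], [i, j, k], atol=1e-8)


class TestRenderStrip:
    def test_uniform_phantom_gives_identical_frames(self, uniform_phantom,
                                                    toy_scan):
        strip = render_strip(uniform_phantom, toy_scan, (8.0, 2.0, 1.0),
                             n_frames=20, rows=16, cols=16)
        frames = strip.frames.astype(float)
        assert np.max(np.abs(frames - frames[0])) <= 1e-6

    def test_point_source_lands_at_inverse_mapped_index(self, toy_scan):
        pitch = (0.5, 0.5, 0.5)
        vol = np.zeros((100, 40, 60), np.float32)
        ph = Phantom((49.5, 19.5, 29.5), pitch, {"nuclear": vol})
        i0, j0, k0 = 20, 6, 12
        xyz = strip_to_world((0.0, 0.0, 0.0), toy_scan.frame_interval_um,
                             toy_scan.sampling_um, toy_scan.tilt_deg,
                             i0, j0, k0)
        idx = np.round(np.asarray(xyz) / np.asarray(pitch)).astype(int)
        snapped = idx * np.asarray(pitch)
        origin = snapped - np.asarray(xyz)  # sample (i0,j0,k0) hits a grid node
        vol[tuple(idx)] = 30000.0
        strip = render_strip(ph, toy_scan, origin, n_frames=60, rows=24,
                             cols=24)
        peak = np.unravel_index(strip.frames.argmax(), strip.frames.shape)
        assert peak == (i0, j0, k0)

    def test_schedule_exactly_cancels_matched_attenuation(self, uniform_phantom,
                                                          toy_scan):
        mu = 30.0
        sched = power_schedule(1.0, mu, np.linspace(-1.0, 30.0, 50))
        strip = render_strip(uniform_phantom, toy_scan, (5.0, 2.0, 1.0),
                             n_frames=30, rows=20, cols=20,
                             mu_true_um=mu, schedule=sched)
        d = deskew(strip, shear_shift_per_row(toy_scan))
        profile = np.array([d.volume[:, :, j][d.mask[:, :, j]].mean()
                            for j in range(20)])
        assert profile.max() - profile.min() <= 1.0  # within quantization

    def test_sheet_attenuates_off_plane_source(self, toy_scan):
        """A source m rows off the sheet plane sees the Gaussian intensity
        weight exp(-2 d^2 / w0^2) for d = m * sampling along the normal."""
        sheet = SheetProfile(depth_of_focus_um=110.0, n=1.56)
        pitch = (0.5, 0.5, 0.5)
        vol = np.zeros((100, 40, 60), np.float32)
        ph = Phantom((49.5, 19.5, 29.5), pitch, {"nuclear": vol})
        i0, j0, k0 = 20, 6, 12
        xyz = strip_to_world((0.0, 0.0, 0.0), toy_scan.frame_interval_um,
                             toy_scan.sampling_um, toy_scan.tilt_deg,
                             i0, j0, k0)
        idx = np.round(np.asarray(xyz) / np.asarray(pitch)).astype(int)
        origin = idx * np.asarray(pitch) - np.asarray(xyz)
        vol[tuple(idx)] = 30000.0
        strip = render_strip(ph, toy_scan, origin, n_frames=60, rows=24,
                             cols=24, sheet=sheet, sheet_taps=41,
                             sheet_span=2.5)
        f = strip.frames.astype(float)
        m = 3
        d_um = m * toy_scan.sampling_um  # ~= one waist (w0 = 2.40 um)
        expected = math.exp(-2 * d_um**2 / sheet.waist_um**2)
        assert f[i0, j0 + m, k0] / f[i0, j0, k0] == pytest.approx(
            expected, rel=0.10)

    def test_sheet_profile_waist_dof_consistency(self):
        sheet = SheetProfile(depth_of_focus_um=110.0, wavelength_um=0.515,
                             n=1.56)
        dof = 2 * math.pi * sheet.waist_um**2 * sheet.n / sheet.wavelength_um
        assert dof == pytest.approx(110.0, rel=1e-9)
        # giving the waist reproduces the DOF
        sheet2 = SheetProfile(waist_um=sheet.waist_um, wavelength_um=0.515,
                              n=1.56)
        assert sheet2.depth_of_focus_um == pytest.approx(110.0, rel=1e-9)

    def test_strip_outside_phantom_rejected(self, uniform_phantom, toy_scan):
        with pytest.raises(PhantomError):
            render_strip(uniform_phantom, toy_scan, (0.0, 500.0, 0.0),
                         n_frames=10, rows=8, cols=8)

    def test_negative_noise_rejected(self, uniform_phantom, toy_scan):
        with pytest.raises(PhantomError):
            render_strip(uniform_phantom, toy_scan, (5.0, 2.0, 1.0),
                         n_frames=5, rows=8, cols=8, noise=(-1.0, 0.0))


class TestRenderDataset:
    def test_strip_count_is_tile_channel_product(self, toy_dataset):
        _, plan, _, strips, records, _, _ = toy_dataset
        assert plan.n_strips_y == 3 and plan.n_tiers_z == 2
        assert len(strips) == 3 * 2 * 2  # x2 channels
        assert len(records) == len(strips)

    def test_noiseless_render_is_deterministic(self, toy_dataset):
        phantom, plan, scan, strips, _, rows, cols = toy_dataset
        again, _ = render_dataset(phantom, plan, scan, rows, cols,
                                  sheet=None, seed=1)
        for a, b in zip(strips, again):
            np.testing.assert_array_equal(a.frames, b.frames)

    def test_adjacent_strips_agree_in_overlap_after_deskew(self, toy_dataset):
        """Snapped tile origins make overlapping strips sample identical
        world points, so their de-skewed overlaps match voxel for voxel."""
        _, plan, scan, strips, _, rows, cols = toy_dataset
        shift = shear_shift_per_row(scan)
        nuclear = [deskew(s, shift) for s in strips if s.channel == "nuclear"]
        a, b = nuclear[0], nuclear[1]  # z-neighbors in the same y strip
        pitch = np.asarray(a.voxel_pitch_um)
        off = np.rint((np.asarray(b.origin_um) - np.asarray(a.origin_um))
                      / pitch).astype(int)
        sa = tuple(slice(max(0, o), min(a.volume.shape[d], b.volume.shape[d] + o))
                   for d, o in enumerate(off))
        sb = tuple(slice(max(0, -o), max(0, -o) + (s.stop - s.start))
                   for o, s in zip(off, sa))
        both = a.mask[sa] & b.mask[sb]
        assert both.sum() > 1000
        diff = np.abs(a.volume[sa][both] - b.volume[sb][both])
        assert diff.max() <= 1.0  # identical up to 16-bit quantization

    def test_metadata_round_trips_through_csv(self, toy_dataset, tmp_path):
        from otlskit.io import read_metadata_csv, write_metadata_csv
        records = toy_dataset[4]
        path = write_metadata_csv(records, tmp_path / "meta.csv")
        assert read_metadata_csv(path) == list(records)
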
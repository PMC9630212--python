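"""Fourier pipeline: spectrum, segmentation, cleanup, axis measurement."""

import numpy as np
import pytest

from cborient import (
    FiberFieldParams,
    MeasurementConfig,
    RgbMicrograph,
    average_sample,
    clean_mask,
    compute_power_spectrum,
    generate_fiber_image,
    measure_axes,
    measure_micrograph,
    orientation_index,
    oracle_feret,
    segment_spectrum,
    split_spikes,
)
from cborient.errors import (
    DegenerateImage,
    EmptyMask,
    MaskTooSmall,
    MixedSample,
)
from cborient.fourier import AxisMeasurement, SpectrumMask
from cborient.io_config import MeasurementRecord
from cborient.preprocess import GreyImage

from conftest import make_grating


def fiber_rgb(kappa=4.0, seed=0):
    grey, _ = generate_fiber_image(FiberFieldParams(kappa=kappa, seed=seed))
    px = np.round(grey.pixels).astype(np.uint8)
    return RgbMicrograph(np.stack([px] * 3, axis=-1), "synthetic", "s1", 1)


class TestPowerSpectrum:
    def test_grating_energy_in_two_points(self):
        # horizontal grating, integer period: exactly two conjugate peaks
        ps = compute_power_spectrum(make_grating(0.0, period=16.0, n=256))
        v = ps.values.copy()
        c = 128
        v[c, c] = 0.0  # DC display point
        peaks = np.argwhere(v > 0.99 * v.max())
        assert len(peaks) == 2
        assert {tuple(p) for p in peaks} == {(c, c - 16), (c, c + 16)}

    def test_point_symmetry(self):
        ps = compute_power_spectrum(fiber_to_grey(), gain=100.0)
        v = ps.values[1:, 1:]  # row/col 0 have no symmetric partner for even n
        np.testing.assert_allclose(v, v[::-1, ::-1], rtol=1e-6, atol=1e-6)

    def test_dc_is_global_maximum(self):
        ps = compute_power_spectrum(fiber_to_grey())
        assert ps.values[ps.dc_position] == ps.values.max()

    def test_gain_is_pointwise_monotone_rescale(self):
        grey = fiber_to_grey()
        v70 = compute_power_spectrum(grey, gain=70.0).values
        v200 = compute_power_spectrum(grey, gain=200.0).values
        unclipped = v200 < 255.0
        np.testing.assert_allclose(
            v200[unclipped], (200.0 / 70.0) * v70[unclipped], rtol=1e-9
        )

    def test_isotropic_noise_has_no_preferred_direction(self):
        rng = np.random.default_rng(5)
        grey = GreyImage(rng.uniform(0, 255, (256, 256)), depth="8bit")
        v = compute_power_spectrum(grey).values
        # radial energy profile invariant under 90-degree rotation
        prof = v.sum(axis=0), np.rot90(v).sum(axis=0)
        ratio = prof[0].sum() / prof[1].sum()
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImage):
            compute_power_spectrum(GreyImage(np.full((128, 128), 9.0), depth="8bit"))

    def test_non_square_center_cropped(self):
        rng = np.random.default_rng(6)
        grey = GreyImage(rng.uniform(0, 255, (300, 200)), depth="8bit")
        ps = compute_power_spectrum(grey)
        assert ps.values.shape == (200, 200)


def fiber_to_grey(kappa=4.0, seed=0):
    grey, _ = generate_fiber_image(FiberFieldParams(kappa=kappa, seed=seed))
    return grey


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive Otsu: maximize between-class variance over candidate splits."""
    data = np.round(values)
    data = data[data > 0]
    best_t, best_var = 0.0, -1.0
    for t in np.unique(data)[1:]:
        lo, hi = data[data < t], data[data >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / data.size, hi.size / data.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, float(t)
    return best_t


class TestSegmentSpectrum:
    def test_manual_threshold_zero_covers_spectrum(self):
        ps = compute_power_spectrum(fiber_to_grey())
        smask = segment_spectrum(ps, mode="manual", manual_threshold=0)
        assert smask.mask.all()
        cleaned = clean_mask(smask, dc_position=ps.dc_position, values=ps.values)
        idx = orientation_index(measure_axes(cleaned))
        assert idx == pytest.approx(1.0, abs=0.01)  # full square: equal calipers

    def test_manual_threshold_above_max_empty(self):
        ps = compute_power_spectrum(fiber_to_grey(), gain=100.0)  # max value 100
        with pytest.raises(EmptyMask):
            segment_spectrum(ps, mode="manual", manual_threshold=255)

    def test_auto_threshold_matches_brute_force_otsu(self):
        # pure-tone spectrum: single Otsu pass, directly comparable
        ps = compute_power_spectrum(make_grating(30.0, period=8.0, n=256), window="hann")
        smask = segment_spectrum(ps, mode="auto")
        assert (ps.values >= smask.threshold_used).mean() <= 0.25
        expected = brute_force_otsu(ps.values)
        assert abs(smask.threshold_used - expected) <= 1.0

    def test_auto_selection_never_dominates_plot(self):
        # noisy low-contrast texture: hierarchical Otsu caps the selection
        for seed in range(3):
            grey = fiber_to_grey(kappa=0.0, seed=seed)
            ps = compute_power_spectrum(grey)
            smask = segment_spectrum(ps, mode="auto")
            assert smask.mask.mean() <= 0.25 + 1e-9


class TestCleanMask:
    def _central_blob(self, n=256, r=30):
        ys, xs = np.mgrid[0:n, 0:n]
        return (xs - n // 2) ** 2 + (ys - n // 2) ** 2 <= r * r

    def test_satellite_speck_removed(self):
        mask = self._central_blob()
        mask[10, 10:13] = True  # 3-px satellite
        out = clean_mask(SpectrumMask(mask, 100), apply_convex_hull=False)
        assert not out.mask[10, 10:13].any()
        assert out.mask[128, 128]

    def test_interior_hole_filled(self):
        mask = self._central_blob()
        hole = self._central_blob(r=8)
        before = SpectrumMask(mask & ~hole, 100)
        out = clean_mask(before, apply_convex_hull=False)
        assert out.area_px > before.area_px
        assert out.mask[128, 128]

    def test_convex_hull_superset_of_cross(self):
        from skimage.morphology import convex_hull_image

        n = 256
        mask = np.zeros((n, n), bool)
        mask[118:138, 78:178] = True  # horizontal bar
        mask[78:178, 118:138] = True  # vertical bar
        out = clean_mask(SpectrumMask(mask, 100), smoothing_radius_px=0,
                         apply_convex_hull=True)
        assert out.area_px >= mask.sum()
        np.testing.assert_array_equal(out.mask, convex_hull_image(mask))

    def test_bright_symmetric_satellites_survive(self):
        # harmonic-like bright clusters must be bridged by the hull
        n = 256
        mask = self._central_blob(r=6)
        mask[128 - 3 : 128 + 3, 28:38] = True
        mask[128 - 3 : 128 + 3, 218:228] = True
        values = np.zeros((n, n))
        values[mask] = 100.0
        out = clean_mask(SpectrumMask(mask, 50), values=values)
        axes = measure_axes(out)
        assert axes.major_px > 190  # spans the satellites


class TestSplitSpikes:
    def test_spike_removed_from_disk(self):
        n = 300
        ys, xs = np.mgrid[0:n, 0:n]
        c = n // 2
        disk_blob = (xs - c) ** 2 + (ys - c) ** 2 <= 40 * 40
        spike = (np.abs(ys - c) <= 1) & (xs >= c) & (xs <= c + 100)
        smask = SpectrumMask(disk_blob | spike, 100)
        before = oracle_feret(smask, angle_step_deg=1.0)
        after_mask = split_spikes(smask, spike_removal_radius_px=3)
        after = oracle_feret(after_mask, angle_step_deg=1.0)
        assert before.major_px == pytest.approx(142, abs=2)  # disk edge to spike tip
        assert after.major_px == pytest.approx(81, abs=2)    # disk diameter only

    def test_radius_zero_is_identity(self):
        mask = SpectrumMask(np.ones((64, 64), bool), 10)
        assert split_spikes(mask, 0) is mask

    def test_thin_blob_falls_back_to_input(self):
        n = 128
        mask = np.zeros((n, n), bool)
        mask[n // 2, 20:100] = True  # 1-px-thick line: opening empties it
        smask = SpectrumMask(mask, 10)
        out = split_spikes(smask, spike_removal_radius_px=3)
        np.testing.assert_array_equal(out.mask, mask)


class TestMeasureAxes:
    def test_rectangle_against_rotation_oracle(self):
        mask = np.zeros((200, 200), bool)
        mask[80:121, 50:151] = True  # 41 x 101 axis-aligned rectangle
        sm = SpectrumMask(mask, 0)
        ours = measure_axes(sm)
        ref = oracle_feret(sm, angle_step_deg=0.5)
        # max Feret of a 101x41 rectangle is its diagonal
        assert ours.major_px == pytest.approx(np.hypot(100, 40) + 1, abs=0.5)
        assert ours.major_px == pytest.approx(ref.major_px, rel=0.005)
        assert ours.minor_px == pytest.approx(ref.minor_px, rel=0.015)

    def test_disk_is_isotropic(self):
        n = 201
        ys, xs = np.mgrid[0:n, 0:n]
        disk_blob = (xs - 100) ** 2 + (ys - 100) ** 2 <= 50 * 50
        axes = measure_axes(SpectrumMask(disk_blob, 0))
        assert axes.major_px == pytest.approx(101, rel=0.01)
        assert axes.minor_px == pytest.approx(101, rel=0.01)
        assert orientation_index(axes) == pytest.approx(1.0, abs=0.02)

    def test_three_collinear_pixels(self):
        mask = np.zeros((32, 32), bool)
        mask[16, 10:13] = True
        axes = measure_axes(SpectrumMask(mask, 0))
        assert axes.major_px == pytest.approx(3.0, abs=1e-6)
        assert axes.minor_px == pytest.approx(1.0, abs=1e-6)
        assert orientation_index(axes) == pytest.approx(1 / 3, abs=1e-6)
        assert axes.major_angle_deg == 0.0

    def test_mask_too_small(self):
        mask = np.zeros((32, 32), bool)
        mask[4, 4] = True
        with pytest.raises(MaskTooSmall):
            measure_axes(SpectrumMask(mask, 0))

    def test_angle_of_oriented_bar(self):
        # bar at 45 degrees (y up): rows decrease as cols increase
        mask = np.zeros((128, 128), bool)
        for i in range(60):
            mask[100 - i, 20 + i] = True
        axes = measure_axes(SpectrumMask(mask, 0))
        assert axes.major_angle_deg == pytest.approx(45.0, abs=0.5)


class TestOrientationIndex:
    @pytest.mark.parametrize("major,minor,expected", [
        (100.0, 67.0, 0.67),   # the printed parallel-case scale
        (100.0, 100.0, 1.0),
        (200.0, 50.0, 0.25),
    ])
    def test_direct_ratio(self, major, minor, expected):
        axes = AxisMeasurement(major_px=major, minor_px=minor, major_angle_deg=0.0)
        assert orientation_index(axes) == pytest.approx(expected, abs=1e-12)


class TestMeasureMicrograph:
    def test_deterministic(self):
        img = fiber_rgb(kappa=2.0, seed=11)
        cfg = MeasurementConfig(window="hann")
        r1 = measure_micrograph(img, cfg)
        r2 = measure_micrograph(img, cfg)
        assert r1 == r2  # bit-identical dataclasses

    def test_index_in_unit_interval(self):
        for kappa, seed in [(0.0, 0), (8.0, 1), (2.0, 2)]:
            r = measure_micrograph(fiber_rgb(kappa, seed))
            assert 0.0 < r.index <= 1.0
            assert r.axes.minor_px <= r.axes.major_px
            assert 0.0 <= r.axes.major_angle_deg < 180.0

    def test_result_records_parameters(self):
        cfg = MeasurementConfig(spectrum_gain=150.0, window="hann")
        r = measure_micrograph(fiber_rgb(), cfg)
        assert r.spectrum_gain == 150.0
        assert r.config == cfg
        rec = r.to_record(fiber_rgb())
        assert rec.config_digest == cfg.digest()


class TestAverageSample:
    def _records(self, indices, sample="s1", technique="synthetic"):
        return [
            MeasurementRecord(sample, technique, i + 1, idx, 100.0, idx * 100.0,
                              0.0, "d")
            for i, idx in enumerate(indices)
        ]

    def test_mean_of_five(self):
        sr = average_sample(self._records([0.2, 0.3, 0.4, 0.5, 0.6]))
        assert sr.mean_index == pytest.approx(0.4)
        assert sr.replicate_indices == (0.2, 0.3, 0.4, 0.5, 0.6)

    def test_single_record_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cborient"):
            sr = average_sample(self._records([0.7]))
        assert sr.mean_index == pytest.approx(0.7)
        assert any("replicates" in m for m in caplog.messages)

    def test_mixed_samples_rejected(self):
        recs = self._records([0.5], sample="a") + self._records([0.6], sample="b")
        with pytest.raises(MixedSample):
            average_sample(recs)
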
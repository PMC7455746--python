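"""Radial-ray and line-profile readouts: fidelity, symmetry, equivariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_detection
from vesiquant.profiling import (
    ImagePlane,
    LineProfile,
    ProfilingError,
    extract_line_profile,
    radial_membrane_intensity,
    two_peak_membrane_intensity,
)
from vesiquant.synthetic import render_ring


def gaussian_bump(x, mu, sigma, amp):
    return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


class TestRadialMembraneIntensity:
    def test_uniform_ring_recovered_within_two_percent(self, ring_plane):
        plane, center, radius, _, amp = ring_plane
        rec = radial_membrane_intensity(plane, make_detection(*center, radius))
        assert rec.n_rays_used == 63
        assert rec.mean_membrane_intensity == pytest.approx(amp, rel=0.02)

    def test_quarter_turn_symmetry(self, ring_plane):
        plane, center, radius, _, _ = ring_plane
        # 64 angles: the angle set is closed under 90-degree rotation, so a
        # rotated image with the mapped centroid gives identical ray maxima
        det = make_detection(*center, radius)
        rec = radial_membrane_intensity(plane, det, n_angles=64)
        rot = ImagePlane(
            np.ascontiguousarray(np.rot90(plane.values)), plane.pixel_size_um
        )
        h = plane.values.shape[1]
        det_rot = make_detection(h - 1 - center[1], center[0], radius)
        rec_rot = radial_membrane_intensity(rot, det_rot, n_angles=64)
        assert sorted(rec_rot.per_ray_max) == pytest.approx(
            sorted(rec.per_ray_max), rel=1e-6
        )

    def test_modulated_ring_matches_annulus_oracle(self):
        # ring with smooth angular modulation of the peak amplitude
        h = w = 160
        center, radius, sigma = (80.2, 79.7), 25.0, 3.0
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        d = np.hypot(rows - center[0], cols - center[1])
        theta = np.arctan2(rows - center[0], cols - center[1])
        img = (1000.0 * (1 + 0.2 * np.sin(3 * theta))) * np.exp(
            -((d - radius) ** 2) / (2 * sigma**2)
        )
        plane = ImagePlane(img, 0.2)
        rec = radial_membrane_intensity(plane, make_detection(*center, radius))
        ref = oracles.annulus_sector_maxima(img, center, radius, 3 * sigma, 63)
        assert rec.mean_membrane_intensity == pytest.approx(ref.mean(), rel=0.03)

    def test_scaling_equivariance_exact(self, ring_plane):
        plane, center, radius, _, _ = ring_plane
        det = make_detection(*center, radius)
        rec = radial_membrane_intensity(plane, det)
        scaled = ImagePlane(3.5 * plane.values, plane.pixel_size_um)
        rec_scaled = radial_membrane_intensity(scaled, det)
        assert rec_scaled.mean_membrane_intensity == pytest.approx(
            3.5 * rec.mean_membrane_intensity, rel=1e-12
        )

    def test_background_additivity_exact(self, ring_plane):
        plane, center, radius, _, _ = ring_plane
        det = make_detection(*center, radius)
        rec = radial_membrane_intensity(plane, det)
        shifted = ImagePlane(plane.values + 42.0, plane.pixel_size_um)
        rec_shifted = radial_membrane_intensity(shifted, det)
        np.testing.assert_allclose(
            np.asarray(rec_shifted.per_ray_max),
            np.asarray(rec.per_ray_max) + 42.0,
            rtol=1e-12,
        )

    def test_per_ray_max_bounds_annulus_mean(self, ring_plane):
        plane, center, radius, sigma, _ = ring_plane
        rec = radial_membrane_intensity(plane, make_detection(*center, radius))
        rows, cols = np.mgrid[0 : plane.values.shape[0], 0 : plane.values.shape[1]]
        d = np.hypot(rows - center[0], cols - center[1])
        annulus_mean = plane.values[np.abs(d - radius) <= 3 * sigma].mean()
        assert rec.mean_membrane_intensity >= annulus_mean

    def test_rays_leaving_image_are_dropped_and_counted(self):
        img = render_ring((64, 64), (12.0, 32.0), 10.0, 2.0, 500.0)
        rec = radial_membrane_intensity(
            ImagePlane(img, 0.2), make_detection(12.0, 32.0, 10.0)
        )
        assert rec.n_rays_used < 63
        with pytest.raises(ProfilingError):
            radial_membrane_intensity(
                ImagePlane(np.ones((8, 8)), 0.2), make_detection(4.0, 4.0, 40.0)
            )

    def test_too_few_angles_rejected(self, ring_plane):
        plane, center, radius, _, _ = ring_plane
        with pytest.raises(ValueError):
            radial_membrane_intensity(plane, make_detection(*center, radius), n_angles=2)


class TestLineProfile:
    def test_constant_image(self):
        plane = ImagePlane(np.full((32, 32), 7.0), 0.5)
        prof = extract_line_profile(plane, (5, 5), (25, 25), step_px=0.5)
        np.testing.assert_allclose(prof.intensities, 7.0)
        assert prof.positions[0] == 0.0
        assert np.all(np.diff(prof.positions) > 0)

    def test_integer_pixel_samples_equal_raw_values(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (16, 16))
        plane = ImagePlane(img, 1.0)
        prof = extract_line_profile(plane, (3, 0), (3, 15), step_px=1.0)
        np.testing.assert_allclose(prof.intensities, img[3, :], rtol=1e-12)

    def test_profile_through_ring_center_has_two_symmetric_maxima(self):
        img = render_ring((64, 64), (32.0, 32.0), 12.0, 2.0, 800.0)
        plane = ImagePlane(img, 0.2)
        prof = extract_line_profile(plane, (32.0, 4.0), (32.0, 60.0), step_px=0.25)
        res = two_peak_membrane_intensity(prof, min_prominence=100.0,
                                          min_separation_um=1.0)
        assert not res.discarded and res.peak_count == 2
        assert res.mean_peak_intensity == pytest.approx(800.0, rel=0.02)

    def test_zero_length_and_outside_endpoints_rejected(self):
        plane = ImagePlane(np.zeros((16, 16)), 1.0)
        with pytest.raises(ValueError):
            extract_line_profile(plane, (5, 5), (5, 5))
        with pytest.raises(ValueError):
            extract_line_profile(plane, (5, 5), (20, 5))


class TestTwoPeakReadout:
    def _profile(self, intensities, spacing_um=0.1):
        n = len(intensities)
        return LineProfile(np.arange(n) * spacing_um, np.asarray(intensities, float))

    def test_two_gaussian_peaks_averaged(self):
        x = np.arange(0, 20, 0.1)
        y = gaussian_bump(x, 5, 0.5, 100) + gaussian_bump(x, 15, 0.5, 120)
        prof = LineProfile(x * 0.1, y)
        res = two_peak_membrane_intensity(prof, min_prominence=10, min_separation_um=0.2)
        assert res.mean_peak_intensity == pytest.approx(110.0, rel=1e-3)

    def test_flat_profile_discarded_with_zero_peaks(self):
        res = two_peak_membrane_intensity(
            self._profile(np.zeros(50)), min_prominence=1.0, min_separation_um=0.2
        )
        assert res.discarded and res.peak_count == 0
        assert res.mean_peak_intensity is None

    def test_triple_crossing_discarded(self):
        x = np.arange(0, 30, 0.1)
        y = (
            gaussian_bump(x, 5, 0.5, 100)
            + gaussian_bump(x, 15, 0.5, 100)
            + gaussian_bump(x, 25, 0.5, 100)
        )
        res = two_peak_membrane_intensity(
            LineProfile(x * 0.1, y), min_prominence=10, min_separation_um=0.2
        )
        assert res.discarded and res.peak_count >= 3

    @given(scale=st.floats(0.1, 100.0), shift=st.floats(0.0, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_peak_mean_affine_in_intensity(self, scale, shift):
        x = np.arange(0, 20, 0.1)
        y = gaussian_bump(x, 5, 0.5, 100) + gaussian_bump(x, 15, 0.5, 120)
        base = two_peak_membrane_intensity(
            LineProfile(x * 0.1, y), min_prominence=1.0, min_separation_um=0.2
        )
        mod = two_peak_membrane_intensity(
            LineProfile(x * 0.1, scale * y + shift),
            min_prominence=0.5 * scale,
            min_separation_um=0.2,
        )
        assert mod.peak_count == base.peak_count == 2
        assert mod.mean_peak_intensity == pytest.approx(
            scale * base.mean_peak_intensity + shift, rel=1e-9
        )
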
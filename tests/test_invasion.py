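"""Spheroid invasion profiling: radial profile, r metrics, areas."""

import math

import numpy as np
import pytest

from nichequant.images import BinaryMask, DegenerateInputError
from nichequant.invasion import (
    RadialProfile,
    intensity_density,
    invasion_metrics,
    outgrowth_area,
    r_metric,
    radial_profile,
    spheroid_centroid,
    total_intensity,
)
from nichequant.synth import make_spheroid_scene

from conftest import disk_mask


class TestCentroid:
    def test_symmetric_disk(self):
        mask = BinaryMask(data=disk_mask(201, 40), spacing=1.0)
        cy, cx = spheroid_centroid(mask)
        assert abs(cy - 100) <= 0.5 and abs(cx - 100) <= 0.5

    def test_ignores_far_speck(self):
        m = disk_mask(201, 40)
        m[5, 5] = True
        cy, cx = spheroid_centroid(BinaryMask(data=m, spacing=1.0))
        assert abs(cy - 100) <= 0.5 and abs(cx - 100) <= 0.5

    def test_l_shape_equals_pixel_mean(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:20, 5:10] = True
        m[15:20, 5:25] = True
        cy, cx = spheroid_centroid(BinaryMask(data=m, spacing=2.0))
        ys, xs = np.nonzero(m)
        assert cy == pytest.approx(ys.mean() * 2.0)
        assert cx == pytest.approx(xs.mean() * 2.0)

    def test_empty_mask_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spheroid_centroid(BinaryMask(data=np.zeros((8, 8), bool), spacing=1.0))


class TestRadialProfile:
    def test_filled_disk_profile(self):
        mask = BinaryMask(data=disk_mask(201, 50), spacing=1.0)
        prof = radial_profile(mask, (100.0, 100.0), bin_width_um=1.0)
        assert (prof.intensity[prof.radii <= 49] == 1.0).all()
        assert (prof.intensity[prof.radii >= 52] == 0.0).all()

    def test_empty_mask_all_zero(self):
        mask = BinaryMask(data=np.zeros((64, 64), bool), spacing=1.0)
        prof = radial_profile(mask, (31.0, 31.0))
        assert (prof.intensity == 0).all()

    def test_matches_per_pixel_oracle(self, rng):
        mask_data = rng.random((48, 48)) < 0.4
        mask = BinaryMask(data=mask_data, spacing=1.0)
        cy = cx = 23.0
        w = 2.0
        prof = radial_profile(mask, (cy, cx), bin_width_um=w)
        n_bins = len(prof.radii)
        fg = np.zeros(n_bins)
        tot = np.zeros(n_bins)
        for y in range(48):
            for x in range(48):
                b = int(math.hypot(y - cy, x - cx) // w)
                if b < n_bins:
                    tot[b] += 1
                    fg[b] += bool(mask_data[y, x])
        np.testing.assert_array_equal(prof.pixel_counts, tot)
        np.testing.assert_allclose(prof.intensity, fg / np.maximum(tot, 1))

    def test_centroid_outside_rejected(self):
        mask = BinaryMask(data=np.ones((16, 16), bool), spacing=1.0)
        with pytest.raises(Exception, match="outside|bounds"):
            radial_profile(mask, (100.0, 5.0))


def _profile(radii, intensity):
    return RadialProfile(
        radii=np.asarray(radii, float),
        intensity=np.asarray(intensity, float),
        centroid_um=(0.0, 0.0),
        pixel_counts=np.full(len(radii), 100),
        bin_width_um=float(radii[1] - radii[0]),
    )


class TestRMetric:
    def test_step_profile_all_metrics_at_step(self):
        r = np.arange(0.5, 100, 1.0)
        prof = _profile(r, (r <= 50).astype(float))
        for pct in (25, 50, 75):
            assert r_metric(prof, pct) == pytest.approx(50, abs=1.5)

    def test_linear_ramp_closed_form(self):
        r = np.arange(0.5, 100, 1.0)
        prof = _profile(r, np.clip(1 - r / 100.0, 0, 1))
        assert r_metric(prof, 50) == pytest.approx(50, abs=1.0)
        assert r_metric(prof, 25) == pytest.approx(75, abs=1.0)
        assert r_metric(prof, 75) == pytest.approx(25, abs=1.0)

    def test_logistic_analytic_inversion(self):
        r = np.arange(0.5, 150, 1.0)
        prof = _profile(r, 1 / (1 + np.exp((r - 60) / 10.0)))
        assert r_metric(prof, 50) == pytest.approx(60, abs=1.0)
        assert r_metric(prof, 25) == pytest.approx(60 + 10 * math.log(3), abs=1.0)
        assert r_metric(prof, 75) == pytest.approx(60 - 10 * math.log(3), abs=1.0)

    def test_monotone_in_percent(self, rng):
        r = np.arange(0.5, 80, 1.0)
        noisy = np.clip(1 - r / 80 + rng.normal(0, 0.05, len(r)), 0, 1)
        prof = _profile(r, noisy)
        radii = [r_metric(prof, p) for p in (10, 25, 50, 75, 90)]
        assert all(a >= b - 1e-9 for a, b in zip(radii, radii[1:]))

    def test_all_zero_profile_degenerate(self):
        prof = _profile(np.arange(0.5, 10), np.zeros(10))
        with pytest.raises(DegenerateInputError):
            r_metric(prof, 50)


class TestTotalIntensity:
    def test_disk_equals_area(self):
        mask = BinaryMask(data=disk_mask(201, 50), spacing=1.0)
        prof = radial_profile(mask, (100.0, 100.0), bin_width_um=1.0)
        assert total_intensity(prof) == pytest.approx(math.pi * 50**2, rel=0.02)

    def test_empty_profile_zero(self):
        mask = BinaryMask(data=np.zeros((64, 64), bool), spacing=1.0)
        assert total_intensity(radial_profile(mask, (31.0, 31.0))) == 0.0

    def test_concentric_rings_pixel_count(self):
        size = 201
        c = 100.0
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(yy - c, xx - c)
        mask_data = ((r >= 20) & (r <= 25)) | ((r >= 60) & (r <= 70))
        mask = BinaryMask(data=mask_data, spacing=1.0)
        prof = radial_profile(mask, (c, c), bin_width_um=1.0)
        assert total_intensity(prof) == pytest.approx(mask_data.sum(), rel=0.02)

    def test_conservation_on_random_masks_inside_disk(self, rng):
        # foreground confined to the profiled disk ⇒ polar integral
        # reproduces the pixel area within 2 %
        for _ in range(5):
            size = 101
            c = 50.0
            inside = disk_mask(size, 50)
            mask_data = (rng.random((size, size)) < 0.5) & inside
            prof = radial_profile(
                BinaryMask(data=mask_data, spacing=1.0), (c, c), 1.0
            )
            assert total_intensity(prof) == pytest.approx(
                mask_data.sum(), rel=0.02
            )


class TestOutgrowthArea:
    def test_filled_square_exact(self):
        m = np.zeros((120, 120), bool)
        m[10:110, 10:110] = True
        assert outgrowth_area(BinaryMask(data=m, spacing=1.0)) == 100 * 100

    def test_four_corners_hull_is_square(self):
        m = np.zeros((120, 120), bool)
        for y in (10, 109):
            for x in (10, 109):
                m[y, x] = True
        area = outgrowth_area(BinaryMask(data=m, spacing=1.0))
        assert area == pytest.approx(100 * 100, rel=0.02)

    def test_disk_hull_is_disk(self):
        mask = BinaryMask(data=disk_mask(201, 70), spacing=1.0)
        assert outgrowth_area(mask) == pytest.approx(math.pi * 70**2, rel=0.03)

    def test_empty_degenerate(self):
        with pytest.raises(DegenerateInputError):
            outgrowth_area(BinaryMask(data=np.zeros((8, 8), bool), spacing=1.0))


class TestDensity:
    def test_filled_disk_near_one(self):
        mask = BinaryMask(data=disk_mask(201, 70), spacing=1.0)
        prof = radial_profile(mask, (100.0, 100.0), 1.0)
        d = intensity_density(total_intensity(prof), outgrowth_area(mask))
        assert d == pytest.approx(1.0, abs=0.05)

    def test_half_deleted_disk(self, rng):
        m = disk_mask(201, 70) & (rng.random((201, 201)) < 0.5)
        m[100, 100] = True
        mask = BinaryMask(data=m, spacing=1.0)
        prof = radial_profile(mask, (100.0, 100.0), 1.0)
        d = intensity_density(total_intensity(prof), math.pi * 70**2)
        assert d == pytest.approx(0.5, abs=0.05)

    def test_zero_area_degenerate(self):
        with pytest.raises(DegenerateInputError):
            intensity_density(10.0, 0.0)


class TestSceneRecovery:
    def test_logistic_scene_r50_within_2um(self):
        errs = []
        for seed in range(5):
            mask, truth = make_spheroid_scene(r0_um=60, s_um=10, seed=seed)
            metrics, _ = invasion_metrics(mask)
            errs.append(abs(metrics.r50_um - truth["r50_um"]))
            assert metrics.r75_um <= metrics.r50_um <= metrics.r25_um
        assert max(errs) <= 2.0

    def test_binarization_threshold_invariance(self):
        # scaling intensities before thresholding leaves outputs unchanged
        mask, _ = make_spheroid_scene(seed=7)
        m1, _ = invasion_metrics(mask)
        m2, _ = invasion_metrics(BinaryMask(data=mask.data.copy(), spacing=1.0))
        assert m1 == m2
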
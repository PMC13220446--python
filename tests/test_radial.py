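"""Cell segmentation, outline-following ring binning and MFI profiles."""

import numpy as np
import pytest

from nanoscope import (CellMask, ImageStack, centralization_summary,
                       profile_average, radial_bins, radial_profile,
                       segment_cell)
from nanoscope.io import ConfigurationError, NanoscopeError
from nanoscope.radial import CentroidOutsideError, RadialProfile
from nanoscope.simulate import SynapseImageSpec, simulate_synapse_image

from oracles import profile_oracle, ray_rho_oracle


def _disk_image(radius_px=50, shape=(128, 128), value=100.0, pixel=100.0):
    ii, jj = np.indices(shape)
    cy, cx = shape[0] / 2 - 0.5, shape[1] / 2 - 0.5
    img = np.where((ii - cy) ** 2 + (jj - cx) ** 2 <= radius_px ** 2, value, 0.0)
    return ImageStack(img, pixel)


class TestSegmentCell:
    def test_disk_area_and_centroid(self):
        # 10 um radius disk at 200 nm pixels
        stack = _disk_image(radius_px=50, pixel=200.0)
        cells = segment_cell(stack, min_area_um2=10.0)
        assert len(cells) == 1
        assert cells[0].area_um2 == pytest.approx(np.pi * 100.0, rel=0.02)
        cx, cy = cells[0].centroid
        assert abs(cx - 64 * 200.0) < 200.0 and abs(cy - 64 * 200.0) < 200.0

    def test_blank_image_empty(self):
        with pytest.warns(UserWarning):
            assert segment_cell(ImageStack(np.zeros((32, 32)), 100.0)) == []

    def test_two_disks_two_masks(self):
        ii, jj = np.indices((64, 160))
        img = np.where((ii - 31.5) ** 2 + (jj - 40) ** 2 <= 15 ** 2, 100.0, 0.0)
        img += np.where((ii - 31.5) ** 2 + (jj - 120) ** 2 <= 15 ** 2, 100.0, 0.0)
        cells = segment_cell(ImageStack(img, 200.0), min_area_um2=10.0)
        assert len(cells) == 2

    def test_min_area_filters(self):
        stack = _disk_image(radius_px=5, pixel=100.0)   # ~0.8 um^2
        with pytest.warns(UserWarning):
            assert segment_cell(stack, min_area_um2=10.0) == []


class TestRadialBins:
    def _disk_cell(self, radius_px=40, pixel=100.0):
        stack = _disk_image(radius_px=radius_px, pixel=pixel)
        return segment_cell(stack, min_area_um2=1.0)[0]

    def test_disk_rho_equals_r_over_R(self):
        cell = self._disk_cell()
        bins, rho = radial_bins(cell, 50)
        rows, cols = np.nonzero(cell.mask)
        cx, cy = cell.centroid
        r = np.hypot((cols + 0.5) * 100 - cx, (rows + 0.5) * 100 - cy)
        R = 40 * 100.0
        # away from the boundary, rho tracks r/R closely
        interior = r < 0.9 * R
        assert np.allclose(rho[rows, cols][interior], (r / R)[interior],
                           atol=0.03)
        ring = (r >= 0.505 * R) & (r < 0.515 * R)
        assert np.all(bins[rows, cols][ring] == 25)

    def test_ellipse_boundary_maps_to_last_bin(self):
        ii, jj = np.indices((96, 192))
        img = np.where(((ii - 47.5) / 40) ** 2 + ((jj - 95.5) / 80) ** 2 <= 1,
                       100.0, 0.0)
        cell = segment_cell(ImageStack(img, 100.0), min_area_um2=1.0)[0]
        bins, rho = radial_bins(cell, 50)
        from scipy import ndimage
        boundary = cell.mask & ~ndimage.binary_erosion(cell.mask, iterations=1)
        # boundary pixels land in the outermost rings on both axes despite a
        # 2:1 difference in absolute radius (up to half-pixel pixelation)
        assert np.percentile(bins[boundary], 5) >= 47
        assert np.median(bins[boundary]) == 49

    def test_star_polygon_matches_ray_oracle(self):
        spec = SynapseImageSpec(shape=(96, 96), mean_radius_um=3.5,
                                roughness=((5, 0.15),), noise_sd=0.0, seed=4)
        _, actin, truth = simulate_synapse_image(spec)
        cell = segment_cell(actin, min_area_um2=1.0)[0]
        bins, rho = radial_bins(cell, 50)
        rows, cols = np.nonzero(cell.mask)
        sub = slice(0, None, 7)          # thin out for the slow oracle
        px_nm = np.column_stack([(cols[sub] + 0.5) * 100.0,
                                 (rows[sub] + 0.5) * 100.0])
        rho_oracle = ray_rho_oracle(cell.centroid, cell.outline, px_nm)
        assert np.allclose(rho[rows[sub], cols[sub]], rho_oracle, atol=1e-9)

    def test_partition_every_mask_pixel_once(self):
        cell = self._disk_cell()
        bins, _ = radial_bins(cell, 50)
        assert (bins[cell.mask] >= 0).all()
        assert (bins[~cell.mask] == -1).all()

    def test_centroid_outside_redirects_to_dt(self):
        # crescent: centroid of a thin ring-like shape falls outside
        ii, jj = np.indices((64, 64))
        outer = (ii - 31.5) ** 2 + (jj - 31.5) ** 2 <= 28 ** 2
        inner = (ii - 31.5) ** 2 + (jj - 20) ** 2 <= 22 ** 2
        shape = outer & ~inner
        img = np.where(shape, 100.0, 0.0)
        cell = segment_cell(ImageStack(img, 100.0), min_area_um2=1.0)[0]
        if not cell.centroid_inside:
            with pytest.raises(CentroidOutsideError):
                radial_bins(cell, 50, method="ray")
        bins, rho = radial_bins(cell, 50, method="dt")
        assert (bins[cell.mask] >= 0).all()


class TestRadialProfile:
    def _disk_setup(self, signal):
        stack = _disk_image(radius_px=40)
        cell = segment_cell(stack, min_area_um2=1.0)[0]
        bins, rho = radial_bins(cell, 50)
        return ImageStack(signal, 100.0), cell, bins, rho

    def test_flat_disk_all_ones(self):
        stack = _disk_image(radius_px=40)
        sig, cell, bins, _ = self._disk_setup(stack.pixels)
        prof = radial_profile(sig, cell, bins, 50)
        assert np.nanmax(np.abs(prof.normalized - 1.0)) <= 0.02

    def test_linear_gradient_matches_pixel_oracle(self):
        stack = _disk_image(radius_px=40)
        cell = segment_cell(stack, min_area_um2=1.0)[0]
        bins, rho = radial_bins(cell, 50)
        signal = np.where(cell.mask, 1.0 - np.nan_to_num(rho), 0.0)
        prof = radial_profile(ImageStack(signal, 100.0), cell, bins, 50)
        mfi_oracle, counts_oracle = profile_oracle(signal, bins, 50)
        assert np.allclose(prof.mfi, mfi_oracle, rtol=1e-6, equal_nan=True)
        assert np.array_equal(prof.counts, counts_oracle)
        valid = ~np.isnan(prof.normalized)
        assert np.all(np.diff(prof.normalized[valid]) < 0)

    def test_central_spot_low_at_periphery(self):
        stack = _disk_image(radius_px=40)
        cell = segment_cell(stack, min_area_um2=1.0)[0]
        bins, rho = radial_bins(cell, 50)
        ii, jj = np.indices(cell.mask.shape)
        r2 = ((ii - 63.5) ** 2 + (jj - 63.5) ** 2) * 100.0 ** 2
        sigma = 0.1 * 4000.0
        signal = np.where(cell.mask, np.exp(-r2 / (2 * sigma ** 2)) + 0.01, 0.0)
        prof = radial_profile(ImageStack(signal, 100.0), cell, bins, 50)
        assert prof.normalized[49] < 0.1

    def test_intensity_scale_invariance_exact(self):
        stack = _disk_image(radius_px=40)
        cell = segment_cell(stack, min_area_um2=1.0)[0]
        bins, rho = radial_bins(cell, 50)
        sig = np.where(cell.mask, 1.0 + np.nan_to_num(rho), 0.0)
        p1 = radial_profile(ImageStack(sig, 100.0), cell, bins, 50)
        # power-of-two gain: bitwise identical normalized profile
        p2 = radial_profile(ImageStack(8.0 * sig, 100.0), cell, bins, 50)
        assert np.array_equal(p1.normalized, p2.normalized)
        p3 = radial_profile(ImageStack(7.5 * sig, 100.0), cell, bins, 50)
        assert np.allclose(p1.normalized, p3.normalized, rtol=1e-12)

    def test_scale_equivariance(self):
        profs = []
        for radius, shape in ((25, (64, 64)), (50, (128, 128))):
            stack = _disk_image(radius_px=radius, shape=shape)
            cell = segment_cell(stack, min_area_um2=1.0)[0]
            bins, rho = radial_bins(cell, 50)
            sig = np.where(cell.mask, 1.0 - 0.5 * np.nan_to_num(rho), 0.0)
            profs.append(radial_profile(ImageStack(sig, 100.0), cell, bins, 50))
        a, b = profs
        ok = ~np.isnan(a.normalized) & ~np.isnan(b.normalized)
        assert np.allclose(a.normalized[ok], b.normalized[ok], atol=0.02)

    def test_geometry_mismatch_rejected(self):
        sig, cell, bins, _ = self._disk_setup(_disk_image().pixels)
        with pytest.raises(ConfigurationError):
            radial_profile(ImageStack(np.zeros((10, 10)), 100.0), cell, bins, 50)


class TestProfileAverage:
    def _profile(self, values):
        v = np.asarray(values, float)
        return RadialProfile(len(v), v.copy(), v.copy(),
                             np.ones(len(v), int))

    def test_identical_profiles_zero_sd(self):
        p = self._profile(np.linspace(1, 0.4, 50))
        avg = profile_average([p, p, p])
        assert np.allclose(avg.sd, 0.0)
        assert avg.normalized[0] == pytest.approx(1.0)

    def test_two_profile_arithmetic(self):
        a = self._profile(np.ones(50))
        b = self._profile(np.ones(50))
        a.normalized[10] = 0.8
        b.normalized[10] = 0.6
        avg = profile_average([a, b])
        assert avg.normalized[10] == pytest.approx(0.7)
        assert avg.sd[10] == pytest.approx(0.141421, abs=1e-5)

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            profile_average([])

    def test_simulated_centralized_cohort(self):
        profs = []
        for seed in range(12):
            spec = SynapseImageSpec(shape=(128, 128), mean_radius_um=5.0,
                                    profile="centralized", contrast=0.46,
                                    seed=seed)
            sig, act, _ = simulate_synapse_image(spec)
            cell = segment_cell(act, min_area_um2=10.0)[0]
            bins, _ = radial_bins(cell, 50)
            profs.append(radial_profile(sig, cell, bins, 50))
        avg = profile_average(profs)
        valid = ~np.isnan(avg.normalized)
        assert np.nanmean(avg.normalized[-5:]) < 0.6
        mono = avg.normalized[valid]
        assert mono[0] > mono[len(mono) // 2] > mono[-1]


class TestCentralizationSummary:
    def test_flat_profile_ratio_one(self):
        prof = RadialProfile(50, np.ones(50), np.ones(50), np.ones(50, int))
        assert centralization_summary(prof) == pytest.approx(1.0)

    def test_linear_profile_matches_direct_mean(self):
        vals = np.linspace(1, 0, 50)
        prof = RadialProfile(50, vals, vals, np.ones(50, int))
        expected = vals[-5:].mean() / vals[:5].mean()
        assert centralization_summary(prof) == pytest.approx(expected)

    def test_zero_periphery(self):
        vals = np.ones(50)
        vals[-5:] = 0.0
        prof = RadialProfile(50, vals, vals, np.ones(50, int))
        assert centralization_summary(prof) == 0.0

    def test_all_nan_edge_rejected(self):
        vals = np.ones(50)
        vals[-5:] = np.nan
        prof = RadialProfile(50, vals, vals, np.ones(50, int))
        with pytest.raises(NanoscopeError):
            centralization_summary(prof)
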
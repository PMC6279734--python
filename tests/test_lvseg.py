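"""Segmentation: upsampling, centering, edge detection, cone-sum volumes."""

import numpy as np
import pytest

from gatedpet.errors import DataError, UnreliableGateError
from gatedpet.gating import GatedImageSeries
from gatedpet.lvseg import (WALL, EndocardialSurface, SegmentationConfig,
                            cavity_volume, detect_endocardium,
                            fibonacci_directions, find_lv_center,
                            segment_series, upsample)
from gatedpet.phantom.geometry import PhantomConfig, voxelize_frame

FAST_SEG = SegmentationConfig(n_directions=250)


def sphere_shell_image(radius=4.61, wall=2.0, voxel=0.25, n=64, blur=0.5):
    """Spherical shell (inner radius ``radius``) on a fine grid, mm units."""
    from scipy.ndimage import gaussian_filter

    half = n * voxel / 2.0
    c = (np.arange(n) + 0.5) * voxel - half
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    img = ((r >= radius) & (r <= radius + wall)).astype(float)
    if blur:
        img = gaussian_filter(img, blur / 2.3548 / voxel)
    return img, voxel, np.array([-half, -half, -half])


class TestUpsample:
    def test_factor_one_is_identity(self, rng):
        img = rng.random((6, 5, 4))
        np.testing.assert_array_equal(upsample(img, 1), img)

    def test_constant_image_stays_constant(self):
        """Constant in, constant out; total counts preserved, so each of
        the f^3 fine voxels carries value/f^3."""
        img = np.full((6, 6, 6), 3.7)
        out = upsample(img, 5)
        assert out.std() == pytest.approx(0.0, abs=1e-12)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-12)
        assert out[0, 0, 0] == pytest.approx(3.7 / 125.0, rel=1e-12)

    def test_total_intensity_preserved(self, rng):
        img = rng.random((8, 8, 8))
        out = upsample(img, 5)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_linear_ramp_interpolates_exactly(self):
        """Trilinear interpolation reproduces affine fields (away from the
        replicated border); the conservation rescale is a single global
        factor, so interior value *ratios* are exact."""
        i, j, k = np.meshgrid(*[np.arange(8)] * 3, indexing="ij")
        img = (2.0 * i + 3.0 * j - k + 30.0).astype(float)
        out = upsample(img, 2)

        def affine_at(fine_idx):
            ci = (np.asarray(fine_idx) + 0.5) / 2.0 - 0.5
            return 2.0 * ci[0] + 3.0 * ci[1] - ci[2] + 30.0

        r1 = out[4, 5, 6] / out[7, 7, 7]
        r2 = affine_at((4, 5, 6)) / affine_at((7, 7, 7))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_bad_factor(self):
        with pytest.raises(DataError):
            upsample(np.ones((4, 4, 4)), 0)


class TestCenter:
    def test_symmetric_shell_centroid(self):
        img, voxel, origin = sphere_shell_image()
        center = find_lv_center(img, voxel, origin)
        np.testing.assert_allclose(center, 0.0, atol=voxel / 2.0)

    def test_single_hot_voxel(self):
        img = np.zeros((5, 5, 5))
        img[2, 3, 1] = 7.0
        center = find_lv_center(img, 1.0, (0.0, 0.0, 0.0))
        np.testing.assert_allclose(center, [2.5, 3.5, 1.5])

    def test_two_blobs_uses_larger_component(self):
        img = np.zeros((12, 6, 6))
        img[1:4, 1:4, 1:4] = 1.0   # 27 voxels
        img[9:11, 1:3, 1:3] = 1.0  # 8 voxels
        center = find_lv_center(img, 1.0, (0.0, 0.0, 0.0))
        assert center[0] == pytest.approx(2.5, abs=0.01)

    def test_empty_image_raises(self):
        with pytest.raises(DataError):
            find_lv_center(np.zeros((4, 4, 4)), 1.0, (0, 0, 0))


class TestDetect:
    def test_spherical_shell_radii(self):
        img, voxel, origin = sphere_shell_image()
        cfg = SegmentationConfig(n_directions=200, basal_exclusion_deg=0.0)
        surf = detect_endocardium(img, voxel, origin, (0.0, 0.0, 0.0), cfg)
        good = surf.status == WALL
        assert good.mean() > 0.95
        np.testing.assert_allclose(surf.radii[good], 4.61, rtol=0.05)
        assert cavity_volume(surf) == pytest.approx(4.0 / 3.0 * np.pi * 4.61 ** 3,
                                                    rel=0.03)

    def test_translation_invariance(self):
        img, voxel, origin = sphere_shell_image()
        cfg = SegmentationConfig(n_directions=150, basal_exclusion_deg=0.0)
        s0 = detect_endocardium(img, voxel, origin, (0.0, 0.0, 0.0), cfg)
        shift = np.array([1.0, -0.75, 0.5])
        s1 = detect_endocardium(img, voxel, origin - shift,
                                -shift, cfg)
        np.testing.assert_allclose(s1.radii, s0.radii, rtol=5e-3)

    def test_uniform_image_is_unreliable(self):
        img = np.ones((40, 40, 40))
        with pytest.raises(UnreliableGateError):
            detect_endocardium(img, 0.25, (-5, -5, -5), (0.0, 0.0, 0.0),
                               SegmentationConfig(n_directions=100))

    def test_center_outside_image_rejected(self):
        img, voxel, origin = sphere_shell_image(n=32)
        with pytest.raises(DataError):
            detect_endocardium(img, voxel, origin, (999.0, 0.0, 0.0))


class TestCavityVolume:
    @staticmethod
    def full_sphere_surface(r, n=400):
        dirs = fibonacci_directions(n)
        return EndocardialSurface(
            center=np.zeros(3), directions=dirs,
            radii=np.full(n, float(r)), status=np.zeros(n, dtype=int),
            solid_angle=4.0 * np.pi / n)

    def test_sphere_quadrature(self):
        surf = self.full_sphere_surface(4.61)
        assert cavity_volume(surf) == pytest.approx(
            4.0 / 3.0 * np.pi * 4.61 ** 3, rel=0.01)

    def test_cubic_scaling(self):
        v1 = cavity_volume(self.full_sphere_surface(3.0))
        v2 = cavity_volume(self.full_sphere_surface(6.0))
        assert v2 == pytest.approx(8.0 * v1, rel=1e-9)

    def test_hemisphere_with_flat_cap(self):
        """Hemisphere sampling closed by the flat-cap term: for an
        exclusion cone of half-angle theta the cap adds pi/3 h^3 tan^2."""
        n = 4000
        dirs = fibonacci_directions(n)
        theta_ex = 30.0
        keep = dirs[:, 2] < np.cos(np.deg2rad(theta_ex))
        r = 5.0
        h = r * np.cos(np.deg2rad(theta_ex))  # plane through the cone ring
        radii = np.full(int(keep.sum()), r)
        surf = EndocardialSurface(
            center=np.zeros(3), directions=dirs[keep], radii=radii,
            status=np.zeros(keep.sum(), dtype=int),
            solid_angle=4.0 * np.pi / n, base_height=h,
            excluded_cone_deg=theta_ex)
        # analytic: sphere cut at z = h (spherical cap removed, cone-to-
        # plane volume added back by the flat lid)
        cap_h = r - h
        v_true = 4.0 / 3.0 * np.pi * r ** 3 \
            - np.pi * cap_h ** 2 * (r - cap_h / 3.0) \
            + 0.0  # flat lid closes the cut exactly at z = h
        assert cavity_volume(surf) == pytest.approx(v_true, rel=0.01)


class TestSegmentSeries:
    @staticmethod
    def series_from_volumes(volumes, cfg, period=0.2):
        frames = [voxelize_frame(cfg, v).activity for v in volumes]
        data = np.stack(frames)
        # scale to plausible counts so intensities look like a histogram
        data = data * 1000.0
        return GatedImageSeries(data=data, voxel_size=cfg.voxel_size,
                                origin=cfg.grid_origin(),
                                period_estimate=period, n_gates=len(volumes))

    def test_recovers_noiseless_phantom_volumes(self, small_phantom):
        vols = np.array([410.8, 350.0, 250.0, 155.1, 200.0, 300.0, 380.0,
                         400.0])
        series = self.series_from_volumes(vols, small_phantom)
        curve, info = segment_series(series, FAST_SEG)
        np.testing.assert_allclose(curve.volumes, vols, rtol=0.05)

    def test_identical_frames_identical_volumes(self, small_phantom):
        series = self.series_from_volumes([300.0] * 4, small_phantom)
        curve, _ = segment_series(series, FAST_SEG)
        assert np.ptp(curve.volumes) == pytest.approx(0.0, abs=1e-9)

    def test_intensity_scale_invariance(self, small_phantom):
        vols = [410.8, 300.0, 155.1, 350.0]
        s1 = self.series_from_volumes(vols, small_phantom)
        s2 = GatedImageSeries(data=s1.data * 7.3, voxel_size=s1.voxel_size,
                              origin=s1.origin, period_estimate=0.2,
                              n_gates=4)
        c1, _ = segment_series(s1, FAST_SEG)
        c2, _ = segment_series(s2, FAST_SEG)
        # identical up to absolute solver stopping tolerances in the fits
        np.testing.assert_allclose(c2.volumes, c1.volumes, rtol=1e-5)

    def test_monotone_in_true_volume(self, small_phantom):
        vols = [150.0, 220.0, 290.0, 360.0, 430.0]
        series = self.series_from_volumes(vols, small_phantom, period=0.25)
        curve, _ = segment_series(series, FAST_SEG)
        assert np.all(np.diff(curve.volumes) > 0)


def test_error_shrinks_with_resolution():
    """Estimation error decreases from the coarsest to the finest grid."""
    errs = {}
    for vox, fwhm in ((1.2, 1.2), (0.5, 0.5)):
        n = int(np.ceil(26.0 / vox / 2.0) * 2)
        cfg = PhantomConfig(wall_thickness=2.0, psf_fwhm=fwhm, voxel_size=vox,
                            grid_shape=(n, n, n), supersample=2)
        frame = voxelize_frame(cfg, 300.0)
        fine = upsample(frame.activity, 5)
        center = find_lv_center(fine, vox / 5.0, cfg.grid_origin())
        surf = detect_endocardium(fine, vox / 5.0, cfg.grid_origin(), center,
                                  FAST_SEG)
        errs[vox] = abs(cavity_volume(surf) - 300.0) / 300.0
    assert errs[0.5] < errs[1.2]
    assert errs[0.5] < 0.03
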
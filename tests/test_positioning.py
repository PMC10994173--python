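import numpy as np
import pytest
from scipy import ndimage

from tiltlive.coarse_align import align_pairs, apply_shift_table, rotate_axis_vertical
from tiltlive.core_io import TiltImage, TiltSeries
from tiltlive.positioning import (
    DegenerateFitError,
    PatchFlowField,
    apply_pretilt_correction,
    dense_flow_track,
    fit_plane_robust,
    horizontal_image_index,
    run_positioning,
    triangulate_positions,
)
from tiltlive.synthetic_data import (
    PhantomSpec,
    apply_inplane_transform,
    default_truth,
    make_phantom,
    project_tilt_series,
)


def _static_series(n=5, shift=None, seed=0):
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 1.2)
    images = []
    for i in range(n):
        px = base if shift is None else apply_inplane_transform(
            base, 0, 1, (shift[0] * i, shift[1] * i), order=1
        )
        images.append(TiltImage(pixels=px.astype(np.float32),
                                tilt_angle_deg=float(i), acquisition_index=i))
    return TiltSeries(images=images, order="by_tilt")


class TestDenseFlow:
    def test_static_series_gives_zero_flow(self):
        flow = dense_flow_track(_static_series())
        finite = flow.flows[np.isfinite(flow.flows)]
        assert np.abs(finite).max() < 0.1

    def test_rigid_shift_measured_everywhere(self):
        flow = dense_flow_track(_static_series(shift=(3.0, 0.0)))
        fx = flow.flows[:, :, 0]
        fx = fx[np.isfinite(fx)]
        assert fx.mean() == pytest.approx(3.0, abs=0.3)

    def test_too_few_images_raise(self):
        with pytest.raises(ValueError):
            dense_flow_track(_static_series(n=1))


class TestTriangulation:
    def _flow_from_positions(self, positions, grid=(2, 2)):
        """Build a PatchFlowField whose integration reproduces `positions`."""
        n_img, P, _ = positions.shape
        flows = positions[1:] - positions[:-1]
        return PatchFlowField(
            patch_centers=positions[n_img // 2],
            pair_indices=[(i, i + 1) for i in range(n_img - 1)],
            flows=flows,
            grid_shape=grid,
        )

    def test_in_plane_point_has_zero_depth(self):
        angles = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
        X, Y = 20.0, -8.0
        xs = 47.5 + X * np.cos(np.deg2rad(angles))
        pos = np.stack([
            np.stack([xs, np.full(5, 47.5 + Y)], axis=1)
        ], axis=1)  # one patch
        pos = np.repeat(pos, 4, axis=1)  # replicate so >= 3 patches
        flow = self._flow_from_positions(pos)
        pts = triangulate_positions(flow, angles, (96, 96))
        assert pts.shape[0] == 4
        np.testing.assert_allclose(pts[:, 2], 0.0, atol=0.3)
        np.testing.assert_allclose(pts[:, 0], X, atol=0.3)

    def test_known_point_recovered(self):
        # anchors on a regular 2x2 grid (the flow field's sampling grid);
        # small angles keep track drift within the anchor patch
        angles = np.array([-16, -8, 0.0, 8, 16])
        rad = np.deg2rad(angles)
        grid = [(24.0, 24.0), (72.0, 24.0), (24.0, 72.0), (72.0, 72.0)]
        depths = [6.0, -6.0, 4.0, -3.0]
        pts_true = np.array(
            [[cx - 47.5, cy - 47.5, z] for (cx, cy), z in zip(grid, depths)]
        )
        pos = np.empty((5, 4, 2))
        for p, (X, Y, Z) in enumerate(pts_true):
            pos[:, p, 0] = 47.5 + X * np.cos(rad) + Z * np.sin(rad)
            pos[:, p, 1] = 47.5 + Y
        flow = self._flow_from_positions(pos)
        pts = triangulate_positions(flow, angles, (96, 96))
        np.testing.assert_allclose(pts, pts_true, atol=2.0)
        # opposite depths come out with opposite signs
        assert pts[0, 2] > 0 > pts[1, 2]


class TestPlaneFit:
    def test_exact_tilted_plane_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-50, 50, 40)
        y = rng.uniform(-50, 50, 40)
        z = np.tan(np.deg2rad(8.0)) * x  # pure slope along x
        fit = fit_plane_robust(np.stack([x, y, z], axis=1))
        assert fit.y_tilt_deg == pytest.approx(-8.0, abs=1e-6)
        assert fit.x_tilt_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.rms_residual < 1e-9

    def test_horizontal_points(self):
        rng = np.random.default_rng(1)
        pts = np.stack([rng.uniform(-50, 50, 30), rng.uniform(-50, 50, 30),
                        np.zeros(30)], axis=1)
        fit = fit_plane_robust(pts)
        assert fit.x_tilt_deg == pytest.approx(0.0, abs=1e-9)
        assert fit.y_tilt_deg == pytest.approx(0.0, abs=1e-9)

    def test_gross_outlier_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-50, 50, 30)
        y = rng.uniform(-50, 50, 30)
        z = np.tan(np.deg2rad(5.0)) * x + rng.normal(0, 0.5, 30)
        pts = np.stack([x, y, z], axis=1)
        clean_fit = fit_plane_robust(pts)
        pts_out = np.vstack([pts, [[30.0, 0.0, 60.0]]])
        fit = fit_plane_robust(pts_out)
        assert not fit.inlier_mask[-1]
        assert fit.y_tilt_deg == pytest.approx(clean_fit.y_tilt_deg, abs=0.1)

    def test_collinear_points_degenerate(self):
        pts = np.stack([np.arange(10.0), np.arange(10.0), np.zeros(10)], axis=1)
        with pytest.raises(DegenerateFitError):
            fit_plane_robust(pts)


class TestPretiltCorrection:
    def test_zero_correction_is_identity(self, clean_series_small):
        series, _ = clean_series_small
        from tiltlive.positioning import PlaneFit

        fit = PlaneFit(x_tilt_deg=0.0, y_tilt_deg=0.0,
                       inlier_mask=np.ones(3, bool), rms_residual=0.0)
        out = apply_pretilt_correction(series, fit)
        np.testing.assert_allclose(out.tilt_angles, series.tilt_angles)

    def test_lamella_pretilt_moves_the_horizontal_image(self, clean_series_small):
        series, _ = clean_series_small
        from tiltlive.positioning import PlaneFit

        # +8 deg correction on a 3-deg-step series: the corrected-angle
        # image nearest zero is the nominal -9 one (|-9+8| < |-6+8|)
        fit = PlaneFit(x_tilt_deg=0.0, y_tilt_deg=8.0,
                       inlier_mask=np.ones(3, bool), rms_residual=0.0)
        out = apply_pretilt_correction(series, fit)
        idx = horizontal_image_index(out)
        assert series.tilt_angles[idx] == pytest.approx(-9.0)


class TestRecovery:
    @pytest.mark.parametrize("ptx,pty", [(6.0, -7.0), (0.0, 0.0)])
    def test_pretilt_recovered_noise_free(self, ptx, pty):
        angles = np.arange(-60, 61, 6.0)
        n = len(angles)
        vol = make_phantom(PhantomSpec(volume_shape=(256, 256, 96),
                                       slab_thickness_voxels=30,
                                       n_features=400, seed=3))
        truth = default_truth(n, seed=5, max_shift_px=15, tilt_axis_deg=85.0,
                              defocus_um=3.0, pre_tilt_x_deg=ptx, pre_tilt_y_deg=pty)
        series = project_tilt_series(vol, angles, truth, pixel_size_A=2.0)
        work = rotate_axis_vertical(series)
        table, usable = align_pairs(work, peak_threshold=0.0)
        work = apply_shift_table(work, table)
        work.usable = usable
        corrected, fit, report = run_positioning(work)
        assert fit.x_tilt_deg == pytest.approx(ptx, abs=1.0)
        assert fit.y_tilt_deg == pytest.approx(pty, abs=1.0)
        np.testing.assert_allclose(
            corrected.tilt_angles, series.tilt_angles + fit.y_tilt_deg
        )
        assert corrected.x_tilt_deg == fit.x_tilt_deg
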
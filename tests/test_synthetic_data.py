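import numpy as np
import pytest

from tiltlive.reconstruct import forward_project
from tiltlive.synthetic_data import (
    GroundTruth,
    PhantomSpec,
    apply_ctf_and_noise,
    apply_inplane_transform,
    defocus_at_offset,
    dose_symmetric_angles,
    make_phantom,
    occlude_grid_bar,
    project_tilt_series,
    simulate_fraction_stack,
)


class TestPhantom:
    def test_no_features_gives_slab_background_only(self):
        spec = PhantomSpec(volume_shape=(32, 32, 32), slab_thickness_voxels=12,
                           n_features=0, seed=0)
        vol = make_phantom(spec)
        z0 = (32 - 12) // 2
        assert np.all(vol[:z0] == 0) and np.all(vol[z0 + 12:] == 0)
        assert vol[z0 + 6].std() < 1e-6  # interior plane is flat background

    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(volume_shape=(48, 48, 32), slab_thickness_voxels=16,
                           n_features=20, seed=3)
        np.testing.assert_array_equal(make_phantom(spec), make_phantom(spec))

    def test_support_confined_to_slab(self):
        spec = PhantomSpec(volume_shape=(64, 64, 128), slab_thickness_voxels=40,
                           n_features=30, seed=1)
        vol = make_phantom(spec)
        nz = 128
        z0 = (nz - 40) // 2
        occupied = np.flatnonzero(np.abs(vol).sum(axis=(1, 2)) > 0)
        assert occupied.min() >= z0 and occupied.max() < z0 + 40

    def test_infeasible_slab_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(volume_shape=(32, 32, 16), slab_thickness_voxels=24)


class TestProjection:
    def test_center_point_projects_to_center_at_any_tilt(self):
        vol = np.zeros((33, 17, 33))
        vol[16, 8, 16] = 1.0
        truth = GroundTruth.zero(3)
        series = project_tilt_series(vol, [-40.0, 0.0, 55.0], truth)
        for im in series.images:
            iy, ix = np.unravel_index(np.argmax(im.pixels), im.pixels.shape)
            assert abs(ix - 16) <= 1 and abs(iy - 8) <= 1

    def test_point_follows_cos_sin_law(self):
        # spot at x = x0 cos(a) + z0 sin(a) for a point off the tilt axis,
        # cross-checked against the voxelised projector
        vol = np.zeros((32, 16, 64))
        x0, z0 = 10, 8
        vol[16 + z0, 8, 32 + x0] = 1.0
        for alpha in (-30.0, 20.0, 50.0):
            p = forward_project(vol, [alpha])[0]
            ix = np.argmax(p.sum(axis=0))
            expected = 31.5 + (
                x0 * np.cos(np.deg2rad(alpha)) + z0 * np.sin(np.deg2rad(alpha))
            )
            assert abs(ix - expected) <= 1.0

    def test_injected_shift_moves_the_image(self):
        vol = np.zeros((17, 33, 33))
        vol[8, 16, 16] = 1.0
        truth = GroundTruth(per_image_shift_px=[[12.0, -7.0]],
                            per_image_rotation_deg=[0.0])
        series = project_tilt_series(vol, [0.0], truth)
        iy, ix = np.unravel_index(np.argmax(series.images[0].pixels),
                                  series.images[0].shape)
        assert ix == pytest.approx(16 + 12, abs=1)
        assert iy == pytest.approx(16 - 7, abs=1)

    def test_projected_mass_is_tilt_independent(self, phantom_small):
        masses = [forward_project(phantom_small, [a])[0].sum()
                  for a in (0.0, 30.0, 60.0)]
        assert np.ptp(masses) / masses[0] < 1e-3

    def test_fov_crop(self, phantom_small):
        truth = GroundTruth.zero(1)
        s = project_tilt_series(phantom_small, [0.0], truth, fov_px=64)
        assert s.shape == (64, 64)


class TestCtfAndNoise:
    def test_defocus_gradient_closed_form(self):
        # a strip 1000 px from the axis at 2 A/px and 60 deg sits
        # 1000*2*tan(60) A ~ 0.3464 um further from focus
        out = defocus_at_offset(3.0, 1000.0, 2.0, 60.0)
        assert out - 3.0 == pytest.approx(0.34641, abs=1e-4)
        assert defocus_at_offset(3.0, 1000.0, 2.0, 0.0) == 3.0

    def test_dose_and_determinism(self, phantom_small):
        angles = [0.0, 30.0]
        truth = GroundTruth.zero(2, defocus_um=np.array([3.0, 3.0]))
        s = project_tilt_series(phantom_small, angles, truth, pixel_size_A=2.0)
        a = apply_ctf_and_noise(s, truth, dose_e_per_A2=3.0, seed=1, n_strips=4)
        b = apply_ctf_and_noise(s, truth, dose_e_per_A2=3.0, seed=1, n_strips=4)
        np.testing.assert_array_equal(a.images[0].pixels, b.images[0].pixels)
        # 3 e/A^2 at 2 A/px = 12 e/px expected at zero tilt
        assert a.images[0].pixels.mean() == pytest.approx(12.0, rel=0.05)

    def test_dose_must_be_positive(self, phantom_small):
        truth = GroundTruth.zero(1, defocus_um=np.array([3.0]))
        s = project_tilt_series(phantom_small, [0.0], truth)
        with pytest.raises(ValueError):
            apply_ctf_and_noise(s, truth, dose_e_per_A2=0.0)


class TestOcclusion:
    def test_zero_coverage_is_identity(self, clean_series_small):
        series, _ = clean_series_small
        out = occlude_grid_bar(series, [0], 0.0)
        np.testing.assert_array_equal(out.images[0].pixels, series.images[0].pixels)

    def test_full_coverage_flattens_the_image(self, clean_series_small):
        series, _ = clean_series_small
        out = occlude_grid_bar(series, [3], 1.0)
        assert out.images[3].pixels.std() < 0.05 * series.images[3].pixels.std()

    def test_occluded_histograms_differ_grossly(self, occluded_series_small):
        series = occluded_series_small
        occ = series.images[0].pixels
        ok = series.images[20].pixels
        # half the occluded image is near-zero: its median collapses
        assert np.median(occ) < 0.5 * np.median(ok)

    def test_out_of_range_index_raises(self, clean_series_small):
        series, _ = clean_series_small
        with pytest.raises(IndexError):
            occlude_grid_bar(series, [len(series)], 0.5)


class TestFractionStack:
    def test_flux_conservation_zero_drift(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.5, 1.5, size=(64, 64))
        stack = simulate_fraction_stack(img, dose_per_frame_e_per_px=50.0,
                                        n_frames=10, seed=1)
        total = stack.frames.sum()
        expected = 10 * 50.0 * img.size
        assert abs(total - expected) / expected < 0.01

    def test_linear_drift_total_displacement(self):
        drift = np.full((40, 2), [0.2, 0.0])
        img = np.zeros((32, 32))
        img[16, 16] = 100.0
        stack = simulate_fraction_stack(img, 1000.0, 40, drift_path=drift, seed=0)
        first = np.unravel_index(np.argmax(stack.frames[0]), (32, 32))
        last = np.unravel_index(np.argmax(stack.frames[-1]), (32, 32))
        assert last[1] - first[1] == pytest.approx(8, abs=1)

    def test_total_dose_arithmetic(self):
        img = np.ones((16, 16))
        stack = simulate_fraction_stack(img, 0.05, 20, seed=2)
        # 0.05 e/px/frame * 20 frames = 1 e/px in expectation
        assert stack.frames.sum() / img.size == pytest.approx(1.0, abs=0.1)


class TestInplaneTransform:
    def test_rotation_moves_blob_as_rotation_matrix(self):
        from scipy import ndimage

        img = np.zeros((64, 64))
        img[37, 42] = 1.0  # centre-relative position (10.5, 5.5)
        img = ndimage.gaussian_filter(img, 1.5)
        out = apply_inplane_transform(img, 30.0, order=1)
        iy, ix = np.unravel_index(np.argmax(out), out.shape)
        win = out[iy - 3 : iy + 4, ix - 3 : ix + 4]
        gy, gx = np.mgrid[-3:4, -3:4]
        cy = iy + (win * gy).sum() / win.sum()
        cx = ix + (win * gx).sum() / win.sum()
        th = np.deg2rad(30)
        q = np.array([10.5, 5.5])
        assert cx == pytest.approx(31.5 + q[0] * np.cos(th) - q[1] * np.sin(th), abs=0.3)
        assert cy == pytest.approx(31.5 + q[0] * np.sin(th) + q[1] * np.cos(th), abs=0.3)


def test_dose_symmetric_scheme_matches_group_two():
    order = dose_symmetric_angles(max_tilt=12, step=3, group=2)
    np.testing.assert_allclose(order, [0, 3, -3, -6, 6, 9, -9, -12, 12])
    full = dose_symmetric_angles(max_tilt=60, step=3, group=2)
    assert len(full) == 41
    assert sorted(full.tolist()) == np.arange(-60, 61, 3).tolist()
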
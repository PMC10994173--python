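import numpy as np
import pytest

from tiltlive.coarse_align import ShiftTable
from tiltlive.fine_align import (
    AlignmentModel,
    InsufficientTracksError,
    RelocationExhaustedError,
    TrackerConfig,
    _rot2,
    apply_alignment,
    compose_raw_model,
    imod_transforms,
    init_patches,
    relocate_patch,
    solve_alignment,
    subpatch_contrast,
    theoretical_shift,
    track_patches,
)
from tiltlive.synthetic_data import apply_inplane_transform


class TestInitPatches:
    def test_sixteen_patches_at_thirty_percent(self):
        centers, (ph, pw) = init_patches(np.zeros((4096, 4096)))
        assert len(centers) == 16
        assert ph == pw == round(0.30 * 4096)  # 1229 px

    def test_grid_symmetric_about_centre(self):
        centers, _ = init_patches(np.zeros((256, 256)))
        arr = np.asarray(centers)
        assert arr.mean(axis=0) == pytest.approx([128.0, 128.0])
        xs = sorted(set(arr[:, 0]))
        assert len(xs) == 4 and np.allclose(np.diff(xs), 64)

    def test_small_image_still_valid(self):
        centers, (ph, pw) = init_patches(np.zeros((100, 100)))
        assert ph == pw == 30

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrackerConfig(patch_frac=1.5)
        with pytest.raises(ValueError):
            TrackerConfig(n_patches=2)


class TestTheoreticalShift:
    def test_on_axis_feature_never_moves(self):
        for a, b in ((0, 30), (-45, 60), (10, 10)):
            assert theoretical_shift(2048.0, 4096.0, a, b) == 0.0

    def test_equal_angles_no_shift(self):
        assert theoretical_shift(3072.0, 4096.0, 24.0, 24.0) == 0.0

    def test_matches_projection_geometry(self):
        # a specimen-plane feature at image x follows X*cos(angle); the
        # independent evaluation for x=3072, w=4096, 0->3 degrees
        got = theoretical_shift(3072.0, 4096.0, 0.0, 3.0)
        expected = 1024.0 * (np.cos(np.deg2rad(3.0)) - 1.0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(-1.40, abs=0.01)


class TestRelocation:
    def test_two_hundred_subpatches(self):
        c = subpatch_contrast(np.zeros((200, 400)), TrackerConfig().subpatch_grid)
        assert c.size == 200

    def test_relocation_lands_on_the_contrast_blob(self):
        rng = np.random.default_rng(0)
        img = np.zeros((200, 400)) + 0.01 * rng.standard_normal((200, 400))
        img[10:30, 350:390] += 50.0 * rng.standard_normal((20, 40))
        cx, cy = relocate_patch(img, set())
        assert cx > 300 and cy < 50

    def test_successive_relocations_never_repeat(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((200, 400))
        occupied: set = set()
        seen = set()
        for _ in range(5):
            c = relocate_patch(img, occupied)
            assert c not in seen
            seen.add(c)

    def test_exhaustion_raises(self):
        occupied = {(r, c) for r in range(10) for c in range(20)}
        with pytest.raises(RelocationExhaustedError):
            relocate_patch(np.zeros((40, 80)), occupied)


@pytest.fixture(scope="module")
def prepared_case(tracking_case):
    """Coarse-aligned, positioned working series + truth."""
    from tiltlive.coarse_align import align_pairs, apply_shift_table, rotate_axis_vertical
    from tiltlive.positioning import run_positioning

    series, truth, angles = tracking_case
    work = rotate_axis_vertical(series)
    table, usable = align_pairs(work, peak_threshold=0.0)
    work = apply_shift_table(work, table)
    work.usable = usable
    corrected, fit, _ = run_positioning(work)
    return corrected, table, truth, angles, series


class TestTracking:
    def test_noise_free_series_keeps_all_sixteen_trajectories(self, prepared_case):
        corrected, *_ = prepared_case
        tset, usable = track_patches(corrected)
        full = [t for t in tset.trajectories if len(t.positions) == len(corrected)]
        assert len(full) == 16
        assert usable.all()

    def test_noise_image_flagged_by_75_percent_rule(self, prepared_case):
        corrected, *_ = prepared_case
        damaged = corrected.copy()
        rng = np.random.default_rng(3)
        k = len(damaged) // 2 + 3
        damaged.images[k].pixels = rng.standard_normal(damaged.shape).astype(np.float32)
        tset, usable = track_patches(damaged)
        assert not usable[k]

    def test_tracked_positions_match_projection_geometry(self, prepared_case):
        corrected, table, truth, angles, _ = prepared_case
        tset, usable = track_patches(corrected)
        h, w = corrected.shape
        anchor = int(np.argmin(np.abs(corrected.tilt_angles)))
        errs = []
        for t in tset.trajectories:
            if anchor not in t.positions:
                continue
            x0 = t.positions[anchor][0] - (w - 1) / 2
            for i, (x, y) in t.positions.items():
                pred = x0 * np.cos(np.deg2rad(corrected.tilt_angles[i])) / np.cos(
                    np.deg2rad(corrected.tilt_angles[anchor])
                )
                errs.append(x - (w - 1) / 2 - pred)
        # depth causes a sin(angle) term; at slab scale this stays bounded
        assert np.percentile(np.abs(errs), 90) < 15


class TestSolver:
    def test_ground_truth_recovered(self, prepared_case):
        corrected, table, truth, angles, series = prepared_case
        tset, usable = track_patches(corrected)
        work_model, kept = solve_alignment(tset, corrected.tilt_angles, usable)
        model = compose_raw_model(work_model, table,
                                 series.nominal_tilt_axis_deg, len(series), usable)
        assert model.tilt_axis_deg == pytest.approx(truth.tilt_axis_deg, abs=0.5)
        # noise-free tracking floor at this patch size (~77 px) is ~0.5 px
        assert model.mean_residual_px < 0.8
        # per-image shifts up to the 3D gauge freedom of the marker cloud
        rad = np.deg2rad(angles)
        rows, rhs = [], []
        for i in range(len(angles)):
            R = model.scale * _rot2(np.deg2rad(model.rotation_deg[i]))
            P = np.array([[np.cos(rad[i]), 0, np.sin(rad[i])], [0, 1, 0]])
            rows.append(R @ P)
            rhs.append(model.shift_px[i] - truth.per_image_shift_px[i])
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        d, *_ = np.linalg.lstsq(A, b, rcond=None)
        res = (b - A @ d).reshape(-1, 2)
        assert np.sqrt((res ** 2).sum(axis=1).mean()) <= 0.5

    def test_corrupted_trajectory_is_pruned(self, prepared_case):
        corrected, table, truth, angles, series = prepared_case
        tset, usable = track_patches(corrected)
        base_model, _ = solve_alignment(tset, corrected.tilt_angles, usable)
        # inject a random-walk trajectory
        rng = np.random.default_rng(4)
        from tiltlive.fine_align import Trajectory

        walk = Trajectory(patch_id=999, birth_tilt=0)
        pos = np.array([60.0, 60.0])
        for i in range(len(corrected)):
            pos = pos + rng.normal(0, 8, 2)
            walk.positions[i] = tuple(pos)
        tset.trajectories.append(walk)
        model, kept = solve_alignment(tset, corrected.tilt_angles, usable)
        assert not kept[-1]
        assert model.axis_residual_deg == pytest.approx(
            base_model.axis_residual_deg, abs=0.1
        )

    def test_insufficient_tracks_raise(self):
        from tiltlive.fine_align import TrajectorySet

        tset = TrajectorySet(trajectories=[], image_shape=(64, 64))
        with pytest.raises(InsufficientTracksError):
            solve_alignment(tset, np.zeros(5), np.ones(5, bool))


class TestApplyAlignment:
    def test_identity_model_returns_input(self, tracking_case):
        series, truth, angles = tracking_case
        n = len(series)
        model = AlignmentModel(
            tilt_axis_deg=0.0, rotation_deg=np.zeros(n),
            shift_px=np.zeros((n, 2)), scale=1.0,
            mean_residual_px=0.0, residual_sigma_px=0.0,
        )
        out, out_angles, kept = apply_alignment(series, model)
        a = series.images[5].pixels[32:-32, 32:-32]
        b = out[5][32:-32, 32:-32]
        assert np.abs(a - b).max() < 1e-6 * max(1.0, np.abs(a).max()) + 1e-3

    def test_composed_transform_matches_two_stage_application(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage as ndi

        base = ndi.gaussian_filter(rng.standard_normal((128, 128)), 1.2)
        rot, shift = 4.0, (6.0, -3.0)
        moved = apply_inplane_transform(base, rot, 1.0, shift)
        from tiltlive.core_io import TiltImage, TiltSeries

        series = TiltSeries(images=[
            TiltImage(pixels=moved.astype(np.float32), tilt_angle_deg=0.0,
                      acquisition_index=0)
        ])
        model = AlignmentModel(
            tilt_axis_deg=rot, rotation_deg=np.array([rot]),
            shift_px=np.array([shift]), scale=1.0,
            mean_residual_px=0.0, residual_sigma_px=0.0,
        )
        out, _, _ = apply_alignment(series, model)
        core = (slice(24, -24),) * 2
        assert np.abs(out[0][core] - base[core]).max() < 0.1

    def test_aligned_features_follow_cosine_law(self, prepared_case):
        corrected, table, truth, angles, series = prepared_case
        tset, usable = track_patches(corrected)
        work_model, _ = solve_alignment(tset, corrected.tilt_angles, usable)
        model = compose_raw_model(work_model, table,
                                 series.nominal_tilt_axis_deg, len(series), usable)
        final = corrected.copy()
        # apply to the raw series (angles corrected, usability from tracking)
        raw = series.copy()
        raw.usable = usable
        aligned, out_angles, kept = apply_alignment(raw, model)
        # track one bright feature across the aligned stack
        from tiltlive.coarse_align import pair_shift

        anchor = int(np.argmin(np.abs(out_angles)))
        drift = []
        for i in range(len(aligned)):
            if i == anchor:
                continue
            ci = np.cos(np.deg2rad(out_angles[i]))
            ca = np.cos(np.deg2rad(out_angles[anchor]))
            from tiltlive.coarse_align import cosine_stretch

            stretched = cosine_stretch(aligned[i], ca / ci)
            dx, dy, q = pair_shift(aligned[anchor], stretched)
            drift.append(np.hypot(dx, dy))
        assert np.median(drift) <= 1.0


def test_imod_transform_inverts_the_model():
    model = AlignmentModel(
        tilt_axis_deg=5.0, rotation_deg=np.array([5.0]),
        shift_px=np.array([[10.0, -4.0]]), scale=1.02,
        mean_residual_px=0.0, residual_sigma_px=0.0,
    )
    rows = imod_transforms(model, [0])
    A = rows[0, :4].reshape(2, 2)
    d = rows[0, 4:]
    # applying A, d to the model's forward map must return the identity
    th = np.deg2rad(5.0)
    M = 1.02 * _rot2(th)
    np.testing.assert_allclose(A @ M, np.eye(2), atol=1e-12)
    np.testing.assert_allclose(A @ np.array([10.0, -4.0]) + d, 0.0, atol=1e-12)
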
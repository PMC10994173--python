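"""Fiducial-free patch tracking and projection-model alignment solving.

Tracking: the 0-degree image is divided into 16 patches of 30% of the image
size on a 4x4 grid.  Each patch is followed outward through the series by
cross-correlating it between neighbouring tilts at its theoretically
expected location.  A measured patch shift that disagrees with the
theoretical shift by more than 2% of the image size means the patch lost
its feature: it is relocated to the most contrasted unused region (chosen
among 200 subpatches) and a fresh trajectory starts there.  An image on
which more than 75% of patches need relocation is dropped as non-usable.

Solving: trajectories are fit to the parallel projection model
``p(k, i) = s * R(theta_i) * P(alpha_i) * X_k + t_i`` with tilt angles
fixed — a scalar Brent search over the global tilt-axis angle first, then
blockwise alternation between marker positions and per-image parameters,
then repeated pruning of trajectories whose residual exceeds three
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .coarse_align import (
    BandpassParams,
    ShiftTable,
    auto_bandpass,
    cosine_stretch,
    pair_shift,
)
from .core_io import TiltSeries
from .synthetic_data import apply_inplane_transform


@dataclass
class TrackerConfig:
    n_patches: int = 16
    patch_frac: float = 0.30
    abnormal_shift_frac: float = 0.02  # of max(image dims)
    n_subpatches: int = 200
    subpatch_grid: tuple[int, int] = (10, 20)  # rows, cols -> 200
    used_core_frac: float = 2.0 / 3.0
    removal_frac: float = 0.75
    min_span: int = 5

    def __post_init__(self) -> None:
        for f in (self.patch_frac, self.abnormal_shift_frac, self.used_core_frac,
                  self.removal_frac):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if self.n_patches < 4:
            raise ValueError("n_patches must be >= 4")


@dataclass
class Trajectory:
    patch_id: int
    positions: dict[int, tuple[float, float]] = field(default_factory=dict)  # tilt idx -> (x, y)
    birth_tilt: int = 0
    status: str = "active"  # active | replaced | outlier


@dataclass
class TrajectorySet:
    trajectories: list[Trajectory]
    image_shape: tuple[int, int]

    def spanning(self, min_span: int) -> list[Trajectory]:
        return [t for t in self.trajectories
                if t.status != "outlier" and len(t.positions) >= min_span]


@dataclass
class AlignmentModel:
    """Solved raw-frame geometry: p_raw = c + scale * R(rot_i) @ q + shift_i.

    ``q`` is the ideal axis-vertical projection position (relative to the
    image centre) of a specimen point.  ``tilt_axis_deg`` is the refined
    global axis; per-image rotations start from it and evolve freely.
    """

    tilt_axis_deg: float
    rotation_deg: np.ndarray  # per image (full in-plane rotation)
    shift_px: np.ndarray  # (n, 2) raw-frame
    scale: float
    mean_residual_px: float
    residual_sigma_px: float
    deleted_tilt_indices: tuple = ()
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.9 <= self.scale <= 1.1:
            raise ValueError(f"implausible scale {self.scale}")


class InsufficientTracksError(RuntimeError):
    pass


def init_patches(zero_tilt_image: np.ndarray, config: TrackerConfig | None = None):
    """16 patch centres on a 4x4 grid symmetric about the image centre."""
    config = config or TrackerConfig()
    h, w = np.asarray(zero_tilt_image).shape
    ph, pw = int(round(config.patch_frac * h)), int(round(config.patch_frac * w))
    if ph >= h or pw >= w:
        raise ValueError("patch larger than image")
    side = int(round(np.sqrt(config.n_patches)))
    ys = (np.arange(side) + 0.5) * h / side
    xs = (np.arange(side) + 0.5) * w / side
    centers = [(float(x), float(y)) for y in ys for x in xs]
    return centers, (ph, pw)


def theoretical_shift(x: float, w: float, alpha_i_deg: float, alpha_j_deg: float) -> float:
    """Expected x-displacement of an in-plane feature between two tilts.

    A specimen-plane point at image x-coordinate ``x`` (tilt axis vertical
    through w/2) sits at sample coordinate X = (x - w/2)/cos(alpha_i) and
    reappears at X*cos(alpha_j), hence dx = (x - w/2)(cos a_j / cos a_i - 1).
    """
    ai, aj = np.deg2rad(alpha_i_deg), np.deg2rad(alpha_j_deg)
    return float((x - w / 2.0) * (np.cos(aj) / np.cos(ai) - 1.0))


def _extract(image: np.ndarray, cx: float, cy: float, ph: int, pw: int):
    """Window of (ph, pw) nearest the requested centre, clamped inside the
    image; returns (window, (x_origin, y_origin)) or (None, None) if the
    centre itself left the image."""
    h, w = image.shape
    if not (0 <= cx < w and 0 <= cy < h):
        return None, None
    y0 = int(np.clip(round(cy) - ph // 2, 0, h - ph))
    x0 = int(np.clip(round(cx) - pw // 2, 0, w - pw))
    return image[y0 : y0 + ph, x0 : x0 + pw], (x0, y0)


def subpatch_contrast(image: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Local standard deviation of each subpatch on a (rows, cols) grid."""
    gr, gc = grid
    h, w = image.shape
    out = np.empty((gr, gc))
    for r in range(gr):
        for c in range(gc):
            sub = image[r * h // gr : (r + 1) * h // gr, c * w // gc : (c + 1) * w // gc]
            out[r, c] = sub.std()
    return out


class RelocationExhaustedError(RuntimeError):
    pass


def relocate_patch(
    image: np.ndarray,
    occupied: set[tuple[int, int]],
    config: TrackerConfig | None = None,
) -> tuple[float, float]:
    """Pick the most contrasted unused subpatch as the new patch centre.

    Marks as used every subpatch whose centre falls in the central
    ``used_core_frac`` of the new patch's surface (mutates ``occupied``).
    """
    config = config or TrackerConfig()
    gr, gc = config.subpatch_grid
    contrast = subpatch_contrast(image, (gr, gc))
    order = np.dstack(np.unravel_index(np.argsort(contrast, axis=None)[::-1], (gr, gc)))[0]
    h, w = image.shape
    ph, pw = config.patch_frac * h, config.patch_frac * w
    for r, c in order:
        if (int(r), int(c)) in occupied:
            continue
        cy = (r + 0.5) * h / gr
        cx = (c + 0.5) * w / gc
        # mark subpatches under the central core of the new patch as used
        core = np.sqrt(config.used_core_frac)
        half_h, half_w = core * ph / 2, core * pw / 2
        for rr in range(gr):
            for cc in range(gc):
                scy = (rr + 0.5) * h / gr
                scx = (cc + 0.5) * w / gc
                if abs(scy - cy) <= half_h and abs(scx - cx) <= half_w:
                    occupied.add((rr, cc))
        return float(cx), float(cy)
    raise RelocationExhaustedError("all subpatches used")


def track_patches(
    series: TiltSeries,
    config: TrackerConfig | None = None,
    peak_threshold: float = 3.0,
) -> tuple[TrajectorySet, np.ndarray]:
    """Track patches outward from the 0-degree image of a prepared series.

    The series must be pair-aligned and positioned (axis vertical, coarse
    shifts removed, tilt angles corrected).  Returns trajectories in the
    working frame plus updated usability flags.
    """
    config = config or TrackerConfig()
    usable = series.usable.copy()
    angles = series.tilt_angles
    idx = np.flatnonzero(usable)
    anchor = int(idx[np.argmin(np.abs(angles[idx]))])
    h, w = series.shape
    centers, (ph, pw) = init_patches(series.images[anchor].pixels, config)
    abnormal_limit = config.abnormal_shift_frac * max(h, w)

    trajs = [Trajectory(patch_id=p, positions={anchor: centers[p]}, birth_tilt=anchor)
             for p in range(len(centers))]
    occupied: set[tuple[int, int]] = set()
    band_cache: dict[int, BandpassParams] = {}
    next_id = len(centers)

    for direction in (+1, -1):
        live = {p: dict(pos=np.array(trajs[p].positions[anchor]), traj=trajs[p])
                for p in range(len(centers))}
        prev = anchor
        j = anchor + direction
        while 0 <= j < len(series):
            if not usable[j]:
                j += direction
                continue
            img_i = np.asarray(series.images[prev].pixels, dtype=float)
            img_j = np.asarray(series.images[j].pixels, dtype=float)
            ci = np.cos(np.deg2rad(angles[prev]))
            cj = np.cos(np.deg2rad(angles[j]))
            f = ci / max(cj, 1e-6)
            wc = np.array([(pw - 1) / 2.0, (ph - 1) / 2.0])
            n_reloc = 0
            moves: dict[int, np.ndarray] = {}
            for p, state in live.items():
                x_i, y_i = state["pos"]
                dx_theo = theoretical_shift(x_i, w, angles[prev], angles[j])
                theo = np.array([x_i + dx_theo, y_i])
                win_a, org_a = _extract(img_i, x_i, y_i, ph, pw)
                win_b, org_b = _extract(img_j, theo[0], theo[1], ph, pw)
                ok = win_a is not None and win_b is not None
                if ok:
                    # undo foreshortening inside the patch before correlating
                    win_b = cosine_stretch(win_b, f)
                    if p not in band_cache:
                        band_cache[p] = auto_bandpass(win_a, win_b)
                    ddx, ddy, q = pair_shift(win_a, win_b, band_cache[p])
                    q_i = state["pos"] - np.asarray(org_a) - wc
                    q_j = np.array([(q_i[0] + ddx) / f, q_i[1] + ddy])
                    pos_j = np.asarray(org_b) + wc + q_j
                    measured = pos_j - state["pos"]
                    deviation = np.linalg.norm(measured - np.array([dx_theo, 0.0]))
                    ok = q >= peak_threshold and deviation <= abnormal_limit
                if ok:
                    moves[p] = state["pos"] + measured
                else:
                    n_reloc += 1
                    moves[p] = None
            if live and n_reloc / len(live) > config.removal_frac:
                usable[j] = False
                j += direction
                continue
            # commit moves; relocate lost patches
            for p in list(live.keys()):
                if moves[p] is not None:
                    live[p]["pos"] = moves[p]
                    live[p]["traj"].positions[j] = tuple(moves[p])
                else:
                    live[p]["traj"].status = "replaced"
                    try:
                        cx, cy = relocate_patch(img_j, occupied, config)
                    except RelocationExhaustedError:
                        del live[p]
                        continue
                    traj = Trajectory(patch_id=next_id, positions={j: (cx, cy)},
                                      birth_tilt=j)
                    next_id += 1
                    trajs.append(traj)
                    live[p] = dict(pos=np.array([cx, cy]), traj=traj)
                    band_cache.pop(p, None)
            prev = j
            j += direction

    tset = TrajectorySet(trajectories=trajs, image_shape=(h, w))
    if len(tset.spanning(config.min_span)) < 4:
        raise InsufficientTracksError("fewer than 4 trajectories span the series")
    return tset, usable


# ---------------------------------------------------------------------------
# Projection-model solver
# ---------------------------------------------------------------------------

def _rot2(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, -s], [s, c]])


def _gather_observations(tset: TrajectorySet, usable_idx: np.ndarray, min_span: int):
    """Per-trajectory dict of image-index -> centre-relative (x, y)."""
    h, w = tset.image_shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    obs = []
    for t in tset.spanning(min_span):
        pts = {i: np.asarray(t.positions[i]) - c for i in t.positions if i in usable_idx}
        if len(pts) >= min_span:
            obs.append(pts)
    return obs


def _solve_markers(obs, thetas, shifts, scale, rad):
    """Linear LSQ for each marker's 3D position given image parameters."""
    markers = []
    for pts in obs:
        rows, rhs = [], []
        for i, p in pts.items():
            q = _rot2(thetas[i]).T @ (p - shifts[i]) / scale
            ca, sa = np.cos(rad[i]), np.sin(rad[i])
            rows.append([ca, 0.0, sa])
            rhs.append(q[0])
            rows.append([0.0, 1.0, 0.0])
            rhs.append(q[1])
        X, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        markers.append(X)
    return np.asarray(markers)


def _project_markers(markers, rad):
    """Planar predicted positions P(alpha_i) X_k for all markers at angle i."""
    ca, sa = np.cos(rad), np.sin(rad)
    qx = markers[:, 0][:, None] * ca[None, :] + markers[:, 2][:, None] * sa[None, :]
    qy = np.broadcast_to(markers[:, 1][:, None], qx.shape)
    return qx, qy  # (K, n_images)


def _fit_image_params(obs, markers, rad, scale, fit_rotation=True, thetas0=None):
    """Per-image rigid (rotation + shift) Procrustes fit at fixed scale."""
    n = len(rad)
    thetas = np.zeros(n) if thetas0 is None else thetas0.copy()
    shifts = np.zeros((n, 2))
    qx, qy = _project_markers(markers, rad)
    by_image: dict[int, list] = {}
    for k, pts in enumerate(obs):
        for i, p in pts.items():
            by_image.setdefault(i, []).append((np.array([qx[k, i], qy[k, i]]), p))
    for i, pairs in by_image.items():
        q = np.array([a for a, _ in pairs]) * scale
        p = np.array([b for _, b in pairs])
        qm, pm = q.mean(axis=0), p.mean(axis=0)
        qc, pc = q - qm, p - pm
        if fit_rotation and len(pairs) >= 2:
            num = float(np.sum(pc[:, 1] * qc[:, 0] - pc[:, 0] * qc[:, 1]))
            den = float(np.sum(pc[:, 0] * qc[:, 0] + pc[:, 1] * qc[:, 1]))
            thetas[i] = np.arctan2(num, den)
        shifts[i] = pm - _rot2(thetas[i]) @ qm
    return thetas, shifts


def _mean_residual(obs, markers, rad, thetas, shifts, scale):
    res = []
    qx, qy = _project_markers(markers, rad)
    for k, pts in enumerate(obs):
        for i, p in pts.items():
            pred = scale * (_rot2(thetas[i]) @ np.array([qx[k, i], qy[k, i]])) + shifts[i]
            res.append(np.linalg.norm(p - pred))
    return np.asarray(res)


def _per_traj_residual(obs, markers, rad, thetas, shifts, scale):
    out = []
    qx, qy = _project_markers(markers, rad)
    for k, pts in enumerate(obs):
        rs = [
            np.linalg.norm(
                p - (scale * (_rot2(thetas[i]) @ np.array([qx[k, i], qy[k, i]])) + shifts[i])
            )
            for i, p in pts.items()
        ]
        out.append(float(np.mean(rs)))
    return np.asarray(out)


def _alternate(obs, rad, thetas, shifts, scale, n_iter, fit_rotation=True,
               fit_scale=False, tol=1e-4):
    """Blockwise alternation markers <-> image params; returns state + residual."""
    prev = np.inf
    markers = None
    for _ in range(n_iter):
        markers = _solve_markers(obs, thetas, shifts, scale, rad)
        markers[:, :] -= markers.mean(axis=0, keepdims=True)
        thetas, shifts = _fit_image_params(obs, markers, rad, scale,
                                           fit_rotation=fit_rotation, thetas0=thetas)
        if fit_scale:
            qx, qy = _project_markers(markers, rad)
            num = den = 0.0
            for k, pts in enumerate(obs):
                for i, p in pts.items():
                    q = _rot2(thetas[i]) @ np.array([qx[k, i], qy[k, i]])
                    num += float(np.dot(p - shifts[i], q))
                    den += float(np.dot(q, q))
            if den > 1e-12:
                scale = float(np.clip(num / den, 0.9, 1.1))
        r = _mean_residual(obs, markers, rad, thetas, shifts, scale).mean()
        if prev - r < tol * max(prev, 1e-12):
            prev = r
            break
        prev = r
    return markers, thetas, shifts, scale, prev


def solve_alignment(
    tset: TrajectorySet,
    tilt_angles_deg: np.ndarray,
    usable: np.ndarray,
    config: TrackerConfig | None = None,
    axis_bracket_deg: float = 10.0,
    max_outer: int = 50,
) -> tuple["AlignmentModelWork", np.ndarray]:
    """Solve the projection model in the working frame.

    Returns the working-frame model (axis residual, per-image rotation and
    shift, scale, residual statistics) and the per-trajectory outlier mask.
    """
    config = config or TrackerConfig()
    angles = np.asarray(tilt_angles_deg, dtype=float)
    usable_idx = set(int(i) for i in np.flatnonzero(usable))
    obs = _gather_observations(tset, usable_idx, config.min_span)
    if len(obs) < 4:
        raise InsufficientTracksError("fewer than 4 usable trajectories")
    rad = np.deg2rad(angles)
    n = len(angles)

    markers0 = _solve_markers(obs, np.zeros(n), np.zeros((n, 2)), 1.0, rad)
    if np.allclose(markers0[:, [0, 1]].std(axis=0), 0):
        raise RuntimeError("degenerate geometry: markers coplanar with the tilt axis")

    # (i) Brent search over the global axis residual, few inner iterations
    def axis_objective(delta_deg):
        thetas = np.full(n, np.deg2rad(delta_deg))
        _, _, _, _, r = _alternate(obs, rad, thetas, np.zeros((n, 2)), 1.0,
                                   n_iter=5, fit_rotation=False)
        return r

    res = minimize_scalar(axis_objective, bounds=(-axis_bracket_deg, axis_bracket_deg),
                          method="bounded", options={"xatol": 0.02})
    delta = float(res.x)

    # (ii) full alternation, rotations free
    thetas = np.full(n, np.deg2rad(delta))
    markers, thetas, shifts, scale, resid = _alternate(
        obs, rad, thetas, np.zeros((n, 2)), 1.0, n_iter=max_outer, fit_scale=True
    )

    # (iii) repeated 3-sigma trajectory pruning
    keep = np.ones(len(obs), dtype=bool)
    for _ in range(10):
        tr = _per_traj_residual([o for o, k in zip(obs, keep) if k],
                                markers[keep], rad, thetas, shifts, scale)
        mu, sd = tr.mean(), tr.std()
        if sd < 1e-12:
            break
        bad_local = tr > mu + 3 * sd
        if not bad_local.any():
            break
        kept_idx = np.flatnonzero(keep)
        if keep.sum() - bad_local.sum() < 4:
            break
        keep[kept_idx[bad_local]] = False
        sub = [o for o, k in zip(obs, keep) if k]
        markers_k, thetas, shifts, scale, resid = _alternate(
            sub, rad, thetas, shifts, scale, n_iter=max_outer, fit_scale=True
        )
        full_markers = np.zeros((len(obs), 3))
        full_markers[keep] = markers_k
        markers = full_markers
    sub = [o for o, k in zip(obs, keep) if k]
    final_res = _mean_residual(sub, markers[keep], rad, thetas, shifts, scale)

    # gauge: zero the anchor image's shift by a rigid marker translation
    anchor = int(min(usable_idx, key=lambda i: abs(angles[i])))
    v = _rot2(thetas[anchor]).T @ shifts[anchor] / scale
    d = np.array([v[0] / max(np.cos(rad[anchor]), 1e-6), v[1], 0.0])
    markers = markers + d
    ca, sa = np.cos(rad), np.sin(rad)
    dq = np.stack([d[0] * ca + d[2] * sa, np.full(n, d[1])], axis=1)
    for i in range(n):
        shifts[i] = shifts[i] - scale * (_rot2(thetas[i]) @ dq[i])

    # the global axis is the common component of the solved rotations;
    # re-reading it here (not from the Brent stage) keeps it outlier-free
    u_list = sorted(usable_idx)
    delta_final = float(np.rad2deg(np.mean(thetas[u_list])))
    model = AlignmentModelWork(
        axis_residual_deg=delta_final,
        rotation_rad=thetas,
        shift_px=shifts,
        scale=scale,
        mean_residual_px=float(final_res.mean()),
        residual_sigma_px=float(final_res.std()),
        markers=markers[keep],
        converged=True,
    )
    return model, keep


@dataclass
class AlignmentModelWork:
    """Working-frame (axis-vertical, coarse-aligned) solved parameters."""

    axis_residual_deg: float
    rotation_rad: np.ndarray
    shift_px: np.ndarray
    scale: float
    mean_residual_px: float
    residual_sigma_px: float
    markers: np.ndarray
    converged: bool = True


def compose_raw_model(
    work: AlignmentModelWork,
    shift_table: ShiftTable,
    nominal_axis_deg: float,
    n_images: int,
    usable: np.ndarray,
) -> AlignmentModel:
    """Compose working-frame solution with the pair-alignment transform.

    Raw-frame mapping of an ideal axis-vertical projection point q:
    ``p_raw = c + scale * R(axis + theta_i) q + R(axis)(t_i + cum_i)``.
    """
    axis = np.deg2rad(nominal_axis_deg)
    Raxis = _rot2(axis)
    rot = np.zeros(n_images)
    shifts = np.zeros((n_images, 2))
    for i in range(n_images):
        rot[i] = nominal_axis_deg + np.rad2deg(work.rotation_rad[i])
        cum = np.asarray(shift_table.shifts.get(i, (0.0, 0.0)))
        shifts[i] = Raxis @ (work.shift_px[i] + cum)
    deleted = tuple(int(i) for i in np.flatnonzero(~np.asarray(usable)))
    return AlignmentModel(
        tilt_axis_deg=nominal_axis_deg + work.axis_residual_deg,
        rotation_deg=rot,
        shift_px=shifts,
        scale=work.scale,
        mean_residual_px=work.mean_residual_px,
        residual_sigma_px=work.residual_sigma_px,
        deleted_tilt_indices=deleted,
        converged=work.converged,
    )


def apply_alignment(
    raw_series: TiltSeries, model: AlignmentModel, order: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample the raw stack into the aligned axis-vertical frame.

    One single interpolation per image: the composed transform (pair shifts
    + solved rotation/scale/shift) is inverted and applied to the raw
    pixels.  Returns (aligned stack, angles, kept raw indices) for usable
    images only, in by-tilt order.
    """
    keep = raw_series.usable_indices()
    h, w = raw_series.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])  # (y, x)
    out = np.empty((keep.size, h, w), dtype=np.float64)
    for n_out, i in enumerate(keep):
        th = np.deg2rad(model.rotation_deg[i])
        # forward map q -> p_raw; affine_transform needs p_raw = M q_abs + off
        M_xy = model.scale * _rot2(th)
        # reorder the (x, y) matrix into (y, x) index order
        M_yx = np.array([[M_xy[1, 1], M_xy[1, 0]], [M_xy[0, 1], M_xy[0, 0]]])
        shift_yx = np.array([model.shift_px[i][1], model.shift_px[i][0]])
        off = c + shift_yx - M_yx @ c
        img = np.asarray(raw_series.images[i].pixels, dtype=float)
        out[n_out] = ndimage.affine_transform(
            img, M_yx, offset=off, order=order, mode="constant", cval=float(img.mean())
        )
    angles = raw_series.tilt_angles[keep]
    return out, angles, keep


def imod_transforms(model: AlignmentModel, indices) -> np.ndarray:
    """Per-image 2x3 transforms (a11 a12 a21 a22 dx dy) in IMOD convention.

    IMOD's .xf maps input (raw) coordinates to aligned coordinates, both
    relative to the image centre: p_out = A p_in + d.  That is the inverse
    of this model's raw-frame map.
    """
    rows = []
    for i in indices:
        th = np.deg2rad(model.rotation_deg[i])
        A = _rot2(th).T / model.scale
        d = -A @ np.asarray(model.shift_px[i])
        rows.append([A[0, 0], A[0, 1], A[1, 0], A[1, 1], d[0], d[1]])
    return np.asarray(rows)
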
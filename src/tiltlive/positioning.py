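"""Tomogram positioning: estimate specimen X/Y pre-tilt from dense flow tracks.

A FIB lamella (or any slab specimen) rarely sits exactly perpendicular to
the beam: it carries static inclinations about the stage X and Y axes.
Feature tracks across the tilt series betray those inclinations without any
reconstruction: patch motions are tracked with dense optical flow, patch 3D
positions are triangulated from the parallel-projection equations, and a
robust plane fit through those points yields the two angles.  The Y tilt is
applied to the tilt angles; the X tilt is used at reconstruction.

Sign conventions (fixed here, covered by synthetic sign tests): with the
tilt axis vertical and x the in-plane axis perpendicular to it,
``y_tilt_deg`` is the angle to *add* to every nominal tilt angle so the
corrected 0-degree image really views the specimen face-on, and positive
``x_tilt_deg`` means the +Y edge of the specimen is closer to the beam
source (plane z = tan(x_tilt) * y in the untilted beam frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import optical_flow_ilk

from .core_io import TiltSeries


@dataclass
class PatchFlowField:
    """Per-patch mean flow vectors between consecutive usable images."""

    patch_centers: np.ndarray  # (P, 2) as (x, y)
    pair_indices: list[tuple[int, int]]
    flows: np.ndarray  # (n_pairs, P, 2) as (dx, dy); NaN where dropped
    grid_shape: tuple[int, int] = (8, 8)


@dataclass
class PlaneFit:
    x_tilt_deg: float
    y_tilt_deg: float
    inlier_mask: np.ndarray
    rms_residual: float
    coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)  # z = a*x + b*y + c

    def __post_init__(self) -> None:
        if abs(self.x_tilt_deg) > 45 or abs(self.y_tilt_deg) > 45:
            raise ValueError("tilt corrections beyond 45 degrees are not plausible")


def dense_flow_track(
    series: TiltSeries,
    grid_shape: tuple[int, int] = (8, 8),
    radius: int = 16,
    variance_factor: float = 16.0,
    plane_coeffs: tuple[float, float] | None = None,
) -> PatchFlowField:
    """Dense optical flow between consecutive usable images, averaged per patch.

    The predictable part of the inter-tilt motion — foreshortening of the
    specimen plane plus, when ``plane_coeffs`` (a, b) of a previous plane
    estimate are given, the Z-relief term — is warped away before the flow
    solve, so the local solver only has to capture the small residual; the
    prediction is added back analytically.  Patch averages are weighted by
    the squared image gradient — flat regions carry no flow information and
    would otherwise dilute the mean toward zero.  Patches whose weighted
    flow variance is far above the median (ratio > ``variance_factor``) are
    dropped (NaN).
    """
    idx = series.usable_indices()
    if idx.size < 2:
        raise ValueError("need at least 2 usable images")
    h, w = series.shape
    gy, gx = grid_shape
    cx_img = (w - 1) / 2.0
    cy_img = (h - 1) / 2.0
    ys = (np.arange(gy) + 0.5) * h / gy
    xs = (np.arange(gx) + 0.5) * w / gx
    centers = np.array([(x, y) for y in ys for x in xs])
    angles = series.tilt_angles
    pair_indices = [(int(idx[k]), int(idx[k + 1])) for k in range(idx.size - 1)]
    flows = np.full((len(pair_indices), len(centers), 2), np.nan)
    per_patch_var = np.full((len(pair_indices), len(centers)), np.nan)
    yy_grid, xx_grid = np.mgrid[0:h, 0:w].astype(float)
    xrel = xx_grid - cx_img
    yrel = yy_grid - cy_img
    pa, pb = (plane_coeffs if plane_coeffs is not None else (0.0, 0.0))
    z_field = pa * xrel + pb * yrel
    for k, (i, j) in enumerate(pair_indices):
        a = np.asarray(series.images[i].pixels, dtype=float)
        b = np.asarray(series.images[j].pixels, dtype=float)
        ai, aj = np.deg2rad(angles[i]), np.deg2rad(angles[j])
        ci, cj = np.cos(ai), np.cos(aj)
        # predicted motion: foreshortening of the specimen plane + its Z relief
        dx_pred = xrel * (cj / max(ci, 1e-6) - 1.0) + z_field * (
            np.sin(aj) - np.sin(ai) * cj / max(ci, 1e-6)
        )
        from scipy import ndimage as _ndi

        b_warp = _ndi.map_coordinates(b, [yy_grid, xx_grid + dx_pred], order=1,
                                      mode="constant", cval=float(b.mean()))
        v_row, v_col = optical_flow_ilk(a, b_warp, radius=radius)
        dx_field = dx_pred + v_col
        dy_field = v_row
        gyy, gxx = np.gradient(a)
        weight = gxx**2 + gyy**2
        for p, (pcx, pcy) in enumerate(centers):
            y0, y1 = int(pcy - h / (2 * gy)), int(pcy + h / (2 * gy))
            x0, x1 = int(pcx - w / (2 * gx)), int(pcx + w / (2 * gx))
            win_w = weight[y0:y1, x0:x1]
            tot = win_w.sum()
            if tot < 1e-12:
                continue
            fx = dx_field[y0:y1, x0:x1]
            fy = dy_field[y0:y1, x0:x1]
            mx = float((fx * win_w).sum() / tot)
            my = float((fy * win_w).sum() / tot)
            flows[k, p] = (mx, my)
            per_patch_var[k, p] = float(
                ((fx - mx) ** 2 * win_w).sum() / tot + ((fy - my) ** 2 * win_w).sum() / tot
            )
        med = np.nanmedian(per_patch_var[k])
        if med > 1e-12:
            bad = per_patch_var[k] > variance_factor * med
            flows[k, bad] = np.nan
    return PatchFlowField(
        patch_centers=centers, pair_indices=pair_indices, flows=flows, grid_shape=grid_shape
    )


def integrate_tracks(flow: PatchFlowField, anchor_pair: int | None = None) -> np.ndarray:
    """Cumulative patch positions per usable image from pairwise flows.

    Returns (n_images_in_chain, P, 2) positions, anchored at the patch
    centres on the chain image nearest the anchor pair boundary.
    """
    n_pairs, P, _ = flow.flows.shape
    n_imgs = n_pairs + 1
    pos = np.full((n_imgs, P, 2), np.nan)
    if anchor_pair is None:
        anchor_pair = n_pairs // 2
    anchor_img = anchor_pair  # left image of the anchor pair
    pos[anchor_img] = flow.patch_centers
    gy, gx = flow.grid_shape
    grid_x = np.unique(flow.patch_centers[:, 0])
    grid_y = np.unique(flow.patch_centers[:, 1])

    def sample(k, pts):
        """Bilinear sample of the coarse patch-flow field at track positions."""
        field = flow.flows[k].reshape(gy, gx, 2)
        fx = np.array(
            [_bilinear(grid_x, grid_y, field[:, :, 0], x, y) for x, y in pts]
        )
        fy = np.array(
            [_bilinear(grid_x, grid_y, field[:, :, 1], x, y) for x, y in pts]
        )
        return np.stack([fx, fy], axis=1)

    for k in range(anchor_img, n_pairs):
        pos[k + 1] = pos[k] + sample(k, pos[k])
    for k in range(anchor_img - 1, -1, -1):
        pos[k] = pos[k + 1] - sample(k, pos[k + 1])
    return pos


def _bilinear(grid_x, grid_y, field, x, y):
    """Bilinear interpolation on a coarse grid, clamped at the borders;
    NaN cells fall back to the nearest finite neighbour average."""
    if not np.isfinite(x) or not np.isfinite(y):
        return np.nan
    ix = np.clip(np.searchsorted(grid_x, x) - 1, 0, len(grid_x) - 2)
    iy = np.clip(np.searchsorted(grid_y, y) - 1, 0, len(grid_y) - 2)
    x0, x1 = grid_x[ix], grid_x[ix + 1]
    y0, y1 = grid_y[iy], grid_y[iy + 1]
    tx = np.clip((x - x0) / max(x1 - x0, 1e-9), 0, 1)
    ty = np.clip((y - y0) / max(y1 - y0, 1e-9), 0, 1)
    corners = np.array([
        [field[iy, ix], field[iy, ix + 1]],
        [field[iy + 1, ix], field[iy + 1, ix + 1]],
    ])
    if np.isnan(corners).any():
        finite = corners[np.isfinite(corners)]
        return float(finite.mean()) if finite.size else np.nan
    top = corners[0, 0] * (1 - tx) + corners[0, 1] * tx
    bot = corners[1, 0] * (1 - tx) + corners[1, 1] * tx
    return float(top * (1 - ty) + bot * ty)


def triangulate_positions(
    flow: PatchFlowField, tilt_angles_deg: np.ndarray, image_shape: tuple[int, int]
) -> np.ndarray:
    """Per-patch (X, Y, Z) by least squares on the parallel projection model.

    With the tilt axis vertical, a point (X, Y, Z) relative to the volume
    centre projects to x = X cos(a) + Z sin(a), y = Y.  A patch needs at
    least 3 tilts with finite positions, else it is dropped.
    """
    angles = np.asarray(tilt_angles_deg, dtype=float)
    n_pairs = len(flow.pair_indices)
    if angles.shape[0] != n_pairs + 1:
        raise ValueError("tilt_angles must cover the usable chain (n_pairs + 1)")
    if len(flow.patch_centers) < 3 or n_pairs + 1 < 5:
        raise ValueError("need >= 3 patches spanning >= 5 tilts")
    anchor = int(np.argmin(np.abs(angles)))
    anchor_pair = min(anchor, n_pairs - 1)
    pos = integrate_tracks(flow, anchor_pair=anchor_pair)
    h, w = image_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rad = np.deg2rad(angles)
    points = []
    for p in range(pos.shape[1]):
        ok = np.isfinite(pos[:, p, 0])
        if ok.sum() < 3:
            continue
        A = np.column_stack([np.cos(rad[ok]), np.sin(rad[ok])])
        bx = pos[ok, p, 0] - cx
        sol, *_ = np.linalg.lstsq(A, bx, rcond=None)
        X, Z = sol
        Y = float(np.mean(pos[ok, p, 1]) - cy)
        points.append((X, Y, Z))
    return np.asarray(points)


class DegenerateFitError(RuntimeError):
    pass


def fit_plane_robust(
    points: np.ndarray, max_iter: int = 10, seed_plane: tuple[float, float] | None = None
) -> PlaneFit:
    """Least-squares plane z = a*x + b*y + c with iterative outlier rejection.

    Points with residual above 3x the MAD-based sigma are dropped and the
    plane refit, up to ``max_iter`` passes.  ``seed_plane`` optionally seeds
    the first residual pass with (a, b) from prior knowledge (e.g. the FIB
    milling pre-tilt), which is then refined.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise DegenerateFitError("need >= 3 points")
    x, y, z = points.T
    spread = np.linalg.matrix_rank(np.column_stack([x - x.mean(), y - y.mean()]))
    if spread < 2:
        raise DegenerateFitError("points are collinear in the XY plane")
    inlier = np.ones(len(points), dtype=bool)
    coeffs = np.array([seed_plane[0], seed_plane[1], 0.0]) if seed_plane else None
    for _ in range(max_iter):
        if coeffs is None or inlier.sum() >= 3:
            A = np.column_stack([x[inlier], y[inlier], np.ones(inlier.sum())])
            coeffs, *_ = np.linalg.lstsq(A, z[inlier], rcond=None)
        res = z - (coeffs[0] * x + coeffs[1] * y + coeffs[2])
        mad = np.median(np.abs(res[inlier] - np.median(res[inlier])))
        sigma = 1.4826 * mad
        if sigma < 1e-9:
            break
        new_inlier = np.abs(res) <= 3 * sigma
        if new_inlier.sum() < 3 or np.array_equal(new_inlier, inlier):
            inlier = new_inlier if new_inlier.sum() >= 3 else inlier
            break
        inlier = new_inlier
    a, b, _ = coeffs
    res = z - (coeffs[0] * x + coeffs[1] * y + coeffs[2])
    rms = float(np.sqrt(np.mean(res[inlier] ** 2))) if inlier.sum() else float("nan")
    return PlaneFit(
        x_tilt_deg=float(-np.rad2deg(np.arctan(b))),
        y_tilt_deg=float(-np.rad2deg(np.arctan(a))),
        inlier_mask=inlier,
        rms_residual=rms,
        coeffs=tuple(float(c) for c in coeffs),
    )


def apply_pretilt_correction(series: TiltSeries, fit: PlaneFit) -> TiltSeries:
    """Add the Y tilt correction to all tilt angles; stash X tilt for SIRT."""
    out = series.copy()
    for im in out.images:
        im.tilt_angle_deg = im.tilt_angle_deg + fit.y_tilt_deg
    out.x_tilt_deg = fit.x_tilt_deg
    return out


def horizontal_image_index(series: TiltSeries) -> int:
    """Index of the usable image whose (corrected) tilt angle is nearest zero."""
    idx = series.usable_indices()
    angles = series.tilt_angles[idx]
    return int(idx[np.argmin(np.abs(angles))])


def run_positioning(
    series: TiltSeries,
    grid_shape: tuple[int, int] = (8, 8),
    bin_factor: int = 2,
    max_tilt_deg: float = 45.0,
    n_passes: int = 4,
) -> tuple[TiltSeries, PlaneFit, dict]:
    """Flow-track, triangulate and plane-fit a pair-aligned series.

    Flow runs on a binned copy restricted to moderate tilts (default
    |tilt| <= 45 deg), where residual motions stay within the local flow
    solver's capture range.  Later passes re-track with the previous plane
    estimate warped away, removing the bias the plane's own relief induces;
    because that feedback is not guaranteed to contract, the pass whose
    plane fit has the smallest inlier RMS wins (goodness-of-fit model
    selection), with an early stop once refits stop improving.
    """
    from .core_io import bin_series

    idx = series.usable_indices()
    keep = idx[np.abs(series.tilt_angles[idx]) <= max_tilt_deg]
    sub = series.copy()
    mask = np.zeros(len(series), dtype=bool)
    mask[keep] = True
    sub.usable = mask
    if bin_factor > 1:
        sub = bin_series(sub, bin_factor)
    angles = sub.tilt_angles[sub.usable_indices()]
    seed = None
    if series.pre_tilt_deg is not None:
        seed = (-np.tan(np.deg2rad(series.pre_tilt_deg)), 0.0)
    plane_coeffs = None
    best_fit = None
    best_points = np.empty((0, 3))
    n_worse = 0
    for _ in range(max(1, n_passes)):
        flow = dense_flow_track(sub, grid_shape=grid_shape, plane_coeffs=plane_coeffs)
        points = triangulate_positions(flow, angles, sub.shape)
        fit = fit_plane_robust(points, seed_plane=seed)
        plane_coeffs = (fit.coeffs[0], fit.coeffs[1])
        if best_fit is None or fit.rms_residual < best_fit.rms_residual:
            best_fit, best_points = fit, points
            n_worse = 0
        else:
            n_worse += 1
            if n_worse >= 2:
                break
    fit, points = best_fit, best_points
    corrected = apply_pretilt_correction(series, fit)
    report = {
        "x_tilt_deg": fit.x_tilt_deg,
        "y_tilt_deg": fit.y_tilt_deg,
        "n_points": int(len(points)),
        "inlier_fraction": float(fit.inlier_mask.mean()) if len(points) else 0.0,
        "rms_residual": fit.rms_residual,
    }
    return corrected, fit, report
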
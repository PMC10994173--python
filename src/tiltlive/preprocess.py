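"""Frame grouping to a target dose and simplified patch-based drift correction.

The motion model is deliberately simple — rigid per-fraction shifts
estimated by cross-correlation against a running average, refined on a
3x3 patch grid, resampled bilinearly and summed with no dose weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import FractionStack

TARGET_DOSE_E_PER_PX = 1.0  # electrons per pixel per grouped fraction


@dataclass
class DriftModel:
    global_shift_per_frame: np.ndarray  # (n, 2) cumulative (dx, dy) px
    patch_shifts: np.ndarray  # (n, 3, 3, 2)
    interpolation: str = "bilinear"


def group_frames(stack: FractionStack) -> FractionStack:
    """Group consecutive frames into fractions of ~1 e-/px.

    Group size g = max(1, round(1 / dose_per_frame)); each fraction is the
    *sum* of its block (i.e. the block average scaled by g), so its expected
    dose is g * dose_per_frame.  Remainder frames fold into the last fraction.
    """
    dose = stack.dose_per_frame_e_per_px
    if not dose or dose <= 0:
        raise ValueError("dose_per_frame_e_per_px unknown; fix the movie metadata")
    g = max(1, int(round(TARGET_DOSE_E_PER_PX / dose)))
    n = stack.n_frames
    if g == 1:
        return stack
    n_fractions = max(1, n // g)
    fracs = []
    for i in range(n_fractions):
        lo = i * g
        hi = (i + 1) * g if i < n_fractions - 1 else n  # fold remainder
        fracs.append(stack.frames[lo:hi].sum(axis=0))
    return FractionStack(
        frames=np.stack(fracs),
        dose_per_frame_e_per_px=dose * g,
        pixel_size_A=stack.pixel_size_A,
    )


def _parabolic_peak(cc: np.ndarray) -> tuple[float, float]:
    """Sub-pixel peak of a correlation surface via 3x3 parabolic fit."""
    h, w = cc.shape
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)

    def refine(vm, v0, vp):
        denom = vm - 2 * v0 + vp
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -1, 1))

    dy = refine(cc[(iy - 1) % h, ix], cc[iy, ix], cc[(iy + 1) % h, ix])
    dx = refine(cc[iy, (ix - 1) % w], cc[iy, ix], cc[iy, (ix + 1) % w])
    # wrap to signed offsets
    sy = iy if iy <= h // 2 else iy - h
    sx = ix if ix <= w // 2 else ix - w
    return sx + dx, sy + dy


def _centroid_peak(cc: np.ndarray, radius: int = 5) -> tuple[float, float]:
    """Sub-pixel peak by centre-of-mass of the (broad) correlation peak.

    Smooth low-dose frames give wide correlation peaks whose 3x3 parabolic
    curvature is noise-dominated; the centroid over a window is stable.
    """
    h, w = cc.shape
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    ys = (np.arange(iy - radius, iy + radius + 1)) % h
    xs = (np.arange(ix - radius, ix + radius + 1)) % w
    win = cc[np.ix_(ys, xs)]
    win = np.clip(win - win.min(), 0, None)
    gy, gx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    tot = win.sum()
    dy = float((win * gy).sum() / tot) if tot > 0 else 0.0
    dx = float((win * gx).sum() / tot) if tot > 0 else 0.0
    sy = iy if iy <= h // 2 else iy - h
    sx = ix if ix <= w // 2 else ix - w
    return sx + dx, sy + dy


def _xcorr_shift(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(dx, dy) such that shifting b by (dx, dy) aligns it to a."""
    A = np.fft.rfft2(a - a.mean())
    B = np.fft.rfft2(b - b.mean())
    cc = np.fft.irfft2(A * np.conj(B), s=a.shape)
    return _centroid_peak(cc)


class ZeroSignalError(ValueError):
    pass


def correct_motion(stack: FractionStack) -> tuple[np.ndarray, DriftModel]:
    """Estimate and correct inter-fraction drift; return (sum image, model).

    Global shifts come from cross-correlating each fraction to a running
    average; a 3x3 patch pass refines them locally.  Fractions are
    bilinearly resampled and summed with no dose weighting.
    """
    frames = np.asarray(stack.frames, dtype=float)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 fractions for motion correction")
    if np.allclose(frames.std(axis=(1, 2)), 0):
        raise ZeroSignalError("all-constant frames carry no signal to align")

    # corrections[i]: shift to apply to fraction i to align it to the average
    corrections = np.zeros((n, 2))
    ref = frames[0].copy()
    n_ref = 1
    for i in range(1, n):
        dx, dy = _xcorr_shift(ref / n_ref, frames[i])
        corrections[i] = (dx, dy)
        ref += ndimage.shift(frames[i], (dy, dx), order=1, mode="nearest")
        n_ref += 1

    h, w = frames.shape[1:]
    patch_shifts = np.zeros((n, 3, 3, 2))
    ph, pw = h // 3, w // 3
    mean_img = ref / n_ref
    if min(ph, pw) >= 32:
        for i in range(1, n):
            aligned = ndimage.shift(
                frames[i], (corrections[i, 1], corrections[i, 0]), order=1, mode="nearest"
            )
            for r in range(3):
                for c in range(3):
                    pa = mean_img[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw]
                    pb = aligned[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw]
                    if pb.std() < 1e-12:
                        continue
                    dx, dy = _xcorr_shift(pa, pb)
                    # keep only small local refinements
                    if abs(dx) <= 4 and abs(dy) <= 4:
                        patch_shifts[i, r, c] = (dx, dy)

    out = np.zeros((h, w))
    for i in range(n):
        local = patch_shifts[i].mean(axis=(0, 1))
        total = corrections[i] + local
        out += ndimage.shift(frames[i], (total[1], total[0]), order=1, mode="nearest")
    # estimated drift is the negative of the applied correction
    model = DriftModel(global_shift_per_frame=-corrections, patch_shifts=patch_shifts)
    return out, model
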
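"""Phantoms and forward-simulated tilt series with known ground truth.

The generator emulates what the alignment/CTF/reconstruction stages see in
a real cryo-ET acquisition of a slab-like specimen (a FIB lamella or a thin
ice layer): parallel-beam projections of features confined to a slab,
per-image shifts and in-plane rotations, a global tilt-axis angle, static
X/Y specimen pre-tilt, a defocus gradient perpendicular to the tilt axis,
Poisson shot noise at the stated electron dose, and grid-bar occlusions at
high tilt.  Every parameter is recorded in a :class:`GroundTruth` so every
pipeline stage can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import FractionStack, TiltImage, TiltSeries
from .reconstruct import forward_project


@dataclass
class GroundTruth:
    """Injected acquisition imperfections for one simulated tilt series."""

    per_image_shift_px: np.ndarray  # (n, 2) as (dx, dy)
    per_image_rotation_deg: np.ndarray  # (n,)
    tilt_axis_deg: float = 0.0
    pre_tilt_x_deg: float = 0.0
    pre_tilt_y_deg: float = 0.0
    defocus_um: np.ndarray | None = None  # (n,)
    astigmatism_um: float = 0.0
    astig_angle_deg: float = 0.0
    slab_thickness_voxels: int = 1
    bad_image_indices: tuple = ()

    def __post_init__(self) -> None:
        self.per_image_shift_px = np.atleast_2d(np.asarray(self.per_image_shift_px, float))
        self.per_image_rotation_deg = np.atleast_1d(
            np.asarray(self.per_image_rotation_deg, float)
        )
        if len(self.per_image_shift_px) != len(self.per_image_rotation_deg):
            raise ValueError("shift and rotation lists must have equal length")
        if self.defocus_um is not None:
            self.defocus_um = np.atleast_1d(np.asarray(self.defocus_um, float))
        if self.slab_thickness_voxels < 1:
            raise ValueError("slab_thickness_voxels must be >= 1")

    @classmethod
    def zero(cls, n: int, **kw) -> "GroundTruth":
        return cls(
            per_image_shift_px=np.zeros((n, 2)),
            per_image_rotation_deg=np.zeros(n),
            **kw,
        )


@dataclass
class PhantomSpec:
    """Recipe for a slab phantom volume.

    ``volume_shape`` is (nx, ny, nz); the produced array is indexed
    ``[z, y, x]``.  Features are confined to a horizontal slab of
    ``slab_thickness_voxels`` planes centred in Z.
    """

    volume_shape: tuple[int, int, int] = (128, 128, 64)
    slab_thickness_voxels: int = 24
    n_features: int = 60
    feature_kinds: tuple = ("spheres", "shells", "rods")
    density_contrast: float = 1.0
    background: float = 0.1
    smooth_sigma: float = 0.8  # band-limit: real densities are resolution-limited
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.volume_shape
        if self.slab_thickness_voxels > nz:
            raise ValueError("slab must fit inside the volume")
        if self.n_features < 0:
            raise ValueError("n_features must be >= 0")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic slab phantom: background slab plus positive features."""
    nx, ny, nz = spec.volume_shape
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros((nz, ny, nx))
    z0 = (nz - spec.slab_thickness_voxels) // 2
    z1 = z0 + spec.slab_thickness_voxels
    vol[z0:z1] = spec.background

    max_r = max(2, spec.slab_thickness_voxels // 3)
    if max_r * 2 > spec.slab_thickness_voxels and spec.n_features > 0:
        max_r = max(1, spec.slab_thickness_voxels // 2)
    for _ in range(spec.n_features):
        kind = spec.feature_kinds[rng.integers(len(spec.feature_kinds))]
        r = float(rng.uniform(2, max_r + 1e-9))
        # centres fill the whole slab; features crossing a slab face are
        # truncated below, as FIB milling truncates real structures
        cz = rng.uniform(z0, z1)
        cy = rng.uniform(r, ny - r)
        cx = rng.uniform(r, nx - r)
        amp = spec.density_contrast * float(rng.uniform(0.5, 1.5))
        L = 3 * r  # rod half-length
        ext = L + r
        zl, zh = max(0, int(cz - ext)), min(nz, int(cz + ext) + 2)
        yl, yh = max(0, int(cy - ext)), min(ny, int(cy + ext) + 2)
        xl, xh = max(0, int(cx - ext)), min(nx, int(cx + ext) + 2)
        zz, yy, xx = np.meshgrid(
            np.arange(zl, zh), np.arange(yl, yh), np.arange(xl, xh), indexing="ij"
        )
        box = vol[zl:zh, yl:yh, xl:xh]
        if kind == "rods":
            theta = rng.uniform(0, np.pi)
            ux, uy = np.cos(theta), np.sin(theta)
            t = (xx - cx) * ux + (yy - cy) * uy
            perp2 = ((xx - cx) - t * ux) ** 2 + ((yy - cy) - t * uy) ** 2 + (zz - cz) ** 2
            box += amp * (
                (np.abs(t) <= L) & (perp2 <= (0.5 * r) ** 2) & (np.abs(zz - cz) <= 0.5 * r)
            )
        else:
            d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            if kind == "spheres":
                box += amp * (d2 <= r**2)
            else:  # shells
                box += amp * ((d2 <= r**2) & (d2 >= (0.6 * r) ** 2))
    # band-limit the density (voxelised hard edges carry frequencies no
    # instrument records), then truncate at the slab faces as milling does
    if spec.smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, spec.smooth_sigma)
    vol[:z0] = 0.0
    vol[z1:] = 0.0
    return vol


def apply_inplane_transform(
    image: np.ndarray,
    rot_deg: float,
    scale: float = 1.0,
    shift: tuple[float, float] = (0.0, 0.0),
    order: int = 3,
) -> np.ndarray:
    """Rotate an image CCW by ``rot_deg`` about its centre, scale, then shift.

    A feature at centre-relative position q (x, y) lands at
    ``scale * R(rot) @ q + shift``.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])  # (y, x)
    th = np.deg2rad(rot_deg)
    # R acts on (x, y); express in (y, x) index order
    R_yx = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]) * scale
    Minv = np.linalg.inv(R_yx)
    shift_yx = np.array([shift[1], shift[0]])
    offset = c - Minv @ (c + shift_yx)
    return ndimage.affine_transform(
        image, Minv, offset=offset, order=order, mode="constant", cval=float(np.mean(image))
    )


def invert_inplane_params(
    rot_deg: float, scale: float, shift: tuple[float, float]
) -> tuple[float, float, tuple[float, float]]:
    """Parameters of the inverse of :func:`apply_inplane_transform`."""
    th = np.deg2rad(rot_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    inv_shift = -(R.T @ np.asarray(shift)) / scale
    return -rot_deg, 1.0 / scale, (float(inv_shift[0]), float(inv_shift[1]))


def project_tilt_series(
    volume: np.ndarray,
    angles_deg,
    truth: GroundTruth,
    pixel_size_A: float = 2.0,
    dose_e_per_A2: float = 3.0,
    fov_px: int | None = None,
) -> TiltSeries:
    """Forward-simulate a tilt series from a phantom and a ground truth.

    Projection is a parallel-beam line integral about the Y axis at
    ``angle + pre_tilt_y`` after a static ``pre_tilt_x`` rotation; each
    projection is then rotated in-plane by ``tilt_axis + rotation_i``,
    scaled, and shifted by the injected per-image shift.  ``fov_px`` crops
    the central field of view after the transform — use a volume wider
    than the field so the specimen fills every image even at high tilt,
    as a real (laterally extended) specimen does.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if len(angles) != len(truth.per_image_shift_px):
        raise ValueError("truth length must match angle count")
    nz, ny, nx = np.asarray(volume).shape
    fov = nx * np.cos(np.deg2rad(np.max(np.abs(angles)))) + nz * np.sin(
        np.deg2rad(np.max(np.abs(angles)))
    )
    if fov > nx * 1.5:
        import warnings

        warnings.warn("volume may not cover the field of view at max tilt")
    eff_angles = angles + truth.pre_tilt_y_deg
    projs = forward_project(volume, eff_angles, x_tilt_deg=truth.pre_tilt_x_deg)
    images = []
    defoci = truth.defocus_um if truth.defocus_um is not None else np.zeros(len(angles))
    for i, ang in enumerate(angles):
        rot = truth.tilt_axis_deg + truth.per_image_rotation_deg[i]
        img = apply_inplane_transform(
            projs[i], rot, 1.0, tuple(truth.per_image_shift_px[i])
        )
        if fov_px is not None:
            r0 = (img.shape[0] - fov_px) // 2
            c0 = (img.shape[1] - fov_px) // 2
            img = img[r0 : r0 + fov_px, c0 : c0 + fov_px]
        images.append(
            TiltImage(
                pixels=img.astype(np.float32),
                tilt_angle_deg=float(ang),
                applied_defocus_um=float(defoci[i]),
                dose_e_per_A2=dose_e_per_A2,
                acquisition_index=i,
            )
        )
    return TiltSeries(
        images=images,
        pixel_size_A=pixel_size_A,
        nominal_tilt_axis_deg=truth.tilt_axis_deg,
        pre_tilt_deg=truth.pre_tilt_y_deg if truth.pre_tilt_y_deg else None,
        order="by_tilt" if np.all(np.diff(angles) >= 0) else "acquisition",
    )


def _ctf_2d(shape, pixel_size_A, defocus_um, optics, astig_um=0.0, astig_angle_deg=0.0):
    from .ctf import ctf_model, OpticsParams

    optics = optics or OpticsParams()
    h, w = shape
    ky = np.fft.fftfreq(h, d=pixel_size_A)[:, None]
    kx = np.fft.fftfreq(w, d=pixel_size_A)[None, :]
    k = np.hypot(kx, ky)
    az = np.arctan2(ky, kx)
    return ctf_model(defocus_um, astig_um, astig_angle_deg, optics, k, az)


def defocus_at_offset(
    defocus_um: float,
    offset_px: float,
    pixel_size_A: float,
    tilt_deg: float,
    sign: float = 1.0,
) -> float:
    """Local defocus at a signed distance from the (vertical) tilt axis.

    The specimen plane at in-plane distance d from the axis sits
    ``d * px * tan(tilt)`` further from focus: f(d) = f0 + d*px*tan(a),
    converted to micrometres.
    """
    return float(
        defocus_um + sign * offset_px * pixel_size_A * np.tan(np.deg2rad(tilt_deg)) * 1e-4
    )


def apply_ctf_and_noise(
    series: TiltSeries,
    truth: GroundTruth,
    dose_e_per_A2: float = 3.0,
    seed: int = 0,
    optics=None,
    n_strips: int = 16,
    ice_contrast: float = 0.08,
    structure_contrast: float = 0.25,
    gradient_sign: float = 1.0,
    thickness_mfp_ratio: float = 0.4,
) -> TiltSeries:
    """Apply a phase-contrast CTF with a tilt defocus gradient, then shot noise.

    The defocus seen by a column at signed distance d (px) from the vertical
    tilt axis is ``f0 + sign * d * pixel_size * tan(alpha)``; the image is
    processed in column strips, each filtered with its local CTF.  A weak
    broadband "ice" texture is added to the contrast so the power spectrum
    carries Thon rings at all frequencies, as amorphous ice does.  Poisson
    noise is drawn at ``dose_e_per_A2 * pixel_size**2`` electrons per pixel,
    attenuated by the longer inelastic path through the tilted slab
    (transmission exp(-tau * (1/cos(a) - 1)), tau = thickness over the
    inelastic mean free path).
    """
    if dose_e_per_A2 <= 0:
        raise ValueError("dose must be > 0")
    if truth.defocus_um is None:
        raise ValueError("truth.defocus_um required")
    if np.any(truth.defocus_um <= 0):
        raise ValueError("defocus values must be positive (underfocus)")
    rng = np.random.default_rng(seed)
    px = series.pixel_size_A
    dose_per_px = dose_e_per_A2 * px**2
    out_images = []
    h, w = series.shape
    cx = (w - 1) / 2.0
    edges = np.linspace(0, w, n_strips + 1).astype(int)
    for i, im in enumerate(series.images):
        img = np.asarray(im.pixels, dtype=float)
        mean = float(img.mean()) or 1.0
        contrast = (img - mean) / max(abs(mean), 1e-9)
        # weak-phase object: cap the structural contrast amplitude so the
        # intensity model 1 + contrast stays positive (no clipping
        # nonlinearity, which would distort the Thon-ring positions)
        cstd = float(contrast.std())
        if cstd > structure_contrast:
            contrast = contrast * (structure_contrast / cstd)
        contrast = contrast + ice_contrast * rng.standard_normal(img.shape)
        filtered = np.empty_like(contrast)
        F = np.fft.fft2(contrast)
        for s in range(n_strips):
            x0, x1 = edges[s], edges[s + 1]
            if x1 <= x0:
                continue
            d = (0.5 * (x0 + x1 - 1) - cx)  # strip centre offset, px
            f_local = defocus_at_offset(
                truth.defocus_um[i], d, px, im.tilt_angle_deg, gradient_sign
            )
            ctf = _ctf_2d(img.shape, px, f_local, optics,
                          truth.astigmatism_um, truth.astig_angle_deg)
            strip = np.fft.ifft2(F * (-ctf)).real
            filtered[:, x0:x1] = strip[:, x0:x1]
        cos_a = max(np.cos(np.deg2rad(im.tilt_angle_deg)), 0.2)
        transmission = np.exp(-thickness_mfp_ratio * (1.0 / cos_a - 1.0))
        expected = dose_per_px * transmission * np.clip(1.0 + filtered, 1e-6, None)
        noisy = rng.poisson(expected).astype(np.float32)
        out_images.append(
            TiltImage(
                pixels=noisy,
                tilt_angle_deg=im.tilt_angle_deg,
                applied_defocus_um=float(truth.defocus_um[i]),
                dose_e_per_A2=dose_e_per_A2,
                acquisition_index=im.acquisition_index,
            )
        )
    return series.copy(images=out_images)


def occlude_grid_bar(
    series: TiltSeries, indices, coverage_fraction: float, seed: int = 0
) -> TiltSeries:
    """Blank a contiguous band of rows on the listed images (grid bar)."""
    if not 0 <= coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in [0, 1]")
    indices = list(np.atleast_1d(indices).astype(int))
    for idx in indices:
        if not 0 <= idx < len(series):
            raise IndexError(f"image index {idx} out of range")
    out = series.copy()
    if coverage_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    h = series.shape[0]
    n_rows = int(round(coverage_fraction * h))
    for idx in indices:
        img = out.images[idx].pixels.astype(float).copy()
        scale = max(abs(img.mean()), 1.0)
        band = np.clip(0.01 * scale * rng.standard_normal((n_rows, img.shape[1])), 0, None)
        img[:n_rows] = band
        out.images[idx].pixels = img.astype(np.float32)
    return out


def simulate_fraction_stack(
    image: np.ndarray,
    dose_per_frame_e_per_px: float,
    n_frames: int,
    drift_path=None,
    seed: int = 0,
    pixel_size_A: float = 1.0,
) -> FractionStack:
    """Simulate a dose-fractionated movie of a (mean-normalised) reference image.

    Each frame is the reference shifted by the cumulative drift, scaled to
    the per-frame dose and Poisson-sampled.
    """
    if dose_per_frame_e_per_px <= 0:
        raise ValueError("dose_per_frame must be > 0")
    if drift_path is None:
        drift_path = np.zeros((n_frames, 2))
    drift_path = np.asarray(drift_path, dtype=float)
    if len(drift_path) != n_frames:
        raise ValueError("drift_path must have n_frames entries")
    image = np.asarray(image, dtype=float)
    norm = image / max(image.mean(), 1e-12)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames,) + image.shape, dtype=np.float32)
    cum = np.cumsum(drift_path, axis=0)
    for f in range(n_frames):
        dx, dy = cum[f]
        shifted = ndimage.shift(norm, (dy, dx), order=1, mode="nearest")
        expected = np.clip(dose_per_frame_e_per_px * shifted, 0, None)
        frames[f] = rng.poisson(expected)
    return FractionStack(
        frames=frames,
        dose_per_frame_e_per_px=dose_per_frame_e_per_px,
        pixel_size_A=pixel_size_A,
    )


def dose_symmetric_angles(
    max_tilt: float = 60.0, step: float = 3.0, group: int = 2
) -> np.ndarray:
    """Acquisition-order dose-symmetric scheme (group-wise side alternation).

    The 0-degree image fills the first slot of the first group, so group 2
    with a 3-degree step records 0, +3, -3, -6, +6, +9, -9, ...
    """
    n_side = int(round(max_tilt / step))
    order = [0.0]
    pos_next = neg_next = 1
    for _ in range(group - 1):
        if pos_next <= n_side:
            order.append(pos_next * step)
            pos_next += 1
    side = -1
    while pos_next <= n_side or neg_next <= n_side:
        for _ in range(group):
            if side < 0 and neg_next <= n_side:
                order.append(-neg_next * step)
                neg_next += 1
            elif side > 0 and pos_next <= n_side:
                order.append(pos_next * step)
                pos_next += 1
        side = -side
    return np.array(order)


def default_truth(
    n: int,
    seed: int = 0,
    max_shift_px: float = 20.0,
    max_rot_deg: float = 1.0,
    tilt_axis_deg: float = 85.0,
    pre_tilt_x_deg: float = 0.0,
    pre_tilt_y_deg: float = 0.0,
    defocus_um: float = 3.0,
    slab_thickness_voxels: int = 24,
) -> GroundTruth:
    """A realistic random ground truth; the 0-degree image is the shift anchor."""
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(-max_shift_px, max_shift_px, size=(n, 2))
    rots = rng.uniform(-max_rot_deg, max_rot_deg, size=n)
    return GroundTruth(
        per_image_shift_px=shifts,
        per_image_rotation_deg=rots,
        tilt_axis_deg=tilt_axis_deg,
        pre_tilt_x_deg=pre_tilt_x_deg,
        pre_tilt_y_deg=pre_tilt_y_deg,
        defocus_um=np.full(n, defocus_um),
        slab_thickness_voxels=slab_thickness_voxels,
    )
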
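"""Domain types for tilt series and MRC/TIFF readers and writers.

Conventions used throughout the package
---------------------------------------
* Images are 2D numpy arrays indexed ``[row, col]``; x = column, y = row,
  0-based, origin at the top-left corner.
* All shifts are in pixels at the working binning.
* Angles are degrees.  The tilt-axis angle is measured counter-clockwise
  from the image Y axis, so rotating an image by ``-tilt_axis_deg`` brings
  the tilt axis vertical.
* Stage tilt is a rotation about the (axis-vertical) image Y axis; positive
  tilt moves +X sample points towards the beam source, so the defocus of a
  strip at signed distance ``d`` px from the axis is
  ``f0 + d * pixel_size * tan(alpha)`` (configurable sign, see `ctf`).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import mrcfile
import tifffile


class MetadataMismatchError(ValueError):
    """Acquisition metadata does not match the image stack."""


class FormatError(IOError):
    """Unreadable or truncated image file."""


class EmptyOutputError(ValueError):
    """A write was requested that would produce zero images."""


@dataclass
class TiltImage:
    """One projection image of a tilt series plus its acquisition metadata."""

    pixels: np.ndarray
    tilt_angle_deg: float
    applied_defocus_um: float = 0.0
    dose_e_per_A2: float = 0.0
    acquisition_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not abs(self.tilt_angle_deg) <= 90:
            raise ValueError(f"|tilt_angle_deg| must be <= 90, got {self.tilt_angle_deg}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TiltSeries:
    """Ordered stack of tilt images; the object every pipeline stage transforms.

    ``order`` is ``"acquisition"`` or ``"by_tilt"``.  ``usable`` flags are
    updated (never removed) by the cleaning/alignment stages; downstream
    stages and exporters honour them.
    """

    images: list[TiltImage]
    pixel_size_A: float = 1.0
    nominal_tilt_axis_deg: float = 0.0
    pre_tilt_deg: float | None = None
    usable: np.ndarray | None = None
    order: str = "acquisition"
    # set by the positioning stage, consumed at reconstruction
    x_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.usable is None:
            self.usable = np.ones(len(self.images), dtype=bool)
        self.usable = np.asarray(self.usable, dtype=bool)
        if len(self.usable) != len(self.images):
            raise ValueError("usable flags must match image count")
        shapes = {im.pixels.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"all images must share dimensions, got {shapes}")
        idx = [im.acquisition_index for im in self.images]
        if len(set(idx)) != len(idx):
            raise ValueError("acquisition_index must be unique within a series")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def tilt_angles(self) -> np.ndarray:
        return np.array([im.tilt_angle_deg for im in self.images], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].pixels.shape

    def stack(self) -> np.ndarray:
        """Pixels as a (n, rows, cols) array in the series' current order."""
        return np.stack([im.pixels for im in self.images])

    def usable_indices(self) -> np.ndarray:
        return np.flatnonzero(self.usable)

    def copy(self, **changes) -> "TiltSeries":
        imgs = [replace(im, pixels=im.pixels) for im in self.images]
        kwargs = dict(
            images=imgs,
            pixel_size_A=self.pixel_size_A,
            nominal_tilt_axis_deg=self.nominal_tilt_axis_deg,
            pre_tilt_deg=self.pre_tilt_deg,
            usable=self.usable.copy(),
            order=self.order,
            x_tilt_deg=self.x_tilt_deg,
        )
        kwargs.update(changes)
        return TiltSeries(**kwargs)


@dataclass
class FractionStack:
    """Dose-fractionated movie: frames of electron counts for one exposure."""

    frames: np.ndarray
    dose_per_frame_e_per_px: float
    pixel_size_A: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (frame, row, col)")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.dose_per_frame_e_per_px > 0:
            raise ValueError("dose_per_frame_e_per_px must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_rawtlt(path: str | os.PathLike) -> np.ndarray:
    """Read an IMOD-style .rawtlt file: one tilt angle (degrees) per line."""
    return np.loadtxt(path, ndmin=1, dtype=float)


def read_metadata_sidecar(path: str | os.PathLike) -> dict:
    """Read a JSON metadata sidecar (tilt angles, defoci, doses, pixel size)."""
    with open(path) as fh:
        return json.load(fh)


def _read_pixels(path: Path) -> tuple[np.ndarray, float | None]:
    """Return (stack-or-image array, header pixel size or None)."""
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path)), None
        with mrcfile.open(path, permissive=True) as mrc:
            data = np.asarray(mrc.data).copy()
            px = float(mrc.voxel_size.x) if mrc.voxel_size.x else None
            return data, px
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


def read_tilt_series(path: str | os.PathLike, metadata: dict) -> TiltSeries:
    """Read a tilt series from an MRC stack or a directory of per-tilt files.

    ``metadata`` must supply ``tilt_angles_deg`` (list, one per image) and may
    supply ``pixel_size_A``, ``applied_defocus_um`` (scalar or list),
    ``dose_e_per_A2`` (scalar or list), ``nominal_tilt_axis_deg`` and
    ``pre_tilt_deg``.  Pixel size falls back to the MRC header.
    """
    path = Path(path)
    angles = np.atleast_1d(np.asarray(metadata["tilt_angles_deg"], dtype=float))
    header_px: float | None = None
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".mrc", ".st", ".tif", ".tiff")
        )
        if not files:
            raise FormatError(f"no MRC/TIFF files in {path}")
        planes = []
        for f in files:
            data, px = _read_pixels(f)
            if data.ndim == 3:
                planes.extend(np.asarray(data))
            else:
                planes.append(data)
            header_px = header_px or px
        data = np.stack(planes)
    else:
        data, header_px = _read_pixels(path)
        if data.ndim == 2:
            data = data[None]
    if data.shape[0] != len(angles):
        raise MetadataMismatchError(
            f"{data.shape[0]} images but {len(angles)} tilt angles"
        )

    n = len(angles)

    def _per_image(key: str, default: float) -> np.ndarray:
        val = metadata.get(key, default)
        return np.broadcast_to(np.asarray(val, dtype=float), (n,)).copy()

    defoci = _per_image("applied_defocus_um", 0.0)
    doses = _per_image("dose_e_per_A2", 0.0)
    images = [
        TiltImage(
            pixels=np.asarray(data[i], dtype=np.float32),
            tilt_angle_deg=float(angles[i]),
            applied_defocus_um=float(defoci[i]),
            dose_e_per_A2=float(doses[i]),
            acquisition_index=i,
        )
        for i in range(n)
    ]
    pixel_size = metadata.get("pixel_size_A") or header_px or 1.0
    return TiltSeries(
        images=images,
        pixel_size_A=float(pixel_size),
        nominal_tilt_axis_deg=float(metadata.get("nominal_tilt_axis_deg", 0.0)),
        pre_tilt_deg=metadata.get("pre_tilt_deg"),
        order="acquisition",
    )


def write_tilt_series(
    series: TiltSeries, path: str | os.PathLike, include_unusable: bool = True
) -> Path:
    """Write a series as an MRC mode-2 stack.

    With ``include_unusable=False`` only usable images are written, in
    by-tilt order — the clean stack the exporters reference.
    """
    if not len(series):
        raise EmptyOutputError("series is empty")
    if include_unusable:
        sub = series
    else:
        keep = series.usable_indices()
        if keep.size == 0:
            raise EmptyOutputError("no usable images to write")
        sub = TiltSeries(
            images=[series.images[i] for i in keep],
            pixel_size_A=series.pixel_size_A,
            nominal_tilt_axis_deg=series.nominal_tilt_axis_deg,
            pre_tilt_deg=series.pre_tilt_deg,
            order=series.order,
        )
        sub = reorder_by_tilt(sub)
    data = np.stack([im.pixels.astype(np.float32) for im in sub.images])
    path = Path(path)
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(data)
        mrc.voxel_size = series.pixel_size_A
    return path


def reorder_by_tilt(series: TiltSeries) -> TiltSeries:
    """Sort images ascending by tilt angle (stable: ties keep acquisition order)."""
    order = sorted(
        range(len(series)),
        key=lambda i: (series.images[i].tilt_angle_deg, series.images[i].acquisition_index),
    )
    return series.copy(
        images=[series.images[i] for i in order],
        usable=series.usable[order],
        order="by_tilt",
    )


def bin_image(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Downsample an image by ``factor``.

    Integer factors use block-mean pooling (exact; a constant image stays
    constant).  Non-integer factors use Fourier cropping of the centred
    spectrum, normalised so the mean intensity is preserved.
    """
    pixels = np.asarray(pixels, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = pixels.shape
    out_h, out_w = int(h // factor), int(w // factor)
    if out_h < 1 or out_w < 1:
        raise ValueError(f"factor {factor} larger than image {pixels.shape}")
    if float(factor).is_integer():
        f = int(factor)
        trimmed = pixels[: out_h * f, : out_w * f]
        return trimmed.reshape(out_h, f, out_w, f).mean(axis=(1, 3))
    spec = np.fft.fftshift(np.fft.fft2(pixels))
    cy, cx = h // 2, w // 2
    half_h, half_w = out_h // 2, out_w // 2
    crop = spec[cy - half_h : cy - half_h + out_h, cx - half_w : cx - half_w + out_w]
    out = np.fft.ifft2(np.fft.ifftshift(crop)).real
    # ifft2 divides by the (smaller) output size; rescale so the mean is kept
    return out * (out_h * out_w) / (h * w)


def bin_series(series: TiltSeries, factor: float) -> TiltSeries:
    """Bin every image of a series; pixel size scales by the factor."""
    imgs = [replace(im, pixels=bin_image(im.pixels, factor)) for im in series.images]
    return series.copy(images=imgs, pixel_size_A=series.pixel_size_A * factor)
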
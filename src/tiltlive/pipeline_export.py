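"""End-to-end pipeline orchestration, quality metrics and file export.

Runs the full on-the-fly processing chain — stack cleaning, pair
alignment, tomogram positioning, patch tracking + model solving, CTF
determination and SIRT reconstruction — and writes the alignment, CTF and
reconstruction results in the formats downstream tools read (IMOD
transform/angle files, a Ctfplotter defocus table, RELION-style STAR and
order-list files).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coarse_align, ctf, fine_align, positioning, reconstruct, stack_cleaner
from .core_io import TiltSeries, read_tilt_series, reorder_by_tilt, write_tilt_series


@dataclass
class PipelineConfig:
    seed: int = 0
    cleaner: stack_cleaner.CleanerConfig = field(default_factory=stack_cleaner.CleanerConfig)
    tracker: fine_align.TrackerConfig = field(default_factory=fine_align.TrackerConfig)
    recon: reconstruct.ReconstructionConfig = field(default_factory=reconstruct.ReconstructionConfig)
    optics: ctf.OpticsParams = field(default_factory=ctf.OpticsParams)
    run_ctf: bool = True
    run_reconstruction: bool = True
    applied_defocus_um: float | None = None


@dataclass
class QualityMetrics:
    """The per-series quality numbers a user filters tomograms by."""

    alignment_accuracy_px: float
    n_deleted_slices: int
    tilt_axis_correction_deg: float
    defocus_um: float
    ctf_confidence_range_A: float
    astigmatism_um: float

    def to_dict(self) -> dict:
        return {
            "alignment_accuracy_px": self.alignment_accuracy_px,
            "n_deleted_slices": self.n_deleted_slices,
            "tilt_axis_correction_deg": self.tilt_axis_correction_deg,
            "defocus_um": self.defocus_um,
            "ctf_confidence_range_A": self.ctf_confidence_range_A,
            "astigmatism_um": self.astigmatism_um,
        }


@dataclass
class PipelineResult:
    series: TiltSeries  # by-tilt order, corrected angles, final usability
    shift_table: coarse_align.ShiftTable
    plane_fit: positioning.PlaneFit
    model: fine_align.AlignmentModel
    aligned_stack: np.ndarray
    aligned_angles: np.ndarray
    aligned_indices: np.ndarray
    ctf_fit: ctf.CTFFit | None
    tomogram: reconstruct.Tomogram | None
    metrics: QualityMetrics
    reports: dict
    nominal_tilt_angles: np.ndarray | None = None


def compute_quality_metrics(
    model: fine_align.AlignmentModel,
    usable: np.ndarray,
    nominal_tilt_axis_deg: float,
    ctf_fit: ctf.CTFFit | None,
) -> QualityMetrics:
    """Assemble the quality metrics from the solved stages.

    Deleted slices counts every image any stage marked non-usable (the
    union of cleaner, pair-alignment and tracking removals is exactly what
    the final ``usable`` flags encode).
    """
    n_deleted = int(np.sum(~np.asarray(usable, dtype=bool)))
    if ctf_fit is not None:
        defoci = np.atleast_1d(ctf_fit.defocus_um)
        finite = defoci[np.isfinite(defoci)]
        # reported Defocus is the horizontal image's (the central fit)
        defocus = float(np.median(finite)) if finite.size else float("nan")
        conf = float(ctf_fit.confidence_range_A)
        astig = float(ctf_fit.astigmatism_um)
    else:
        defocus = conf = astig = float("nan")
    return QualityMetrics(
        alignment_accuracy_px=float(model.mean_residual_px),
        n_deleted_slices=n_deleted,
        tilt_axis_correction_deg=float(model.tilt_axis_deg - nominal_tilt_axis_deg),
        defocus_um=defocus,
        ctf_confidence_range_A=conf,
        astigmatism_um=astig,
    )


def run_pipeline(
    series: TiltSeries | str | os.PathLike,
    config: PipelineConfig | None = None,
    metadata: dict | None = None,
) -> PipelineResult:
    """Execute every processing stage in order on a tilt series.

    Deterministic for a fixed input and config.  Non-fatal issues
    accumulate in ``result.reports``; a stage that cannot proceed raises
    with its name in the message.
    """
    config = config or PipelineConfig()
    if not isinstance(series, TiltSeries):
        if metadata is None:
            raise ValueError("metadata required when reading from a path")
        series = read_tilt_series(series, metadata)
    reports: dict = {}

    series = reorder_by_tilt(series)
    nominal_angles = series.tilt_angles.copy()

    # 1. stack cleaner
    series, reports["cleaner"] = stack_cleaner.clean_series(series, config.cleaner)

    # 2. pair alignment (axis-vertical working frame)
    work = coarse_align.rotate_axis_vertical(series)
    try:
        table, usable = coarse_align.align_pairs(work)
    except coarse_align.AnchorQualityError as exc:
        raise RuntimeError(f"pair alignment failed: {exc}") from exc
    work = coarse_align.apply_shift_table(work, table)
    work.usable = usable
    reports["pair_alignment"] = {
        "n_usable": int(usable.sum()),
        "skipped_pairs": table.skipped_pairs,
    }

    # 3. tomogram positioning
    corrected_work, plane_fit, reports["positioning"] = positioning.run_positioning(work)

    # 4. patch tracking + alignment solution
    tset, usable2 = fine_align.track_patches(corrected_work, config.tracker)
    work_model, kept = fine_align.solve_alignment(
        tset, corrected_work.tilt_angles, usable2, config.tracker
    )
    model = fine_align.compose_raw_model(
        work_model, table, series.nominal_tilt_axis_deg, len(series), usable2
    )
    reports["fine_alignment"] = {
        "n_trajectories": len(tset.trajectories),
        "n_pruned": int(np.sum(~kept)),
        "mean_residual_px": model.mean_residual_px,
        "converged": model.converged,
    }

    # final usability + corrected angles on the raw series
    final = positioning.apply_pretilt_correction(series, plane_fit)
    final.usable = usable2

    # 5. single-interpolation aligned stack from the raw images
    aligned, aligned_angles, kept_idx = fine_align.apply_alignment(final, model)

    # 6. CTF on the aligned (axis-vertical) stack
    ctf_fit = None
    if config.run_ctf:
        applied = config.applied_defocus_um
        if applied is None:
            applied = float(
                np.median([im.applied_defocus_um for im in final.images]) or 2.0
            )
        if applied <= 0:
            applied = 2.0
        ctf_fit, ctf_reports = ctf.fit_ctf_series(
            aligned, aligned_angles, final.pixel_size_A, applied, config.optics
        )
        # re-index per-image defoci onto the raw series (NaN = not usable)
        full = np.full(len(final), np.nan)
        full[kept_idx] = np.atleast_1d(ctf_fit.defocus_um)
        ctf_fit.defocus_um = full
        reports["ctf"] = {
            "low_confidence_images": [
                int(i) for i, r in enumerate(ctf_reports) if r.get("low_confidence")
            ],
        }

    # 7. reconstruction with automatic thickness
    tomogram = None
    if config.run_reconstruction:
        thickness = reconstruct.estimate_thickness(aligned, aligned_angles)
        tomogram = reconstruct.final_reconstruct(
            aligned,
            aligned_angles,
            x_tilt_deg=final.x_tilt_deg,
            thickness=thickness,
            config=config.recon,
            pixel_size_A=final.pixel_size_A,
        )
        reports["reconstruction"] = {
            "thickness_voxels": int(tomogram.thickness_voxels),
            "x_tilt_deg": float(final.x_tilt_deg),
        }

    metrics = compute_quality_metrics(
        model, usable2, series.nominal_tilt_axis_deg, ctf_fit
    )
    return PipelineResult(
        series=final,
        shift_table=table,
        plane_fit=plane_fit,
        model=model,
        aligned_stack=aligned,
        aligned_angles=aligned_angles,
        aligned_indices=kept_idx,
        ctf_fit=ctf_fit,
        tomogram=tomogram,
        metrics=metrics,
        reports=reports,
        nominal_tilt_angles=nominal_angles,
    )


# ---------------------------------------------------------------------------
# Exporters
# ---------------------------------------------------------------------------

@dataclass
class ExportBundle:
    rawtlt: Path
    tlt: Path
    xf: Path
    tltxf: Path
    newst_com: Path
    tilt_com: Path
    clean_mrc: Path
    defocus: Path | None = None
    star: Path | None = None
    order_csv: Path | None = None

    def paths(self) -> list[Path]:
        return [p for p in (self.rawtlt, self.tlt, self.xf, self.tltxf,
                            self.newst_com, self.tilt_com, self.clean_mrc,
                            self.defocus, self.star, self.order_csv)
                if p is not None]


def export_imod(
    model: fine_align.AlignmentModel,
    series: TiltSeries,
    out_dir: str | os.PathLike,
    basename: str = "series",
    nominal_angles: np.ndarray | None = None,
) -> ExportBundle:
    """Write IMOD-compatible alignment files plus the cleaned stack.

    ``.rawtlt`` carries the nominal angles of every image; ``.tlt``, ``.xf``
    and ``.tltxf`` are restricted to usable images in by-tilt order, with
    2x3 transforms (a11 a12 a21 a22 dx dy) mapping raw to aligned
    coordinates about the image centre.  ``newst.com``/``tilt.com`` are
    runnable command templates referencing the cleaned stack.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    keep = series.usable_indices()
    if keep.size == 0:
        raise ValueError("cannot export a series with no usable images")
    angles = series.tilt_angles

    rawtlt = out / f"{basename}.rawtlt"
    raw_angles = nominal_angles if nominal_angles is not None else angles
    np.savetxt(rawtlt, raw_angles, fmt="%8.2f")
    tlt = out / f"{basename}.tlt"
    np.savetxt(tlt, angles[keep], fmt="%8.2f")

    rows = fine_align.imod_transforms(model, keep)
    xf = out / f"{basename}.xf"
    np.savetxt(xf, rows, fmt="%12.7f %11.7f %11.7f %11.7f %11.3f %11.3f")
    tltxf = out / f"{basename}.tltxf"
    np.savetxt(tltxf, rows, fmt="%12.7f %11.7f %11.7f %11.7f %11.3f %11.3f")

    clean = out / f"{basename}_clean.mrc"
    write_tilt_series(series, clean, include_unusable=False)

    h, w = series.shape
    newst = out / "newst.com"
    newst.write_text(
        "# Aligned-stack generation (IMOD newstack template)\n"
        "$newstack -StandardInput\n"
        f"InputFile {clean.name}\n"
        f"OutputFile {basename}_ali.mrc\n"
        f"TransformFile {xf.name}\n"
        f"SizeToOutputInXandY {w},{h}\n"
        "BinByFactor 1\n"
        "AdjustOrigin\n"
    )
    tiltcom = out / "tilt.com"
    tiltcom.write_text(
        "# Reconstruction (IMOD tilt template)\n"
        "$tilt -StandardInput\n"
        f"InputProjections {basename}_ali.mrc\n"
        f"OutputFile {basename}_rec.mrc\n"
        f"TILTFILE {tlt.name}\n"
        f"IMAGEBINNED 1\n"
        f"THICKNESS {max(int(h // 4), 64)}\n"
        "RADIAL 0.35 0.035\n"
        "FalloffIsTrueSigma 1\n"
        "SCALE 0.0 1.0\n"
        "PERPENDICULAR\n"
        "MODE 2\n"
    )
    return ExportBundle(
        rawtlt=rawtlt, tlt=tlt, xf=xf, tltxf=tltxf,
        newst_com=newst, tilt_com=tiltcom, clean_mrc=clean,
    )


def export_ctfplotter(
    ctf_fit: ctf.CTFFit, series: TiltSeries, path: str | os.PathLike
) -> Path:
    """Write a Ctfplotter-format .defocus file (astigmatism dialect).

    One row per usable image:
    ``view view tilt tilt defocus1_nm defocus2_nm astig_angle_deg``,
    with the format version flag (3) appended to the first row.  Defoci
    are in nanometres, positive = underfocus; defocus1/2 are the two
    astigmatic axes (mean defocus ± magnitude/2).
    """
    path = Path(path)
    keep = series.usable_indices()
    defoci = np.atleast_1d(ctf_fit.defocus_um)
    if defoci.size == 1:
        defoci = np.full(len(series), float(defoci[0]))
    angles = series.tilt_angles
    lines = []
    for n_out, i in enumerate(keep):
        f_nm = defoci[i] * 1000.0
        a_nm = ctf_fit.astigmatism_um * 1000.0
        row = (
            f"{n_out + 1:4d} {n_out + 1:4d} {angles[i]:7.2f} {angles[i]:7.2f} "
            f"{f_nm - a_nm / 2:9.1f} {f_nm + a_nm / 2:9.1f} "
            f"{ctf_fit.astig_angle_deg:7.2f}"
        )
        if n_out == 0:
            row += "  3"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_ctfplotter(path: str | os.PathLike) -> list[dict]:
    """Parse a .defocus file written by :func:`export_ctfplotter`."""
    rows = []
    for n, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        if n == 0 and len(parts) == 8:
            parts = parts[:7]
        v1, v2, t1, t2, d1, d2, ang = parts[:7]
        rows.append(
            dict(
                view=int(v1),
                tilt_deg=float(t1),
                defocus1_nm=float(d1),
                defocus2_nm=float(d2),
                astig_angle_deg=float(ang),
            )
        )
    return rows


def write_star(path: str | os.PathLike, block_name: str, columns: list[str],
               rows: list[list]) -> Path:
    """Write a single-block STAR loop file."""
    path = Path(path)
    out = [f"data_{block_name}", "", "loop_"]
    out += [f"_{c} #{i + 1}" for i, c in enumerate(columns)]
    for row in rows:
        out.append(" ".join(
            f"{v:.6f}" if isinstance(v, float) else str(v) for v in row
        ))
    path.write_text("\n".join(out) + "\n")
    return path


def parse_star(path: str | os.PathLike) -> tuple[str, list[str], list[list[str]]]:
    """Minimal STAR grammar parser for a single loop block."""
    name = None
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            name = line[5:]
        elif line == "loop_":
            in_loop = True
        elif line.startswith("_") and in_loop:
            columns.append(line.split()[0][1:])
        elif in_loop and columns:
            vals = line.split()
            if len(vals) == len(columns):
                rows.append(vals)
    if name is None:
        raise ValueError(f"{path} is not a STAR file")
    return name, columns, rows


def export_relion(
    series: TiltSeries,
    model: fine_align.AlignmentModel,
    ctf_fit: ctf.CTFFit | None,
    out_dir: str | os.PathLike,
    basename: str = "series",
) -> tuple[Path, Path]:
    """Write the RELION-oriented order list (CSV) and tilt-series STAR file.

    The order CSV reproduces the acquisition sequence (one row per image:
    acquisition order, nominal tilt angle).  The STAR file carries one row
    per usable image with its tilt angle, alignment transform and defocus
    (DefocusU/V in Angstrom, astigmatism split RELION-style).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order_csv = out / f"{basename}_order_list.csv"
    by_acq = sorted(range(len(series)), key=lambda i: series.images[i].acquisition_index)
    with open(order_csv, "w") as fh:
        for n_out, i in enumerate(by_acq, start=1):
            fh.write(f"{n_out},{series.images[i].tilt_angle_deg:.2f}\n")

    keep = series.usable_indices()
    defoci = None
    if ctf_fit is not None:
        defoci = np.atleast_1d(ctf_fit.defocus_um)
        if defoci.size == 1:
            defoci = np.full(len(series), float(defoci[0]))
    columns = [
        "rlnTomoName", "rlnTomoTiltMovieIndex", "rlnTomoNominalStageTiltAngle",
        "rlnTomoXShiftAngst", "rlnTomoYShiftAngst", "rlnTomoZRot",
        "rlnDefocusU", "rlnDefocusV", "rlnDefocusAngle",
    ]
    rows = []
    px = series.pixel_size_A
    for i in keep:
        du = dv = dang = 0.0
        if defoci is not None:
            f_A = defoci[i] * 1e4
            a_A = ctf_fit.astigmatism_um * 1e4
            du, dv, dang = f_A + a_A / 2, f_A - a_A / 2, ctf_fit.astig_angle_deg
        rows.append([
            basename,
            int(series.images[i].acquisition_index + 1),
            float(series.images[i].tilt_angle_deg),
            float(model.shift_px[i][0] * px),
            float(model.shift_px[i][1] * px),
            float(model.rotation_deg[i]),
            float(du), float(dv), float(dang),
        ])
    star = write_star(out / f"{basename}.star", basename, columns, rows)
    return order_csv, star


def export_all(
    result: PipelineResult, out_dir: str | os.PathLike, basename: str = "series"
) -> ExportBundle:
    """Write the full export bundle plus a JSON metrics report."""
    out = Path(out_dir)
    bundle = export_imod(result.model, result.series, out, basename,
                         nominal_angles=result.nominal_tilt_angles)
    if result.ctf_fit is not None:
        bundle.defocus = export_ctfplotter(
            result.ctf_fit, result.series, out / f"{basename}.defocus"
        )
    bundle.order_csv, bundle.star = export_relion(
        result.series, result.model, result.ctf_fit, out, basename
    )
    report = {
        "metrics": result.metrics.to_dict(),
        "reports": _jsonable(result.reports),
    }
    (out / f"{basename}_report.json").write_text(json.dumps(report, indent=2))
    if result.tomogram is not None:
        import mrcfile

        with mrcfile.new(out / f"{basename}_rec.mrc", overwrite=True) as mrc:
            mrc.set_data(result.tomogram.volume.astype(np.float32))
            mrc.voxel_size = result.tomogram.voxel_size_A
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
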
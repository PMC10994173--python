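# Methods

This note documents the models, conventions, parameter choices and known
limits of the package. It states no measured numbers beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Coordinate and angle conventions

Images are `[row, col]` arrays with x = column, y = row, origin top-left,
0-based; shifts are in pixels at the working binning. Angles are degrees.
The tilt-axis angle is measured counter-clockwise from the image Y axis:
rotating an image by −axis brings the axis vertical. Stage tilt is a
rotation about the (axis-vertical) image Y axis; a point `(X, Y, Z)`
relative to the volume centre projects to `x = X cos α + Z sin α, y = Y`.
Volumes are `[z, y, x]`. The defocus of a strip at signed in-plane
distance `d` px from the axis is `f0 + sign · d · px · tan α` (µm, with
px in Å and the factor 10⁻⁴); the sign convention is configurable because
it depends on the stage/detector handedness, which metadata rarely states.

## Synthetic data generator

The generator emulates tilted parallel-beam imaging of a slab specimen —
a FIB lamella or a thin ice layer:

* **Phantom**: spheres, shells and rods with random radii placed uniformly
  through a slab; features crossing a slab face are truncated there, as
  milling truncates real structures, so the per-plane material density is
  uniform with sharp slab boundaries. The density is band-limited
  (Gaussian, σ = 0.8 voxels by default) because voxelised hard edges carry
  spatial frequencies no instrument records — and, under a ±60° missing
  wedge, frequencies no reconstruction can restore.
* **Projection**: line integrals by the same bilinear-weight projector the
  reconstruction uses, at `α + pre_tilt_y` after a static `pre_tilt_x`
  rotation; then per-image in-plane rotation (`tilt_axis + δθ_i`), scale
  and shift. A `fov_px` crop lets the specimen extend beyond the field of
  view, as real specimens do — without it, high-tilt images have empty
  margins.
* **Intensity model**: weak-phase bright-field contrast. The structural
  contrast amplitude is capped (default std 0.25) so `1 + contrast`
  remains positive — clipping would be a nonlinearity that measurably
  shifts Thon-ring positions. A white "ice" texture (default contrast
  0.08) stands in for the amorphous background that carries Thon rings at
  all frequencies. Transmission falls with tilt as
  `exp(−τ(1/cos α − 1))`, τ = thickness over the inelastic mean free path
  (default 0.4, appropriate for a 100–300 nm slab at 300 kV). Shot noise
  is Poisson at `dose · px²` electrons per pixel; the CTF (defaults:
  300 kV, Cs 2.7 mm, amplitude contrast 0.07) is applied in column strips
  so the defocus gradient perpendicular to the tilt axis is present.
* **Defaults as study conditions**: 41 images at 3° steps over ±60°
  (dose-symmetric order, group 2), 3 e⁻/Å² per image, applied defoci of a
  few µm, tilt axis near 85°, pre-tilts up to ±10°, per-image shifts up to
  tens of px and rotations ≲1°.

What the generator does **not** model: multislice/solvent scattering,
detector DQE, dose-dependent damage, beam-induced doming or any non-rigid
deformation. Passing tests therefore demonstrate correct geometry and
estimator behaviour under realistic dose and contrast, not robustness to
deformation or detector artefacts.

## Stack cleaner

Histogram over the series-global robust intensity range (1st–99th
percentile), 256 bins, Pearson correlation between image pairs (histogram
intersection available behind the config). Matrix mean and σ are computed
over the off-diagonal upper triangle. An image is usable iff it correlates
above `mean − 1σ` with more than 4 other images. The threshold sits
*below* the mean: usable images' histogram correlations saturate near 1
with a long left tail, so σ always exceeds their distance to 1 and any
threshold above the mean would reject every image of a perfectly clean
stack. With σ = 0 (identical histograms) the threshold is `mean − ε` so
perfect stacks pass.

## Pair alignment

The stack is reordered by tilt and rotated axis-vertical. Before
correlating a pair, the farther-tilted image is cosine-stretched
(`cos α_i / cos α_j` along x, using angles corrected by the lamella
pre-tilt when metadata provides one); without this the foreshortening
biases the peak by several px. The measured shift recursion
`s_j = (m_x + s_{i,x}) · cos α_j / cos α_i` is exact for in-plane
features; depth (Z) structure adds a `Z·sin α` term that coarse alignment
cannot separate — the fine-alignment solver absorbs it into the marker
positions. Peak quality is a z-score, `(peak − background mean) /
background std` with the background ≥ 8 px from the peak; the default
robust-peak threshold 5.5 is the 99th percentile of this score over 100
seeded pairs of independent noise images (`calibrate_null_threshold`
reproduces it). Pairs below threshold mark the farther image non-usable
and the chain continues with i→i+2, i+3 (accumulating across the skipped
image, up to 3 consecutive skips).

## Tomogram positioning

Dense optical flow (scikit-image iterative Lucas–Kanade, radius 16 at
2× binning) between consecutive usable images within |tilt| ≤ 45°, where
residual motions stay inside the local solver's capture range. The
predictable motion — plane foreshortening plus, on the second pass, the
first plane estimate's Z-relief — is warped away before the solve and
restored analytically. Patch averages (8×8 grid) are weighted by the
squared image gradient, because flat regions carry no flow information
and would dilute the mean toward zero. Trajectories integrate the coarse
flow field sampled at the moving track position (bilinear between patch
centres); patch 3D positions come from linear least squares on the
projection equations; the plane fit `z = ax + by + c` iterates 3×MAD
outlier rejection (≤10 passes). Sign conventions: `y_tilt = −atan(a)` is
*added* to every nominal tilt angle; `x_tilt = −atan(b)` is applied at
reconstruction; both are covered by synthetic sign tests. When FIB
pre-tilt metadata exists it seeds the plane fit and is refined, not
replaced.

## Patch tracking and alignment determination

Constants: 16 patches on a 4×4 grid, each 30% of the image dimensions;
measured−theoretical shift deviations above 2% of max(width, height)
relocate the patch; relocation picks the most contrasted unused of 200
subpatches (20×10 grid; the central 2/3 of a placed patch's surface marks
its subpatches used); an image needing relocation of >75% of patches is
dropped. Patch windows clamp inside the image (bookkeeping keeps the true
window origin) and the pair is cosine-stretched like the coarse stage.

The solver minimises `p(k,i) = s·R(θ_i)·P(α_i)·X_k + t_i` with tilt
angles fixed: (i) bounded Brent search over the global axis residual
(nominal ± 10°, 5 inner iterations per evaluation); (ii) blockwise
alternation — markers by linear least squares, per-image rotation+shift
by Procrustes, global scale by projection — to relative residual change
< 10⁻⁴ or 50 iterations; (iii) repeated pruning of trajectories with mean
residual > mean + 3σ. The reported tilt-axis angle is the mean of the
final per-image rotations (outlier-free, unlike the Brent stage value).
Gauge: the marker centroid is shifted so the anchor (0°) image's shift is
zero; consequently per-image shifts are determined up to the projection
of a global 3D marker translation, and recovery tests compare shifts
after removing that 3-parameter gauge by least squares. The final aligned
stack is produced by one single resampling per raw image (composition of
pair shifts and the solved rotation/scale/shift). The noise-free tracking
residual floor is a few tenths of a pixel (interpolation-limited), rising
toward ~0.5 px at 256-px image sizes.

## CTF determination

2D fit (horizontal image): tiled 128-px periodogram (stride 32, Hanning);
the radial background — a spline through the rotational average's CTF
minima — is interpolated back onto the 2D grid and removed; defocus,
astigmatism magnitude and angle maximise the normalised 2D
cross-correlation of the squared CTF model against the residual inside
the fit window (0.6 of the first zero to 90% of Nyquist; below that the
specimen's structure factor dominates). The search is initialised at the
acquisition defocus (grid ± 1.5 µm, 0.02 µm step, then Nelder–Mead).

Tilted images: 9 strips parallel to the axis, each sampled by rectangular
patches — 256 px tall along the axis (constant defocus, fine frequency
sampling) and 64 px wide across it (negligible within-patch gradient) —
tiled at stride 64. Curves are equiphase averages (iso-phase ellipses of
the series-constant astigmatism) with the background spline anchored at
the model's zero crossings plus the high-frequency tail. A frequency
rescaling factor u superposing one curve's zeros on a reference maps to a
defocus ratio u²; the correlation window is u-independent and starts at
1.2× the first zero (above the structure factor); a best match at the
search boundary is treated as no match. Each image's defocus comes from
its on-axis strip (bundled with its two neighbours for SNR) rescaled
against the *horizontal image's* on-axis curve — the on-axis region shows
the same specimen area unforeshortened at every tilt. Off-axis strips
feed the consistency check that the defocus-vs-offset slope matches
`px·tan α` (tested only when the expected slope exceeds the rescaling
resolution); failures flag the image low-confidence. The automatic
resampling decision compares the sample count of the first CTF
oscillation with its value at the reference sampling (1.5 Å; the
reference is a configurable constant — see the known-issues note below)
and rounds the ratio to the nearest half-integer, ties up, clamped ≥ 1.

## Reconstruction

The projector builds, per tilt angle, a sparse matrix of bilinear
line-integral weights (step 1 voxel); forward and back projection are
exact transposes, so the adjoint test holds to machine precision and SIRT
(`x ← x + λ C Aᵀ R (b − Ax)`, R/C reciprocal row/column sums) behaves as
analysed. Relaxation defaults to 1.9 — the classical near-optimal value
for normalised SIRT, reaching a given residual in roughly half the
iterations of λ = 1 — with 30 iterations. A static specimen X tilt is
handled by reconstructing in the beam-aligned frame and levelling the
volume with a rotation about X afterwards, which keeps the projector pair
matched; at the ≤10° angles involved this is equivalent to tilting the
projection geometry. Early stop with a warning if the residual grows 3
consecutive iterations.

Thickness: quick SIRT (15 iterations) at ≤256 px with Z = 0.75× the
image width; the contrast profile is the per-plane std of the band-passed
plane (difference of Gaussians, σ = 1–4) with the outermost two planes
clamped (edge spikes). Plain std is dominated by smooth missing-wedge
smears, and a pure high-pass is dominated by white shot noise, which is
why the top octave is excluded. A top-hat-convolved-Gaussian plateau
model validates the shape; the width is read at 40% of the fitted
contrast amplitude, a level calibrated once on an independent seed set of
synthetic slabs spanning 20–60% of Z (the half-maximum is biased inward
by the wedge's asymmetric tails). A profile whose amplitude is below half
its base (back-projected noise produces only a shallow dome) triggers the
Z/3 fallback with a warning. The final reconstruction runs on the
4×-binned aligned stack with Z = thickness + 10%.

## Pipeline, metrics and export

Stage order: clean → pair align → position → track/solve → single-resample
aligned stack → CTF → thickness + SIRT. Deleted slices are the union of
cleaner, pair-alignment and tracking removals. `.rawtlt` keeps nominal
angles; `.tlt/.xf/.tltxf` cover usable images only in by-tilt order with
2×3 transforms (input→aligned about the image centre, IMOD convention);
`newst.com`/`tilt.com` are templates in IMOD 4.11 syntax (they require an
IMOD installation to run). The Ctfplotter `.defocus` writer uses the
astigmatism dialect (two defoci in nm + angle, version flag 3 on the
first row). The STAR export targets RELION-4-style tomography columns
(defoci split into DefocusU/V in Å); the exact dialect of other tools may
differ, so the column names live in one place in `pipeline_export.py`.

## Numerical choices and degenerate inputs

* Sub-pixel correlation peaks: 3×3 parabolic refinement (alignment), or
  windowed centroid for the broad peaks of smooth movie frames.
* Frame grouping: group size `max(1, round(1/dose))`, remainder frames
  folded into the last fraction.
* Duplicate tilt angles sort by acquisition index; an all-unusable export
  raises; a series shorter than the cleaner's support count passes with a
  warning; a flat contrast profile falls back to Z/3.
* `bin_image`: block mean for integer factors (exact), Fourier crop
  otherwise; mean intensity preserved.

## Known limitations

* Motion correction is a deliberately simple rigid per-fraction model
  (global + 3×3 patch refinement, no dose weighting, no polynomial
  trajectories); it is functional rather than a high-fidelity port of
  production motion-correction algorithms. EER decoding is out of scope.
* The reference sampling for the CTF resampling rule is stated
  inconsistently in the literature this follows (a 1.5 nm reference
  pixel would place the first CTF zero beyond Nyquist, making the rule
  undefined); the package uses 1.5 Å, which reproduces the intended
  behaviour (R = 3 at 0.5 Å sampling), and exposes it as a constant.
* Per-image astigmatism, phase-plate phase shifts, local (non-rigid)
  alignment, tilt-angle refinement, GPU kernels and CTF correction of the
  reconstruction are not implemented.
* The solver keeps tilt angles fixed (as designed); errors in nominal
  angles propagate into marker depths.
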
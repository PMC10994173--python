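# tiltlive

On-the-fly processing for cryo-electron tomography tilt series: automatic
stack cleaning, fiducial-free alignment, tomogram positioning, tilted-image
CTF estimation, SIRT reconstruction with automatic thickness determination,
and export to IMOD / Ctfplotter / RELION formats.

`tiltlive` is aimed at people who collect tilt series and want immediate,
unattended feedback on whether each series is worth keeping: it turns a raw
stack (or dose-fractionated movies) into an aligned stack, per-image CTF
parameters, a quick SIRT tomogram and a handful of quality metrics —
alignment accuracy, number of deleted images, tilt-axis correction,
defocus, CTF confidence range and astigmatism — without any manual steps
or fiducial markers.  A forward simulator with fully known ground truth is
part of the package, so every stage is covered by parameter-recovery tests.

## The processing model

A tilt series records projections `p_i` of a specimen at stage tilts
`α_i` about an in-plane axis.  The pipeline estimates, per image, the
in-plane rotation, shift and (global) scale that map an ideal
parallel-beam projection onto the recorded image:

```
p_i(k) = s · R(θ_i) · P(α_i) · X_k + t_i
```

where `X_k` are 3D positions of tracked features, `P(α) = [[cos α, 0,
sin α], [0, 1, 0]]` is the parallel projection after rotating the tilt
axis vertical, `R(θ_i)` the in-plane rotation (initialised from the global
tilt-axis angle), `t_i` the per-image shift and `s` a global scale.  The
stages are:

1. **Stack cleaner** — gray-value histogram correlations between all image
   pairs; an image stays usable only if it correlates above a threshold
   (one σ below the matrix mean) with more than four other images.  Grid
   bars and blocked exposures fail this vote; fiducials or content shared
   by every image do not affect it.
2. **Pair alignment** — cosine-stretched cross-correlation between
   neighbouring tilts, walking outward from the 0° image, with a per-pair
   automatic bandpass that maximises the correlation-peak z-score.  Images
   with no robust peak are dropped and the chain skips across them.
3. **Tomogram positioning** — dense optical-flow feature tracks are
   triangulated through the projection model; a robust plane fit yields the
   specimen's X/Y pre-tilt.  The Y correction is applied to the tilt
   angles, the X correction is used at reconstruction.
4. **Patch tracking + alignment solve** — 16 patches (30% of the image
   size) tracked by cross-correlation at their theoretically expected
   positions, `dx = (x − w/2)(cos α_j / cos α_i − 1)`; lost patches are
   relocated to the most contrasted of 200 subpatches.  The projection
   model is then solved by a Brent search over the tilt-axis angle,
   blockwise alternation for markers and per-image parameters, and
   repeated 3σ trajectory pruning.
5. **CTF determination** — 2D defocus/astigmatism fit on the horizontal
   image (normalised cross-correlation of the squared CTF model against
   the background-subtracted Thon pattern); tilted images are divided into
   strips parallel to the tilt axis, equiphase-averaged with the series
   astigmatism, and their defoci recovered from the frequency rescaling
   that superposes their CTF zeros on the on-axis reference.
6. **Reconstruction** — matched-pair SIRT (`x ← x + λ C Aᵀ R (b − Ax)`)
   with automatic thickness from the plateau of the per-plane contrast
   profile of a quick binned reconstruction.

## Worked example

```python
import numpy as np
from tiltlive import (PhantomSpec, make_phantom, project_tilt_series,
                      apply_ctf_and_noise, occlude_grid_bar, run_pipeline,
                      export_all)
from tiltlive.synthetic_data import default_truth

angles = np.arange(-60, 61, 6.0)
vol = make_phantom(PhantomSpec(volume_shape=(256, 256, 64),
                               slab_thickness_voxels=24,
                               n_features=250, seed=9))
truth = default_truth(len(angles), seed=9, max_shift_px=12,
                      tilt_axis_deg=85.0, defocus_um=3.0, pre_tilt_y_deg=5.0)
series = project_tilt_series(vol, angles, truth, pixel_size_A=4.0)
series = apply_ctf_and_noise(series, truth, dose_e_per_A2=3.0, seed=10)
series = occlude_grid_bar(series, [0, 1, 19, 20], 0.5, seed=2)  # grid bars

result = run_pipeline(series)
print(result.metrics.to_dict())
export_all(result, "out/", basename="demo")
```

prints (numbers from an actual run):

```
{'alignment_accuracy_px': 0.372, 'n_deleted_slices': 4,
 'tilt_axis_correction_deg': 0.537, 'defocus_um': 2.985,
 'ctf_confidence_range_A': 8.192, 'astigmatism_um': 0.009}
```

meaning: the solved projection model fits the tracked trajectories to
0.37 px on average; the four grid-bar images were removed; the refined
tilt-axis angle sits 0.54° from the nominal 85°; the estimated defocus
(2.99 µm) matches the simulated 3 µm; Thon rings correlate with the model
out to 8.2 Å; and the fitted astigmatism is negligible, as simulated.
The tomogram's Z extent comes from the automatic thickness estimate
(24 unbinned voxels here, matching the simulated slab).
`export_all` writes `demo.rawtlt/.tlt/.xf/.tltxf`, `newst.com/tilt.com`,
`demo_clean.mrc` (usable images only), `demo.defocus` (Ctfplotter format),
`demo.star` + `demo_order_list.csv` (RELION) and the tomogram.

There is also a small CLI:

```bash
tiltlive synth --preset lamella --seed 1 --out data/
tiltlive run --in data/lamella_1.mrc --meta data/lamella_1.json --out results/
tiltlive clean --in data/lamella_1.mrc --meta data/lamella_1.json --report clean.json
```

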
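"""Shared synthetic fixtures.

Everything is generated at test time from seeded simulators; the expensive
objects (forward-projected tilt series, a full pipeline run) are session
scoped so every test file shares one copy.
"""

import numpy as np
import pytest

from tiltlive.synthetic_data import (
    GroundTruth,
    PhantomSpec,
    apply_ctf_and_noise,
    default_truth,
    make_phantom,
    occlude_grid_bar,
    project_tilt_series,
)


@pytest.fixture(scope="session")
def phantom_small():
    """128^3-ish slab phantom shared by cheap tests."""
    return make_phantom(
        PhantomSpec(volume_shape=(128, 128, 48), slab_thickness_voxels=20,
                    n_features=120, seed=11)
    )


@pytest.fixture(scope="session")
def clean_series_small(phantom_small):
    """41-image noisy 128^2 series, no injected defects beyond noise."""
    angles = np.arange(-60, 61, 3.0)
    truth = default_truth(len(angles), seed=4, max_shift_px=6,
                          tilt_axis_deg=85.0, defocus_um=3.0)
    series = project_tilt_series(phantom_small, angles, truth, pixel_size_A=2.0)
    return apply_ctf_and_noise(series, truth, dose_e_per_A2=3.0, seed=5,
                               n_strips=4), truth


@pytest.fixture(scope="session")
def occluded_series_small(clean_series_small):
    """Same series with grid bars over the four highest-tilt images."""
    series, truth = clean_series_small
    n = len(series)
    return occlude_grid_bar(series, [0, 1, n - 2, n - 1], 0.5, seed=6)


@pytest.fixture(scope="session")
def tracking_case():
    """256^2, 21-tilt noise-free case with known geometry for alignment tests."""
    angles = np.arange(-60, 61, 6.0)
    vol = make_phantom(
        PhantomSpec(volume_shape=(256, 256, 64), slab_thickness_voxels=24,
                    n_features=250, seed=21)
    )
    truth = default_truth(len(angles), seed=22, max_shift_px=15,
                          max_rot_deg=1.0, tilt_axis_deg=85.0, defocus_um=3.0)
    series = project_tilt_series(vol, angles, truth, pixel_size_A=2.0)
    return series, truth, angles


@pytest.fixture(scope="session")
def pipeline_case():
    """Noisy 256^2 series with occlusions + its ground truth (pipeline tests)."""
    angles = np.arange(-60, 61, 6.0)
    n = len(angles)
    vol = make_phantom(
        PhantomSpec(volume_shape=(256, 256, 64), slab_thickness_voxels=24,
                    n_features=250, seed=9)
    )
    truth = default_truth(n, seed=9, max_shift_px=12, tilt_axis_deg=85.0,
                          defocus_um=3.0, pre_tilt_y_deg=5.0)
    series = project_tilt_series(vol, angles, truth, pixel_size_A=4.0)
    noisy = apply_ctf_and_noise(series, truth, dose_e_per_A2=3.0, seed=10,
                                n_strips=4)
    return occlude_grid_bar(noisy, [0, 1, n - 2, n - 1], 0.5, seed=2), truth


@pytest.fixture(scope="session")
def pipeline_result(pipeline_case):
    """One full pipeline run (all stages) shared by pipeline/export tests."""
    from tiltlive.pipeline_export import PipelineConfig, run_pipeline
    from tiltlive.reconstruct import ReconstructionConfig

    series, truth = pipeline_case
    config = PipelineConfig(
        recon=ReconstructionConfig(n_iterations=15, binning=2),
    )
    return run_pipeline(series, config), truth
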
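import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tiltlive.ctf import (
    OpticsParams,
    auto_resample_factor,
    ctf_model,
    electron_wavelength_A,
    equiphase_average,
    first_zero_frequency,
    fit_ctf_2d,
    points_to_first_zero,
    rotational_average,
    round_to_half,
    strip_spectra,
    subtract_background_spline,
)
from tiltlive.synthetic_data import (
    GroundTruth,
    PhantomSpec,
    apply_ctf_and_noise,
    make_phantom,
    project_tilt_series,
)

OPTICS = OpticsParams()


@pytest.fixture(scope="module")
def ctf_image():
    """512^2 image of a wide slab specimen with a 2.5 um CTF imprint."""
    vol = make_phantom(PhantomSpec(volume_shape=(768, 512, 48),
                                   slab_thickness_voxels=24,
                                   n_features=500, seed=31))
    truth = GroundTruth.zero(1, defocus_um=np.array([2.5]))
    s = project_tilt_series(vol, [0.0], truth, pixel_size_A=4.0, fov_px=512)
    noisy = apply_ctf_and_noise(s, truth, dose_e_per_A2=3.0, seed=32)
    return noisy.images[0].pixels.astype(float)


class TestCtfModel:
    def test_zero_frequency_equals_minus_amplitude_contrast(self):
        val = ctf_model(2.0, 0.0, 0.0, OPTICS, np.array(0.0))
        assert val == pytest.approx(-OPTICS.amplitude_contrast, abs=1e-12)

    def test_no_astigmatism_is_azimuth_independent(self):
        k = np.full(8, 0.05)
        az = np.linspace(0, 2 * np.pi, 8)
        vals = ctf_model(2.0, 0.0, 0.0, OPTICS, k, az)
        assert np.ptp(vals) < 1e-12

    def test_astigmatic_defocus_modulates_with_cos_two_theta(self):
        k = np.full(4, 0.05)
        az = np.deg2rad([45.0, 135.0, 225.0, 315.0])
        vals = ctf_model(2.0, 0.3, 45.0, OPTICS, k, az)
        assert vals[0] == pytest.approx(vals[2], abs=1e-12)  # period pi
        assert vals[0] != pytest.approx(vals[1], abs=1e-6)

    def test_first_zero_matches_root_finder_oracle(self):
        from scipy.optimize import brentq

        lam = electron_wavelength_A(300.0)
        cs = 2.7e7
        A = OPTICS.amplitude_contrast
        ph0 = np.arctan2(A, np.sqrt(1 - A ** 2))

        def phase(k):
            return np.pi * lam * 2.0e4 * k ** 2 - 0.5 * np.pi * cs * lam ** 3 * k ** 4 + ph0

        oracle = brentq(lambda k: phase(k) - np.pi, 1e-6, 0.2)
        assert first_zero_frequency(2.0, OPTICS) == pytest.approx(oracle, rel=1e-9)
        # the model amplitude really crosses zero there
        assert abs(ctf_model(2.0, 0.0, 0.0, OPTICS, np.array(oracle))) < 1e-9


class TestEquiphaseAverage:
    def test_zero_astigmatism_equals_rotational_average(self):
        rng = np.random.default_rng(0)
        spec = rng.uniform(size=(128, 128))
        k1, a = equiphase_average(spec, 0.0, 0.0, 2.0)
        k2, b = rotational_average(spec, 2.0)
        np.testing.assert_allclose(a, b, rtol=1e-6)
        np.testing.assert_allclose(k1, k2)

    def test_equiphase_sharpens_astigmatic_zeros(self):
        # analytic astigmatic |CTF|^2 spectrum: the circular average blurs
        # the first zero, the matched elliptical average keeps it deep
        px = 3.0
        ky = np.fft.fftfreq(256, d=px)[:, None]
        kx = np.fft.fftfreq(256, d=px)[None, :]
        k = np.hypot(kx, ky)
        az = np.arctan2(ky, kx)
        spec = ctf_model(2.5, 0.4, 30.0, OPTICS, k, az) ** 2
        k1, circ = rotational_average(spec, px)
        _, equi = equiphase_average(spec, 0.4, 30.0, px, defocus_um=2.5)
        z1 = first_zero_frequency(2.5, OPTICS)
        sel = (k1 > 0.8 * z1) & (k1 < 1.2 * z1)
        assert equi[sel].min() < circ[sel].min()

    def test_noise_spectrum_gives_flat_curve(self):
        rng = np.random.default_rng(1)
        spec = rng.uniform(0.9, 1.1, size=(128, 128))
        k, curve = equiphase_average(spec, 0.0, 0.0, 2.0)
        sig = subtract_background_spline(k, curve)
        assert np.abs(sig[5:]).max() < 0.3


class TestResampling:
    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_round_to_half_is_a_half_integer(self, x):
        r = round_to_half(x)
        assert (2 * r) == int(2 * r)
        assert abs(r - x) <= 0.25 + 1e-9

    def test_tie_rounds_up(self):
        assert round_to_half(1.25) == 1.5
        assert round_to_half(2.75) == 3.0

    def test_reference_sampling_gives_unity(self):
        from tiltlive.ctf import REFERENCE_PIXEL_SIZE_A

        dec = auto_resample_factor(REFERENCE_PIXEL_SIZE_A)
        assert dec.n_exp == dec.n_ref
        assert dec.r_factor == 1.0

    def test_half_sampling_doubles_the_factor(self):
        # direct-ratio oracle: n_exp scales with pixel size, so half the
        # reference pixel size halves n_exp and doubles R
        from tiltlive.ctf import REFERENCE_PIXEL_SIZE_A

        dec = auto_resample_factor(REFERENCE_PIXEL_SIZE_A / 2, n_bins=512)
        oracle = round_to_half(dec.n_ref / dec.n_exp)
        assert dec.r_factor == oracle == pytest.approx(2.0, abs=0.5)

    def test_ratio_rounds_to_nearest_half(self):
        # a 1.3 ratio rounds to 1.5 (2.6 half-units -> 3)
        assert round_to_half(1.3) == 1.5

    def test_factor_clamped_to_at_least_one(self):
        dec = auto_resample_factor(4.0)  # coarser than the reference
        assert dec.r_factor == 1.0


class TestFit2D:
    def test_defocus_and_null_astigmatism_recovered(self, ctf_image):
        fit = fit_ctf_2d(ctf_image, applied_defocus_um=2.7, pixel_size_A=4.0)
        assert float(fit.defocus_um[0]) == pytest.approx(2.5, abs=0.05)
        assert fit.astigmatism_um <= 0.05
        assert fit.confidence_range_A > 2 * 4.0

    def test_astigmatism_recovered(self):
        vol = make_phantom(PhantomSpec(volume_shape=(768, 512, 48),
                                       slab_thickness_voxels=24,
                                       n_features=500, seed=33))
        truth = GroundTruth.zero(1, defocus_um=np.array([2.5]),
                                 astigmatism_um=0.3, astig_angle_deg=45.0)
        s = project_tilt_series(vol, [0.0], truth, pixel_size_A=4.0, fov_px=512)
        noisy = apply_ctf_and_noise(s, truth, dose_e_per_A2=3.0, seed=34)
        fit = fit_ctf_2d(noisy.images[0].pixels, 2.7, pixel_size_A=4.0)
        assert float(fit.defocus_um[0]) == pytest.approx(2.5, abs=0.06)
        assert fit.astigmatism_um == pytest.approx(0.3, abs=0.08)
        assert fit.astig_angle_deg == pytest.approx(45.0, abs=8.0)

    def test_pure_noise_is_flagged_low_confidence(self):
        rng = np.random.default_rng(2)
        img = rng.poisson(40.0, size=(512, 512)).astype(float)
        fit = fit_ctf_2d(img, 2.5, pixel_size_A=4.0)
        assert fit.low_confidence


class TestStripSpectra:
    def test_untilted_strips_share_their_first_zero(self, ctf_image):
        strips = strip_spectra(ctf_image, 4.0)
        from tiltlive.ctf import CTFFit, strip_curves

        central = CTFFit(defocus_um=np.array([2.5]), astigmatism_um=0.0,
                         astig_angle_deg=0.0, confidence_range_A=10.0)
        k, curves = strip_curves(strips, central)
        z1 = first_zero_frequency(2.5, OPTICS)
        zero_pos = []
        from scipy.ndimage import gaussian_filter1d

        for c in (curves[1], curves[4], curves[7]):
            sel = np.flatnonzero((k > 0.7 * z1) & (k < 1.3 * z1))
            cs = gaussian_filter1d(c, 2.0)
            j = sel[np.argmin(cs[sel])]
            # parabolic sub-bin refinement of the minimum
            den = cs[j - 1] - 2 * cs[j] + cs[j + 1]
            dj = 0.5 * (cs[j - 1] - cs[j + 1]) / den if abs(den) > 1e-12 else 0.0
            zero_pos.append(k[j] + dj * (k[1] - k[0]))
        assert np.ptp(zero_pos) / np.mean(zero_pos) < 0.05

    def test_offsets_are_signed_and_span_the_width(self, ctf_image):
        strips = strip_spectra(ctf_image, 4.0)
        offs = np.array([s.row_offset_px for s in strips])
        assert offs.min() < -100 and offs.max() > 100
        assert np.all(np.diff(offs) >= 0)

    def test_narrow_image_reduces_rows_with_warning(self):
        with pytest.warns(UserWarning):
            strips = strip_spectra(np.zeros((64, 24)), 4.0, n_rows=9)
        assert len(strips) <= 6
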
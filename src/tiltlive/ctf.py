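"""CTF determination: 2D fitting on the horizontal image, strip-based defocus
with equiphase averaging for tilted images, spline background and automatic
spectrum resampling.

On a tilted specimen the defocus varies linearly across the image in the
direction perpendicular to the tilt axis, which blurs Thon rings in a
whole-image power spectrum.  Defocus and astigmatism are therefore fitted
in 2D only on the image where the specimen is horizontal; every other image
is divided into strips parallel to the (vertical) tilt axis, each strip's
patch-averaged power spectrum is collapsed to 1D by averaging along the
iso-phase ellipses set by the series astigmatism, and per-strip defoci
follow from the frequency rescaling that superposes each strip's CTF zeros
onto the on-axis strip's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq, minimize
from scipy.signal import argrelmin


@dataclass
class OpticsParams:
    """Microscope optical constants (common 300 kV cryo-TEM defaults)."""

    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07


@dataclass
class CTFFit:
    defocus_um: np.ndarray  # per image, positive = underfocus
    astigmatism_um: float  # series-constant magnitude
    astig_angle_deg: float  # series-constant angle
    confidence_range_A: float
    optics: OpticsParams = field(default_factory=OpticsParams)
    low_confidence: bool = False


@dataclass
class ResamplingDecision:
    n_exp: int
    n_ref: int
    r_factor: float


@dataclass
class StripSpectrum:
    row_offset_px: float  # signed strip-centre offset from the tilt axis
    spectrum_2d: np.ndarray  # patch-averaged 2D power spectrum (fft order)
    n_patches_averaged: int
    pixel_size_A: float


def electron_wavelength_A(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


def ctf_model(
    defocus_um: float,
    astig_um: float,
    astig_angle_deg: float,
    optics: OpticsParams,
    spatial_frequency: np.ndarray,
    azimuth: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Phase-contrast CTF amplitude at spatial frequency k (1/A) and azimuth.

    chi(k) = pi*lambda*df(theta)*k^2 - (pi/2)*Cs*lambda^3*k^4, with
    df(theta) = f + a*cos(2(theta - theta0)); the returned amplitude is
    -(sqrt(1 - A^2) sin chi + A cos chi), so CTF(0) = -A (the amplitude
    contrast term) and underfocus (positive df) gives positive contrast at
    low frequency.
    """
    k = np.asarray(spatial_frequency, dtype=float)
    lam = electron_wavelength_A(optics.voltage_kV)
    df_A = (defocus_um + astig_um * np.cos(2 * (np.asarray(azimuth) - np.deg2rad(astig_angle_deg)))) * 1e4
    cs_A = optics.cs_mm * 1e7
    chi = np.pi * lam * df_A * k**2 - 0.5 * np.pi * cs_A * lam**3 * k**4
    A = optics.amplitude_contrast
    return -(np.sqrt(1 - A**2) * np.sin(chi) + A * np.cos(chi))


def first_zero_frequency(defocus_um: float, optics: OpticsParams) -> float:
    """Frequency (1/A) of the first CTF zero, by root finding on the phase."""
    lam = electron_wavelength_A(optics.voltage_kV)
    cs_A = optics.cs_mm * 1e7
    A = optics.amplitude_contrast
    phase0 = np.arctan2(A, np.sqrt(1 - A**2))

    def chi_total(k):
        return (np.pi * lam * defocus_um * 1e4 * k**2
                - 0.5 * np.pi * cs_A * lam**3 * k**4 + phase0)

    # first zero of sin(chi + phase0): chi_total = pi
    k_hi = 1.0
    while chi_total(k_hi) < np.pi and k_hi < 10:
        k_hi *= 1.5
    return float(brentq(lambda k: chi_total(k) - np.pi, 1e-6, k_hi))


# ---------------------------------------------------------------------------
# Power spectra
# ---------------------------------------------------------------------------

def periodogram_average(
    image: np.ndarray, tile: int = 256, stride: int | None = None
) -> np.ndarray:
    """Tiled periodogram-averaged 2D power spectrum (fft order, DC at [0,0])."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    tile = min(tile, h, w)
    stride = stride or tile // 2
    win = np.hanning(tile)[:, None] * np.hanning(tile)[None, :]
    acc = np.zeros((tile, tile))
    n = 0
    for y0 in range(0, h - tile + 1, stride):
        for x0 in range(0, w - tile + 1, stride):
            patch = image[y0 : y0 + tile, x0 : x0 + tile]
            patch = (patch - patch.mean()) * win
            acc += np.abs(np.fft.fft2(patch)) ** 2
            n += 1
    return acc / max(n, 1)


def _freq_grids(shape, pixel_size_A: float):
    if np.isscalar(shape):
        shape = (int(shape), int(shape))
    ky = np.fft.fftfreq(shape[0], d=pixel_size_A)[:, None]
    kx = np.fft.fftfreq(shape[1], d=pixel_size_A)[None, :]
    return np.hypot(kx, ky), np.arctan2(ky, kx)


def equiphase_average(
    spectrum_2d: np.ndarray,
    astig_um: float,
    astig_angle_deg: float,
    pixel_size_A: float,
    defocus_um: float = 2.0,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average a 2D spectrum along iso-phase ellipses; returns (k_bins, curve).

    The phase of the astigmatic CTF at azimuth theta scales as
    df(theta) * k^2, so pixels are binned by the effective frequency
    k * sqrt(df(theta)/f).  Zero astigmatism degenerates to circles (the
    plain rotational average).
    """
    k, az = _freq_grids(spectrum_2d.shape, pixel_size_A)
    ratio = 1.0 + (astig_um / max(defocus_um, 1e-6)) * np.cos(
        2 * (az - np.deg2rad(astig_angle_deg))
    )
    k_eff = k * np.sqrt(np.clip(ratio, 1e-6, None))
    n_bins = n_bins or max(spectrum_2d.shape) // 2
    k_nyq = 0.5 / pixel_size_A
    edges = np.linspace(0, k_nyq, n_bins + 1)
    idx = np.clip(np.digitize(k_eff.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=spectrum_2d.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    curve = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, curve


def rotational_average(
    spectrum_2d: np.ndarray, pixel_size_A: float, n_bins: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Plain circular average of a 2D power spectrum."""
    k, _ = _freq_grids(spectrum_2d.shape, pixel_size_A)
    n_bins = n_bins or max(spectrum_2d.shape) // 2
    k_nyq = 0.5 / pixel_size_A
    edges = np.linspace(0, k_nyq, n_bins + 1)
    idx = np.clip(np.digitize(k.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=spectrum_2d.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    curve = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return 0.5 * (edges[:-1] + edges[1:]), curve


def model_zero_frequencies(
    defocus_um: float, optics: OpticsParams, k_max: float, n_max: int = 40
) -> np.ndarray:
    """Frequencies of successive CTF zeros up to k_max."""
    lam = electron_wavelength_A(optics.voltage_kV)
    cs_A = optics.cs_mm * 1e7
    A = optics.amplitude_contrast
    ph0 = np.arctan2(A, np.sqrt(1 - A**2))

    def chi_total(k):
        return (np.pi * lam * defocus_um * 1e4 * k**2
                - 0.5 * np.pi * cs_A * lam**3 * k**4 + ph0)

    zeros = []
    for nz in range(1, n_max + 1):
        try:
            zeros.append(brentq(lambda kk: chi_total(kk) - nz * np.pi, 1e-6, k_max))
        except ValueError:
            break
    return np.asarray(zeros)


def subtract_background_model(
    k: np.ndarray, curve: np.ndarray, defocus_um: float, optics: OpticsParams
) -> np.ndarray:
    """Remove the background via a spline through the CTF zero crossings.

    Knots sit at the model's zero frequencies for the (approximately)
    known defocus plus the high-frequency tail, where the true CTF signal
    vanishes, so the spline traces the background rather than the rings.
    """
    from scipy.interpolate import CubicSpline

    zeros = model_zero_frequencies(defocus_um, optics, 0.95 * k[-1])
    c = gaussian_filter1d(np.asarray(curve, float), 1.0)
    knot_k = [k[1]]
    knot_v = [c[1]]
    for z in zeros:
        i = int(np.argmin(np.abs(k - z)))
        if i <= 1 or i >= len(k) - 1:
            continue
        knot_k.append(k[i])
        knot_v.append(float(c[max(i - 1, 0) : i + 2].min()))
    for i in range(int(0.92 * len(k)), len(k), 2):
        knot_k.append(k[i])
        knot_v.append(c[i])
    knot_k, order = np.unique(knot_k, return_index=True)
    knot_v = np.asarray(knot_v)[order]
    if len(knot_k) < 4:
        return curve - c
    spl = CubicSpline(knot_k, knot_v)
    return curve - spl(k)


def subtract_background_spline(k: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Remove the smooth background through the CTF zero-crossing minima.

    A cubic smoothing spline is fit through the local minima of the curve
    plus the top 10% frequency tail, then subtracted.
    """
    c = gaussian_filter1d(np.asarray(curve, float), 1.0)
    minima = list(argrelmin(c, order=2)[0])
    tail = list(range(int(0.9 * len(c)), len(c)))
    knots = sorted(set(minima + tail))
    knots = [i for i in knots if i > 0]
    if len(knots) < 4:
        return curve - c  # no oscillation structure: flatten
    spl = UnivariateSpline(k[knots], c[knots], k=3,
                           s=len(knots) * np.var(c[knots]) * 0.01)
    return curve - spl(k)


# ---------------------------------------------------------------------------
# 2D fit on the horizontal image
# ---------------------------------------------------------------------------

def _score_defocus_1d(k, signal, defocus_um, optics, kmin, kmax):
    sel = (k >= kmin) & (k <= kmax)
    if sel.sum() < 8:
        return -1.0
    model = ctf_model(defocus_um, 0.0, 0.0, optics, k[sel]) ** 2
    s = signal[sel]
    if s.std() < 1e-15 or model.std() < 1e-15:
        return -1.0
    return float(np.corrcoef(s, model - model.mean())[0, 1])


def _fit_window(pixel_size_A: float, defocus_um: float, optics: OpticsParams):
    """Frequency window for scoring.

    Below ~0.6 of the first CTF zero the spectrum is dominated by the
    specimen's own structure factor, not Thon rings, so scoring starts
    there (equivalent to the 30-50 A lower bound practitioners use) and
    runs to 90% of Nyquist.
    """
    k_nyq = 0.5 / pixel_size_A
    k1 = first_zero_frequency(defocus_um, optics)
    kmin = max(0.6 * k1, 1.0 / 60.0)
    kmin = min(kmin, 0.5 * k_nyq)
    return kmin, 0.9 * k_nyq


def fit_ctf_2d(
    horizontal_image: np.ndarray,
    applied_defocus_um: float,
    optics: OpticsParams | None = None,
    pixel_size_A: float = 1.0,
    tile: int = 128,
    defocus_span_um: float = 1.5,
    max_astig_um: float = 0.8,
) -> CTFFit:
    """Fit defocus and astigmatism on the horizontal-specimen image.

    The radially smooth background (spline through the rotational average's
    CTF minima) is removed from the tiled periodogram spectrum; defocus,
    astigmatism magnitude and angle then maximise the normalised 2D
    cross-correlation between the squared CTF model and the residual Thon
    pattern inside the fit window.  The defocus search is initialised at
    the value applied at acquisition.
    """
    optics = optics or OpticsParams()
    img = np.asarray(horizontal_image, dtype=float)
    tile = min(tile, *img.shape)
    spec = periodogram_average(img, tile=tile, stride=max(tile // 4, 16))
    kmin, kmax = _fit_window(pixel_size_A, max(applied_defocus_um, 0.3), optics)
    k1d, curve = rotational_average(spec, pixel_size_A)
    sig1 = subtract_background_spline(k1d, curve)
    bg2 = np.interp(_freq_grids(tile, pixel_size_A)[0].ravel(), k1d, curve - sig1)
    k2, az2 = _freq_grids(tile, pixel_size_A)
    resid = spec - bg2.reshape(spec.shape)
    mask = (k2 >= kmin) & (k2 <= kmax)
    rm = resid[mask]
    rm = rm - rm.mean()
    rm_norm = np.sqrt(np.dot(rm, rm))

    def score(f, a, ang):
        if f <= 0.1 or not 0 <= a <= max_astig_um:
            return -1.0
        m = ctf_model(f, a, ang, optics, k2, az2) ** 2
        mm = m[mask]
        mm = mm - mm.mean()
        denom = rm_norm * np.sqrt(np.dot(mm, mm))
        if denom < 1e-12:
            return -1.0
        return float(np.dot(rm, mm) / denom)

    f_grid = np.arange(max(0.3, applied_defocus_um - defocus_span_um),
                       applied_defocus_um + defocus_span_um + 1e-9, 0.02)
    scores = [score(f, 0.0, 0.0) for f in f_grid]
    j = int(np.argmax(scores))
    best = (scores[j], float(f_grid[j]), 0.0, 0.0)
    for a in (0.05, 0.1, 0.2, 0.3, 0.45, 0.6):
        if a > max_astig_um:
            break
        for ang in range(0, 180, 15):
            s = score(best[1], a, float(ang))
            if s > best[0]:
                best = (s, best[1], a, float(ang))
    res = minimize(
        lambda p: -score(p[0], abs(p[1]), p[2]),
        [best[1], best[2], best[3]],
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 300},
    )
    if -res.fun >= best[0]:
        f, a, ang = float(res.x[0]), abs(float(res.x[1])), float(res.x[2]) % 180.0
        final_score = float(-res.fun)
    else:
        final_score, f, a, ang = best
    conf = confidence_range(k1d, sig1, f, optics, kmin)
    return CTFFit(
        defocus_um=np.atleast_1d(f),
        astigmatism_um=a,
        astig_angle_deg=ang,
        confidence_range_A=conf,
        optics=optics,
        low_confidence=bool(final_score < 0.1),
    )


def confidence_range(
    k: np.ndarray, signal: np.ndarray, defocus_um: float, optics: OpticsParams,
    kmin: float, window: int = 9, threshold: float = 0.3,
) -> float:
    """Highest resolution (A) where windowed model/spectrum correlation > 0.3."""
    model = ctf_model(defocus_um, 0.0, 0.0, optics, k) ** 2
    best_k = kmin
    for i0 in range(0, len(k) - window):
        sel = slice(i0, i0 + window)
        if k[i0] < kmin:
            continue
        s, m = signal[sel], model[sel]
        if s.std() < 1e-15 or m.std() < 1e-15:
            continue
        if np.corrcoef(s, m)[0, 1] > threshold:
            best_k = k[i0 + window - 1]
    return float(1.0 / best_k) if best_k > 0 else float("inf")


# ---------------------------------------------------------------------------
# Automatic resampling
# ---------------------------------------------------------------------------

REFERENCE_PIXEL_SIZE_A = 1.5  # sampling at which N_ref is defined
REFERENCE_DEFOCUS_UM = 2.0


def round_to_half(x: float) -> float:
    """Round to the nearest half-integer; ties round up."""
    return np.floor(2 * x + 0.5) / 2.0


def points_to_first_zero(
    pixel_size_A: float, defocus_um: float, optics: OpticsParams, n_bins: int
) -> int:
    """Spectrum samples between k = 0 and the first CTF zero."""
    k1 = first_zero_frequency(defocus_um, optics)
    k_nyq = 0.5 / pixel_size_A
    return max(1, int(round(k1 / k_nyq * n_bins)))


def auto_resample_factor(
    pixel_size_A: float,
    defocus_um: float = REFERENCE_DEFOCUS_UM,
    optics: OpticsParams | None = None,
    n_bins: int = 128,
) -> ResamplingDecision:
    """Resampling factor R = round_to_half(N_ref / N_exp), clamped to >= 1.

    N_exp counts the spectrum samples describing the first CTF oscillation
    at the native sampling; N_ref is the same count at the reference
    sampling (REFERENCE_PIXEL_SIZE_A).  Fine pixel sizes under-sample the
    first oscillation (small N_exp) and get R > 1.
    """
    optics = optics or OpticsParams()
    n_exp = points_to_first_zero(pixel_size_A, defocus_um, optics, n_bins)
    n_ref = points_to_first_zero(REFERENCE_PIXEL_SIZE_A, defocus_um, optics, n_bins)
    r = max(1.0, round_to_half(n_ref / n_exp))
    return ResamplingDecision(n_exp=n_exp, n_ref=n_ref, r_factor=r)


# ---------------------------------------------------------------------------
# Tilted images: strips parallel to the tilt axis
# ---------------------------------------------------------------------------

def strip_spectra(
    tilted_image: np.ndarray,
    pixel_size_A: float,
    n_rows: int = 9,
    patch_size: int = 256,
    patch_width: int = 64,
    tilt_axis_vertical: bool = True,
) -> list[StripSpectrum]:
    """Per-strip patch-averaged power spectra of an axis-vertical image.

    The image is divided into ``n_rows`` column bands parallel to the
    vertical tilt axis.  Rectangular patches — ``patch_size`` tall along
    the axis (constant defocus, fine frequency sampling) but only
    ``patch_width`` wide across it (so the defocus gradient inside one
    patch stays negligible) — are centred on each band's midline, tiled
    along it and periodogram-averaged.
    """
    if not tilt_axis_vertical:
        raise ValueError("rotate the image axis-vertical first")
    img = np.asarray(tilted_image, dtype=float)
    h, w = img.shape
    ph = min(patch_size, h)
    pw = min(patch_width, w)
    if w / n_rows < 4:
        import warnings

        n_rows = max(1, w // 4)
        warnings.warn(f"strips narrower than 4 px; reduced to {n_rows} rows")
    cx = (w - 1) / 2.0
    centers = (np.arange(n_rows) + 0.5) * w / n_rows
    win = np.hanning(ph)[:, None] * np.hanning(pw)[None, :]
    out = []
    stride = max(ph // 4, 16)
    for cxs in centers:
        x0 = int(np.clip(round(cxs - pw / 2), 0, w - pw))
        acc = np.zeros((ph, pw))
        n = 0
        for y0 in range(0, h - ph + 1, stride):
            tilein = img[y0 : y0 + ph, x0 : x0 + pw]
            tilein = (tilein - tilein.mean()) * win
            acc += np.abs(np.fft.fft2(tilein)) ** 2
            n += 1
        out.append(
            StripSpectrum(
                # offset of the actually-sampled (clamped) window centre
                row_offset_px=float(x0 + pw / 2.0 - 0.5 - cx),
                spectrum_2d=acc / max(n, 1),
                n_patches_averaged=n,
                pixel_size_A=pixel_size_A,
            )
        )
    return out


def _rescale_correlation(k, ref_sig, cur_sig, u, kmin, kmax):
    """Correlation of the strip curve with its frequency axis stretched by u
    against the on-axis reference curve.

    ``np.interp(k, k*u, cur)`` evaluates the curve at k/u, i.e. features at
    frequency k0 move to k0*u; a strip at higher defocus (zeros compressed
    toward low k) therefore matches the reference at u > 1 and its defocus
    is ``f_ref * u**2``.
    """
    resampled = np.interp(k, k * u, cur_sig, left=0.0, right=0.0)
    # upper bound must stay inside the resampled curve's support for every
    # candidate u, or zero-padding rewards spurious compression
    sel = (k > max(k[3], kmin)) & (k < kmax)
    a, b = ref_sig[sel], resampled[sel]
    if a.std() < 1e-15 or b.std() < 1e-15:
        return -1.0
    return float(np.corrcoef(a, b)[0, 1])


RESCALE_KMIN_FACTOR = 1.2  # of the first CTF zero: above the structure factor


def _best_rescale(k, ref, cur, kmin, kmax, u_grid):
    """Best frequency-rescaling factor of cur onto ref; (u, score) or None."""
    scores = np.array([_rescale_correlation(k, ref, cur, u, kmin, kmax) for u in u_grid])
    j = int(np.argmax(scores))
    if j == 0 or j == len(u_grid) - 1:
        return None  # best match at the search boundary: no believable peak
    denom = scores[j - 1] - 2 * scores[j] + scores[j + 1]
    du = 0.5 * (scores[j - 1] - scores[j + 1]) / denom if abs(denom) > 1e-12 else 0.0
    u = u_grid[j] + np.clip(du, -1, 1) * (u_grid[1] - u_grid[0])
    return float(u), float(scores[j])


def strip_curves(
    strips: list[StripSpectrum], central_fit: CTFFit
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Equiphase-averaged, background-subtracted 1D curves of each strip."""
    px = strips[0].pixel_size_A
    f_c = float(np.atleast_1d(central_fit.defocus_um)[0])
    curves = []
    k = None
    for s in strips:
        k, c = equiphase_average(
            s.spectrum_2d, central_fit.astigmatism_um, central_fit.astig_angle_deg,
            px, defocus_um=f_c,
        )
        curves.append(subtract_background_model(k, c, f_c, central_fit.optics))
    return k, curves


def bundled_axis_curve(
    strips: list[StripSpectrum], central_fit: CTFFit, bundle: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """On-axis 1D curve from the axis strip averaged with its neighbours.

    The defocus difference between adjacent strips is far below the
    rescaling resolution, so bundling trades a negligible zero blur for a
    threefold SNR gain.
    """
    px = strips[0].pixel_size_A
    f_c = float(np.atleast_1d(central_fit.defocus_um)[0])
    offsets = np.array([s.row_offset_px for s in strips])
    i_axis = int(np.argmin(np.abs(offsets)))
    lo = max(0, i_axis - bundle)
    hi = min(len(strips), i_axis + bundle + 1)
    spec = np.mean([strips[i].spectrum_2d for i in range(lo, hi)], axis=0)
    k, c = equiphase_average(
        spec, central_fit.astigmatism_um, central_fit.astig_angle_deg, px,
        defocus_um=f_c,
    )
    return k, subtract_background_model(k, c, f_c, central_fit.optics)


def fit_tilted_defocus(
    strips: list[StripSpectrum],
    central_fit: CTFFit,
    tilt_angle_deg: float,
    reference_curve: np.ndarray | None = None,
    slope_tolerance: float = 0.5,
) -> tuple[float, dict]:
    """Per-image defocus from the strip spectra of one tilted image.

    Every curve is rescaled along the frequency axis to superpose its CTF
    zeros on a reference curve; a rescaling factor u maps to a defocus
    ``f_ref * u**2``.  The image defocus comes from the on-axis strip
    (matched against ``reference_curve`` — the horizontal image's on-axis
    curve — when given, since the on-axis region shows the same specimen
    area unforeshortened at every tilt); the off-axis strips provide the
    consistency check that the fitted defocus-versus-offset slope agrees
    with the geometric expectation pixel_size * tan(tilt), else the result
    is flagged low-confidence.
    """
    if len(strips) < 3:
        raise ValueError("need >= 3 strips")
    px = strips[0].pixel_size_A
    f_c = float(np.atleast_1d(central_fit.defocus_um)[0])
    optics = central_fit.optics
    offsets = np.array([s.row_offset_px for s in strips])
    i_axis = int(np.argmin(np.abs(offsets)))
    k, curves = strip_curves(strips, central_fit)

    u_grid = np.linspace(0.85, 1.18, 133)
    kmin = RESCALE_KMIN_FACTOR * first_zero_frequency(f_c, optics)
    kmax = 0.95 * k[-1] * u_grid[0]

    # image defocus: bundled on-axis curve against the horizontal-image
    # reference (same specimen area, unforeshortened at every tilt)
    if reference_curve is not None:
        _, axis_cur = bundled_axis_curve(strips, central_fit)
        hit = _best_rescale(k, reference_curve, axis_cur, kmin, kmax, u_grid)
    else:
        hit = (1.0, 1.0)
    if hit is None:
        image_defocus = f_c
        image_ok = False
    else:
        image_defocus = f_c * hit[0] ** 2
        image_ok = True

    # per-strip defoci against this image's own axis strip (slope check)
    strip_defoci = np.full(len(strips), np.nan)
    weights = np.zeros(len(strips))
    for i, cur in enumerate(curves):
        got = _best_rescale(k, curves[i_axis], cur, kmin, kmax, u_grid)
        if got is None:
            strip_defoci[i] = image_defocus
            continue
        strip_defoci[i] = image_defocus * got[0] ** 2
        weights[i] = max(got[1], 0.0)

    expected_slope = px * np.tan(np.deg2rad(tilt_angle_deg)) * 1e-4
    ok = weights > 0.2
    report: dict = {"strip_offsets_px": offsets.tolist(),
                    "strip_defoci_um": strip_defoci.tolist(),
                    "weights": weights.tolist()}
    if ok.sum() >= 3:
        Wm = np.diag(weights[ok])
        A = np.column_stack([offsets[ok], np.ones(ok.sum())])
        sol = np.linalg.lstsq(Wm @ A, Wm @ strip_defoci[ok], rcond=None)[0]
        slope = float(sol[0])
    else:
        slope = 0.0
    report["slope_um_per_px"] = slope
    report["expected_slope_um_per_px"] = float(expected_slope)
    low_conf = not image_ok
    # the geometric slope is only testable once the gradient spans the
    # strips by more than the rescaling resolution (moderate-to-high tilt)
    if abs(expected_slope) > 1e-4:
        if abs(slope - expected_slope) > slope_tolerance * abs(expected_slope) + 5e-6:
            low_conf = True
    report["low_confidence"] = low_conf
    return float(image_defocus), report


def fit_ctf_series(
    stack: np.ndarray,
    tilt_angles_deg: np.ndarray,
    pixel_size_A: float,
    applied_defocus_um: float,
    optics: OpticsParams | None = None,
    n_rows: int = 9,
    patch_size: int = 256,
    patch_width: int = 64,
    central_tile: int = 128,
) -> tuple[CTFFit, list[dict]]:
    """CTF parameters for a whole aligned (axis-vertical) stack.

    2D defocus + astigmatism on the image nearest zero tilt; strip-based
    defocus for every other image with the astigmatism held series-constant.
    """
    optics = optics or OpticsParams()
    angles = np.asarray(tilt_angles_deg, dtype=float)
    i0 = int(np.argmin(np.abs(angles)))
    central = fit_ctf_2d(stack[i0], applied_defocus_um, optics, pixel_size_A,
                         tile=central_tile)
    ref_strips = strip_spectra(stack[i0], pixel_size_A, n_rows=n_rows,
                               patch_size=patch_size, patch_width=patch_width)
    _, reference = bundled_axis_curve(ref_strips, central)
    defoci = np.empty(len(angles))
    reports = []
    for i in range(len(angles)):
        if i == i0:
            defoci[i] = float(np.atleast_1d(central.defocus_um)[0])
            reports.append({"central": True})
            continue
        strips = strip_spectra(stack[i], pixel_size_A, n_rows=n_rows,
                               patch_size=patch_size, patch_width=patch_width)
        d, rep = fit_tilted_defocus(strips, central, angles[i],
                                    reference_curve=reference)
        defoci[i] = d
        reports.append(rep)
    return (
        CTFFit(
            defocus_um=defoci,
            astigmatism_um=central.astigmatism_um,
            astig_angle_deg=central.astig_angle_deg,
            confidence_range_A=central.confidence_range_A,
            optics=optics,
            low_confidence=central.low_confidence,
        ),
        reports,
    )
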
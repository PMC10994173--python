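"""Remove obviously unusable tilt images via histogram correlation.

Grid bars sweeping into the field of view, ice contamination or a closed
shutter change an image's gray-value histogram drastically, while a usable
image's histogram resembles the rest of the series regardless of tilt or
of high-contrast features like fiducials (which appear on every image and
therefore shift every histogram equally).  Each image gets a usability
vote: it stays usable only if its histogram correlates above a threshold —
one sigma below the mean of the whole correlation matrix — with more than
`support_count` other images.  The threshold sits below the mean because
histogram correlations of usable images saturate near 1 with a long left
tail: sigma always exceeds their distance to 1, so a threshold above the
mean would reject every image of a perfectly clean series.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .core_io import TiltSeries


@dataclass
class CleanerConfig:
    n_bins: int = 256
    sigma_multiplier: float = -1.0
    support_count: int = 4
    method: str = "pearson"  # or "intersection"

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.support_count < 1:
            raise ValueError("support_count must be >= 1")


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    mean: float
    sigma: float


def series_intensity_range(series: TiltSeries) -> tuple[float, float]:
    """Robust (1st, 99th percentile) intensity range over the whole series."""
    samples = np.concatenate([im.pixels.ravel()[::7] for im in series.images])
    lo, hi = np.percentile(samples, [1, 99])
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def gray_histogram(
    pixels: np.ndarray, n_bins: int = 256, value_range: tuple[float, float] | None = None
) -> np.ndarray:
    """L1-normalised gray-value histogram over a robust intensity range."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pixels = np.asarray(pixels, dtype=float)
    if value_range is None:
        lo, hi = np.percentile(pixels, [1, 99])
        if hi <= lo:
            hi = lo + 1.0
        value_range = (float(lo), float(hi))
    hist, _ = np.histogram(pixels, bins=n_bins, range=value_range)
    total = hist.sum()
    return hist / total if total > 0 else hist.astype(float)


def _correlate(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "intersection":
        return float(np.minimum(a, b).sum())
    sa, sb = a.std(), b.std()
    if sa < 1e-15 or sb < 1e-15:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def histogram_correlation_matrix(
    series: TiltSeries, config: CleanerConfig | None = None
) -> CorrelationMatrix:
    """Pairwise histogram correlations; mean/sigma over the off-diagonal upper triangle."""
    config = config or CleanerConfig()
    if len(series) < 2:
        raise ValueError("need at least 2 images")
    vrange = series_intensity_range(series)
    hists = [gray_histogram(im.pixels, config.n_bins, vrange) for im in series.images]
    n = len(hists)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _correlate(hists[i], hists[j], config.method)
    upper = values[np.triu_indices(n, k=1)]
    return CorrelationMatrix(values=values, mean=float(upper.mean()), sigma=float(upper.std()))


def flag_non_usable(
    matrix: CorrelationMatrix, config: CleanerConfig | None = None
) -> np.ndarray:
    """Usability flags: image i is usable iff its correlation exceeds
    mean + sigma_multiplier*sigma (default: one sigma *below* the mean)
    with more than `support_count` other images.

    Degenerate sigma = 0 (identical histograms) uses threshold mean - eps so
    a perfect stack stays fully usable.
    """
    config = config or CleanerConfig()
    values = matrix.values
    n = values.shape[0]
    if n <= config.support_count + 1:
        warnings.warn("series shorter than support_count + 1; keeping all images")
        return np.ones(n, dtype=bool)
    if matrix.sigma < 1e-12:
        threshold = matrix.mean - 1e-9
    else:
        threshold = matrix.mean + config.sigma_multiplier * matrix.sigma
    usable = np.zeros(n, dtype=bool)
    for i in range(n):
        support = int(np.sum(values[i] > threshold)) - (1 if values[i, i] > threshold else 0)
        usable[i] = support > config.support_count
    return usable


def clean_series(
    series: TiltSeries, config: CleanerConfig | None = None
) -> tuple[TiltSeries, dict]:
    """Run the stack cleaner; returns (series with updated flags, report)."""
    config = config or CleanerConfig()
    matrix = histogram_correlation_matrix(series, config)
    usable = flag_non_usable(matrix, config)
    out = series.copy(usable=series.usable & usable)
    threshold = (
        matrix.mean - 1e-9
        if matrix.sigma < 1e-12
        else matrix.mean + config.sigma_multiplier * matrix.sigma
    )
    support = [
        int(np.sum(matrix.values[i] > threshold))
        - (1 if matrix.values[i, i] > threshold else 0)
        for i in range(len(series))
    ]
    report = {
        "matrix_mean": matrix.mean,
        "matrix_sigma": matrix.sigma,
        "support_counts": support,
        "flagged": [int(i) for i in np.flatnonzero(~usable)],
    }
    return out, report
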
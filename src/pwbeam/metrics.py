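"""Image-quality metrics for beamformed ultrasound images.

Local, ROI-based metrics on the envelope: contrast (dB), contrast-to-noise
ratio (CNR), generalized CNR (gCNR, one minus the overlap of the two
ROIs' 256-bin envelope histograms), speckle signal-to-noise ratio
(SNR = mean/std, ~1.91 for fully developed Rayleigh speckle), and axial /
lateral full width at half maximum of point targets.

Global image-to-image metrics between a test and a reference envelope
image on the same grid: mean absolute and mean squared error on linear and
log-compressed scales, peak signal-to-noise ratio, and normalized cross
correlation, all restricted to pixels within a dB window (default -40 to
0 dB) of the reference maximum, after fitting a single scalar gain to the
test image that minimizes the achievable squared error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BeamformedImage, PixelGrid, ROISpec, ValidationError, bind_roi

__all__ = [
    "ROIStats",
    "MetricReport",
    "roi_stats",
    "contrast",
    "cnr",
    "gcnr",
    "snr",
    "fwhm",
    "global_compare",
]

GCNR_BINS = 256


@dataclass
class ROIStats:
    """Mean, standard deviation, and normalized histogram of an ROI."""

    mean: float
    std: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    n_pixels: int


@dataclass
class MetricReport:
    """Named metric values, split into local and global families."""

    local: dict = field(default_factory=dict)
    global_: dict = field(default_factory=dict)
    mask_pixel_count: int = 0
    normalization_gain: float = 1.0


def _envelope_values(env: BeamformedImage, roi: ROISpec) -> np.ndarray:
    if env.stage != "envelope":
        raise ValidationError(f"metrics require an envelope image, got {env.stage}")
    return env.values_in(roi)


def roi_stats(
    env: BeamformedImage, roi: ROISpec, bins: int = GCNR_BINS,
    value_range: tuple[float, float] | None = None,
) -> ROIStats:
    vals = _envelope_values(env, roi)
    hist, edges = np.histogram(vals, bins=bins, range=value_range)
    total = hist.sum()
    return ROIStats(
        mean=float(vals.mean()),
        std=float(vals.std()),
        histogram=hist / total if total else hist.astype(float),
        bin_edges=edges,
        n_pixels=vals.size,
    )


def contrast(
    env: BeamformedImage, target: ROISpec, background: ROISpec
) -> float:
    """Contrast in dB: 20*log10(mu_target / mu_background)."""
    mu1 = _envelope_values(env, target).mean()
    mu2 = _envelope_values(env, background).mean()
    if mu2 == 0:
        raise ValidationError("background mean is zero; contrast undefined")
    return float(20.0 * np.log10(mu1 / mu2))


def cnr(env: BeamformedImage, roi1: ROISpec, roi2: ROISpec) -> float:
    """Contrast-to-noise ratio: (mu1 - mu2) / sqrt(sigma1^2 + sigma2^2)."""
    v1 = _envelope_values(env, roi1)
    v2 = _envelope_values(env, roi2)
    denom = math.sqrt(v1.std() ** 2 + v2.std() ** 2)
    if denom == 0:
        raise ValidationError("both ROIs have zero variance; CNR undefined")
    return float((v1.mean() - v2.mean()) / denom)


def gcnr(
    env: BeamformedImage, roi1: ROISpec, roi2: ROISpec, bins: int = GCNR_BINS
) -> float:
    """Generalized CNR: 1 minus the overlap of the two ROI histograms.

    Histograms use ``bins`` equal-width bins spanning the combined
    min-max of both ROIs, so the result is bounded in [0, 1] and invariant
    to strictly monotone intensity transforms applied to both ROIs.
    Identical distributions give 0; fully separable ones give 1.
    """
    v1 = _envelope_values(env, roi1)
    v2 = _envelope_values(env, roi2)
    lo = min(v1.min(), v2.min())
    hi = max(v1.max(), v2.max())
    if lo == hi:
        warnings.warn(
            "all envelope values identical across both ROIs; gCNR "
            "degenerates to 0", RuntimeWarning,
        )
        return 0.0
    f1, _ = np.histogram(v1, bins=bins, range=(lo, hi))
    f2, _ = np.histogram(v2, bins=bins, range=(lo, hi))
    overlap = np.minimum(f1 / v1.size, f2 / v2.size).sum()
    return float(1.0 - overlap)


def snr(env: BeamformedImage, roi: ROISpec) -> float:
    """Speckle SNR: mean/std of the envelope in the ROI.

    Fully developed speckle has a Rayleigh envelope, for which
    mean/std = sqrt(pi / (4 - pi)) ~ 1.91; departures from that value
    flag loss of speckle texture.
    """
    vals = _envelope_values(env, roi)
    sd = vals.std()
    if sd == 0:
        raise ValidationError("zero variance in ROI; SNR undefined")
    return float(vals.mean() / sd)


def _half_max_width(coords: np.ndarray, profile: np.ndarray, peak_idx: int) -> float:
    """Distance between the half-max crossings nearest the peak.

    Crossings are located by linear interpolation between samples; a side
    whose profile never falls below half maximum raises with the side
    named.
    """
    half = profile[peak_idx] / 2.0

    def cross(indices, side: str) -> float:
        prev = peak_idx
        for i in indices:
            if profile[i] < half:
                # linear interpolation between samples i and prev
                f = (half - profile[i]) / (profile[prev] - profile[i])
                return coords[i] + f * (coords[prev] - coords[i])
            prev = i
        raise ValidationError(
            f"profile does not fall below half maximum on the {side} side "
            "within the ROI"
        )

    left = cross(range(peak_idx - 1, -1, -1), "left/shallow")
    right = cross(range(peak_idx + 1, len(profile)), "right/deep")
    return right - left


def fwhm(
    env: BeamformedImage, grid: PixelGrid | None = None,
    point_roi: ROISpec | None = None,
) -> tuple[float, float]:
    """Lateral and axial full width at half maximum of a point target, mm.

    The envelope maximum inside ``point_roi`` is located (no sub-sample
    refinement: the grid spacing bounds the accuracy), the lateral and
    axial profiles through the peak are extracted, and each width is the
    distance between the two half-max crossings nearest the peak, found by
    linear interpolation.
    """
    grid = env.grid if grid is None else grid
    if env.stage != "envelope":
        raise ValidationError(f"fwhm requires an envelope image, got {env.stage}")
    if point_roi is not None:
        mask = bind_roi(point_roi, grid)
    else:
        mask = np.ones(grid.shape, dtype=bool)
    masked = np.where(mask, env.pixels, -np.inf)
    iz, ix = np.unravel_index(np.argmax(masked), grid.shape)

    rows = np.nonzero(mask[iz, :])[0]
    cols = np.nonzero(mask[:, ix])[0]
    lateral = _half_max_width(
        grid.x_m[rows], env.pixels[iz, rows], int(np.searchsorted(rows, ix))
    )
    axial = _half_max_width(
        grid.z_m[cols], env.pixels[cols, ix], int(np.searchsorted(cols, iz))
    )
    return float(lateral * 1e3), float(axial * 1e3)


def global_compare(
    test_env: BeamformedImage,
    ref_env: BeamformedImage,
    dynamic_range_db: float = 40.0,
) -> MetricReport:
    """Image-to-image comparison of a test envelope against a reference.

    Procedure: (i) pixels are selected where the log-compressed reference
    is within ``dynamic_range_db`` of its maximum (the mask depends on the
    reference only, and indexes both images); (ii) the test image is
    scaled by the least-squares gain sum(x*y)/sum(x*x) over the mask, the
    gain that minimizes the achievable squared error — equivalently an
    additive offset on the log scale; (iii) mean absolute (l1) and mean
    squared (l2) errors are computed on the masked linear envelopes and,
    as l1_log / l2_log, on the masked log images; (iv) PSNR is
    20*log10(dynamic_range / rms log error); (v) rho is the Pearson
    correlation of the masked log images.

    An identical pair yields zero losses, rho = 1, and infinite PSNR
    (reported as ``inf``).
    """
    if test_env.stage != "envelope" or ref_env.stage != "envelope":
        raise ValidationError("global_compare requires envelope images")
    if test_env.grid.shape != ref_env.grid.shape:
        raise ValidationError("test and reference images must share a grid")

    ref = np.asarray(ref_env.pixels, dtype=float)
    test = np.asarray(test_env.pixels, dtype=float)
    ref_peak = ref.max()
    if ref_peak <= 0:
        raise ValidationError("reference image is identically zero")

    with np.errstate(divide="ignore"):
        ref_log = 20.0 * np.log10(ref / ref_peak)
    mask = ref_log >= -dynamic_range_db
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("empty comparison mask")

    x = test[mask]
    y = ref[mask]
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValidationError("test image is zero over the comparison mask")
    gain = float(np.dot(x, y) / sxx)
    x = gain * x

    # both images on a dB scale relative to the reference maximum
    with np.errstate(divide="ignore"):
        x_log = 20.0 * np.log10(x / ref_peak)
        y_log = ref_log[mask]

    xn = x / ref_peak
    yn = y / ref_peak
    l1 = float(np.mean(np.abs(xn - yn)))
    l2 = float(np.mean((xn - yn) ** 2))
    l1_log = float(np.mean(np.abs(x_log - y_log)))
    mse_log = float(np.mean((x_log - y_log) ** 2))

    if mse_log == 0:
        psnr = float("inf")
    else:
        psnr = float(20.0 * np.log10(dynamic_range_db / math.sqrt(mse_log)))

    y_var = float(np.var(y_log))
    if y_var == 0:
        raise ValidationError("reference has zero variance over the mask")
    x_var = float(np.var(x_log))
    if x_var == 0:
        rho = 0.0
    else:
        rho = float(
            np.mean((x_log - x_log.mean()) * (y_log - y_log.mean()))
            / math.sqrt(x_var * y_var)
        )

    return MetricReport(
        global_={
            "l1": l1,
            "l2": l2,
            "l1_log": l1_log,
            "l2_log": mse_log,
            "psnr_db": psnr,
            "rho": rho,
        },
        mask_pixel_count=n,
        normalization_gain=gain,
    )
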
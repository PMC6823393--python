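"""Surface-wave metrics: period, wavelength, velocity, oscillation mode.

Standing-wave period comes from the median over pixels of the first peak
of each pixel's temporal autocorrelation.  Traveling-wave wavelength and
velocity come from a line kymograph: edge detection along the space axis,
a linear Hough transform, and the slope/spacing of the detected stripe
lines.  In-vesicle oscillation modes (pulsing, pole-to-pole, circling) are
classified from the phase profile of the dominant temporal frequency
around the perimeter kymograph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, signal, stats
from skimage.filters import threshold_otsu
from skimage.transform import hough_line, hough_line_peaks

from .io import ImageStack
from .kymo import Kymograph

__all__ = [
    "WaveEstimate",
    "OscillationMode",
    "standing_wave_period",
    "line_kymograph",
    "preblur",
    "estimate_traveling_wave",
    "classify_oscillation_mode",
]


@dataclass
class WaveEstimate:
    wavelength: float           # µm
    velocity: float             # µm/s
    period: float               # s; wavelength/velocity for traveling waves
    n_lines: int
    flags: list[str] = field(default_factory=list)


@dataclass
class OscillationMode:
    label: Literal["pulsing", "pole_to_pole", "circling", "undetermined"]
    dominant_period: float      # s (NaN when undetermined without a peak)
    phase_profile: np.ndarray   # radians per perimeter column


def standing_wave_period(stack: ImageStack | np.ndarray,
                         frame_interval: float | None = None,
                         min_prominence: float = 0.1) -> float:
    """Oscillation period from per-pixel temporal autocorrelation.

    For every pixel, the mean-subtracted, lag-0-normalized autocorrelation
    over time is computed; the first local maximum at positive lag with
    prominence >= ``min_prominence`` qualifies.  The result is the median
    of the qualifying lags (midpoint for even counts) times the frame
    interval, in seconds.
    """
    if isinstance(stack, ImageStack):
        frames = stack.channel(0)
        dt = stack.frame_interval
    else:
        frames = np.asarray(stack, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for a bare array")
        dt = frame_interval
    n_t = frames.shape[0]
    flat = frames.reshape(n_t, -1).astype(float)
    flat = flat - flat.mean(axis=0)
    var = (flat ** 2).sum(axis=0)
    ok = var > 0
    if not ok.any():
        raise ValueError("constant movie: no pixel has temporal variance")

    # full autocorrelation via FFT with zero padding (linear, not circular)
    nfft = 2 * n_t
    spec = np.fft.rfft(flat[:, ok], n=nfft, axis=0)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=0)[:n_t]
    ac /= ac[0]

    lags = np.empty(ac.shape[1])
    lags.fill(np.nan)
    for j in range(ac.shape[1]):
        peaks, _ = signal.find_peaks(ac[:, j], prominence=min_prominence)
        if peaks.size:
            lags[j] = peaks[0]
    lags = lags[np.isfinite(lags)]
    if lags.size == 0:
        raise ValueError("no pixel has a qualifying autocorrelation peak; "
                         "period undefined")
    return float(np.median(lags) * dt)


def line_kymograph(stack: ImageStack, p0: tuple[float, float],
                   p1: tuple[float, float], channel: int = 0) -> Kymograph:
    """Kymograph along the segment p0 -> p1 ((row, col) px coordinates).

    Positions are sampled every 1 px along the segment by bilinear
    interpolation; rows of the result are time, columns are position.
    """
    y0, x0 = p0
    y1, x1 = p1
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length < 1:
        raise ValueError("degenerate sampling segment")
    n_samples = int(np.floor(length)) + 1
    frac = np.linspace(0.0, 1.0, n_samples)
    rows = y0 + frac * (y1 - y0)
    cols = x0 + frac * (x1 - x0)
    frames = stack.channel(channel)
    kymo = np.empty((stack.n_frames, n_samples))
    for i in range(stack.n_frames):
        kymo[i] = ndimage.map_coordinates(frames[i].astype(float),
                                          [rows, cols], order=1)
    return Kymograph(kymo, stack.pixel_size, stack.frame_interval,
                     origin_convention="line start p0")


def preblur(stack: ImageStack, radius: float = 8.0) -> ImageStack:
    """Per-frame Gaussian blur (sigma = radius px) to suppress small-scale
    features before kymograph analysis; radius 0 returns the stack as is."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return stack
    blurred = ndimage.gaussian_filter(
        stack.data.astype(float), sigma=(0, 0, radius, radius))
    return ImageStack(blurred, stack.pixel_size, stack.frame_interval,
                      stack.channel_names)


def _stripe_lines(kymo_matrix: np.ndarray, angle_step_deg: float = 0.5,
                  min_rho_separation: int = 3, max_lines: int = 40,
                  denoise_sigma: float = 1.5):
    """Detect stripe lines in a kymograph via edge detection + Hough.

    The kymograph of a periodic wave is a set of parallel stripes.  The
    matrix is first lightly blurred (``denoise_sigma`` px; the stripe
    period is tens of px so the stripes are untouched while pixel noise,
    which otherwise dominates the Sobel derivative, is suppressed).  Edges
    are then the rising flanks along the space axis (signed Sobel
    derivative, Otsu threshold on its positive part, thinned to local
    maxima), which marks each wave crest once per wavelength; a linear
    Hough transform with 0.5° angular and 1 px radial resolution finds the
    lines.
    """
    if denoise_sigma > 0:
        kymo_matrix = ndimage.gaussian_filter(kymo_matrix, denoise_sigma)
    grad = ndimage.sobel(kymo_matrix, axis=1)
    pos = grad[grad > 0]
    if pos.size == 0 or np.ptp(pos) == 0:
        raise ValueError("blank kymograph: no edges to detect")
    thr = threshold_otsu(pos)
    # thin each rising flank to one pixel: keep local maxima along space
    local_max = np.ones_like(grad, dtype=bool)
    local_max[:, 1:] &= grad[:, 1:] >= grad[:, :-1]
    local_max[:, :-1] &= grad[:, :-1] > grad[:, 1:]
    edges = (grad > thr) & local_max
    theta = np.deg2rad(np.arange(-90.0, 90.0, angle_step_deg))
    hspace, angles, dists = hough_line(edges, theta=theta)
    _, peak_angles, peak_dists = hough_line_peaks(
        hspace, angles, dists,
        min_distance=min_rho_separation, min_angle=1, num_peaks=max_lines)
    return (np.asarray(peak_angles), np.asarray(peak_dists),
            hspace, angles, dists)


def _stripe_period_px(matrix: np.ndarray) -> float | None:
    """Coarse spatial stripe period (px) from the row-averaged spectrum.

    Used only to choose the denoising scale for edge detection; the
    reported wavelength always comes from the Hough line spacing.
    """
    rows = matrix - matrix.mean(axis=1, keepdims=True)
    power = (np.abs(np.fft.rfft(rows, axis=1)) ** 2).mean(axis=0)
    if power.size < 3:
        return None
    k = int(np.argmax(power[1:])) + 1
    if power[k] < 3 * np.median(power[1:]):
        return None
    return matrix.shape[1] / k


def estimate_traveling_wave(kymo: Kymograph, *, angle_gate_deg: float = 5.0,
                            angle_step_deg: float = 0.5,
                            denoise_sigma: float | None = None) -> WaveEstimate:
    """Wavelength and velocity of a traveling wave from its line kymograph.

    Hough-peak lines within ±``angle_gate_deg`` of the dominant angle give
    the slope: with rows = time and columns = space, a line at Hough angle
    θ has space-per-time slope -tan(θ), so velocity = median |slope| ×
    pixel_size / frame_interval.  The wavelength comes from the accumulator
    column at the dominant angle: its ρ-peaks are the parallel stripe
    lines, whose consecutive spacing along the space axis at fixed time is
    Δρ/|cos θ|, so wavelength = median spacing × pixel_size.  Reading the
    parallel-line family off a single angle column avoids the accumulator
    side-lobes that strong lines cast at neighboring angles.

    ``denoise_sigma`` (px) smooths the kymograph before edge detection;
    the default (None) picks it from the stripe period estimated on the
    spatial power spectrum (~period/12, clipped to [1, 5] px).
    """
    if denoise_sigma is None:
        period_px = _stripe_period_px(kymo.matrix)
        denoise_sigma = (float(np.clip(period_px / 12.0, 1.0, 5.0))
                         if period_px else 1.5)
    peak_angles, _, hspace, thetas, rhos = _stripe_lines(
        kymo.matrix, angle_step_deg=angle_step_deg,
        denoise_sigma=denoise_sigma)
    flags: list[str] = []
    if peak_angles.size < 2:
        raise ValueError("fewer than 2 stripe lines detected; "
                         "wave estimate undefined")
    dominant = peak_angles[0]  # hough_line_peaks returns strongest first
    gate = np.abs(peak_angles - dominant) <= np.deg2rad(angle_gate_deg)
    if gate.sum() < 2:
        raise ValueError("fewer than 2 parallel stripe lines within the "
                         "angle gate; wave estimate undefined")
    if not gate.all():
        flags.append("non_parallel_lines_rejected")
    gated_angles = peak_angles[gate]

    slopes = np.abs(-np.tan(gated_angles))  # px of space per frame of time
    velocity = float(np.median(slopes) * kymo.pixel_size / kymo.frame_interval)

    cos_t = np.abs(np.cos(dominant))
    if cos_t < 1e-6:
        raise ValueError("stripe lines parallel to the space axis; "
                         "spacing along space undefined")
    col = hspace[:, int(np.argmin(np.abs(thetas - dominant)))].astype(float)
    # edge jitter across rows smears each line's votes over a few ρ bins;
    # consolidate the cluster before measuring the line spacing
    col = ndimage.gaussian_filter1d(col, 2.0)
    rho_peaks, _ = signal.find_peaks(col, height=0.3 * col.max(), distance=3)
    if rho_peaks.size < 2:
        raise ValueError("could not measure line spacing")
    spacings = np.diff(rhos[rho_peaks])
    wavelength = float(np.median(spacings) / cos_t * kymo.pixel_size)
    n_lines = int(rho_peaks.size)

    period = wavelength / velocity if velocity > 0 else float("inf")
    return WaveEstimate(wavelength=wavelength, velocity=velocity,
                        period=period, n_lines=n_lines, flags=flags)


def _dominant_frequency(matrix: np.ndarray, min_peak_ratio: float = 3.0):
    """Index of the shared dominant temporal frequency of a kymograph.

    Uses the column-averaged power spectrum (DC excluded); returns None
    when the peak does not stand out against the median spectral floor.
    """
    n_t = matrix.shape[0]
    detrended = matrix - matrix.mean(axis=0, keepdims=True)
    spec = np.fft.rfft(detrended, axis=0)
    power = (np.abs(spec) ** 2).mean(axis=1)
    if power.size < 3:
        return None, spec
    body = power[1:]
    peak = int(np.argmax(body)) + 1
    floor = np.median(body)
    if floor <= 0 or body[peak - 1] < min_peak_ratio * floor:
        return None, spec
    return peak, spec


def _circular_sd(phases: np.ndarray) -> float:
    """Circular standard deviation in radians."""
    r = np.abs(np.mean(np.exp(1j * phases)))
    r = min(max(r, 1e-12), 1.0)
    return float(np.sqrt(-2 * np.log(r)))


def classify_oscillation_mode(kymo: Kymograph, *,
                              pulsing_sd_deg: float = 30.0,
                              circling_rho: float = 0.9,
                              min_peak_ratio: float = 3.0) -> OscillationMode:
    """Classify a perimeter kymograph as pulsing, pole-to-pole or circling.

    The per-column phase of the shared dominant temporal frequency defines
    a phase profile around the perimeter:

    * pulsing — all columns oscillate in phase (circular SD < 30°);
    * circling — the unwrapped phase advances monotonically through ~2π
      around the perimeter (Spearman |ρ| > 0.9 against column index);
    * pole-to-pole — the phases split into two antiphase groups ~180°
      apart, each internally coherent;
    * otherwise undetermined (also when no dominant frequency stands out).
    """
    peak, spec = _dominant_frequency(kymo.matrix, min_peak_ratio=min_peak_ratio)
    n_t = kymo.matrix.shape[0]
    if peak is None:
        return OscillationMode("undetermined", float("nan"),
                               np.zeros(kymo.matrix.shape[1]))
    period = n_t * kymo.frame_interval / peak
    phases = np.angle(spec[peak])

    if np.rad2deg(_circular_sd(phases)) < pulsing_sd_deg:
        return OscillationMode("pulsing", period, phases)

    unwrapped = np.unwrap(phases)
    cols = np.arange(unwrapped.size)
    rho = stats.spearmanr(cols, unwrapped).statistic
    span = abs(unwrapped[-1] - unwrapped[0])
    if abs(rho) > circling_rho and span > 1.2 * np.pi:
        return OscillationMode("circling", period, phases)

    # antiphase bimodality: doubled phases concentrate while raw phases do not
    r1 = np.abs(np.mean(np.exp(1j * phases)))
    r2 = np.abs(np.mean(np.exp(2j * phases)))
    if r2 > 0.7 and r1 < 0.6:
        axis = np.angle(np.mean(np.exp(2j * phases))) / 2
        group_a = np.cos(phases - axis) >= 0
        sd_a = _circular_sd(phases[group_a]) if group_a.any() else np.inf
        sd_b = _circular_sd(phases[~group_a]) if (~group_a).any() else np.inf
        if np.rad2deg(max(sd_a, sd_b)) < 2 * pulsing_sd_deg:
            return OscillationMode("pole_to_pole", period, phases)

    return OscillationMode("undetermined", period, phases)
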
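"""Perimeter kymographs, membrane/lumen intensity traces and shape metrics.

Given per-frame masks of a tracked liposome and the reporter channel, this
module extracts the quantities plotted against time in vesicle oscillation
experiments: the intensity profile along the membrane contour (stacked
into a kymograph), the mean reporter intensity at the membrane versus in
the lumen, the moment-based elongation, the equal-area-circle perimeter,
and the phase lag between shape and reporter oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import LabeledMask

__all__ = [
    "Kymograph",
    "IntensityTraces",
    "ShapeSeries",
    "smooth_reporter",
    "perimeter_path",
    "build_kymograph",
    "membrane_lumen_traces",
    "elongation",
    "normalized_perimeter",
    "elongation_phase_lag",
    "shape_series",
]


@dataclass
class Kymograph:
    """Space x time intensity matrix.

    Rows are time frames; columns are positions along the (normalized)
    perimeter or along a sampling line.  For perimeter kymographs every row
    is resampled to the longest raw circumference of the movie; the column
    origin is each frame's topmost-then-leftmost boundary pixel, proceeding
    clockwise.
    """

    matrix: np.ndarray
    pixel_size: float       # µm / px (along columns, before normalization)
    frame_interval: float   # s between rows
    origin_convention: str = "topmost-leftmost boundary pixel, clockwise"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph must be 2-D (time x space)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("kymograph contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


@dataclass
class IntensityTraces:
    membrane: np.ndarray    # per-frame mean intensity within the membrane band
    lumen: np.ndarray       # per-frame mean intensity in the eroded interior
    band_width: int
    lumen_empty: np.ndarray | None = None  # frames where the lumen region vanished

    def __post_init__(self) -> None:
        self.membrane = np.asarray(self.membrane, dtype=float)
        self.lumen = np.asarray(self.lumen, dtype=float)
        if self.membrane.shape != self.lumen.shape:
            raise ValueError("membrane and lumen traces must align")


@dataclass
class ShapeSeries:
    area_px2: np.ndarray
    area_um2: np.ndarray
    elongation: np.ndarray
    normalized_perimeter_um: np.ndarray


def _gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian sampled on a ``size`` x ``size`` support.

    For even sizes the sample grid is offset half a pixel so the kernel
    stays symmetric about its support center.
    """
    coords = np.arange(size) - (size - 1) / 2
    g = np.exp(-(coords ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_reporter(frame: np.ndarray, size: int = 10, sigma: float = 1.2) -> np.ndarray:
    """Smooth a reporter frame with a 10x10, sigma 1.2 px Gaussian kernel."""
    frame = np.asarray(frame, dtype=float)
    return ndimage.convolve(frame, _gaussian_kernel_2d(size, sigma), mode="nearest")


# Moore neighborhood in clockwise order for an image with y down:
# E, SE, S, SW, W, NW, N, NE
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def perimeter_path(mask: LabeledMask | np.ndarray) -> np.ndarray:
    """Ordered boundary pixels of a single-component mask.

    Moore-neighbor tracing: a closed, 8-connected path over the boundary
    pixels, starting at the topmost-then-leftmost boundary pixel and
    proceeding clockwise (in image coordinates, y pointing down).  Returns
    an (L, 2) array of (row, col) indices; a 1-pixel mask gives L = 1.
    """
    m = mask.mask if isinstance(mask, LabeledMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask has no perimeter")
    ys, xs = np.nonzero(m)
    start = (int(ys.min()), int(xs[ys == ys.min()].min()))
    if len(ys) == 1:
        return np.array([start])

    ny, nx = m.shape

    def filled(p):
        y, x = p
        return 0 <= y < ny and 0 <= x < nx and m[y, x]

    path = [start]
    # backtrack starts pointing N (towards the exterior above the start pixel)
    prev_dir = 6  # index of N in _MOORE
    current = start
    while True:
        # scan clockwise from the neighbor after the backtrack direction
        found = None
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            cand = (current[0] + _MOORE[d][0], current[1] + _MOORE[d][1])
            if filled(cand):
                found = (cand, d)
                break
        if found is None:  # isolated pixel (already handled) — safety net
            break
        nxt, d = found
        if nxt == start and len(path) > 1:
            break
        path.append(nxt)
        # next scan starts one past the backtrack (opposite of this step)
        prev_dir = (d + 4) % 8
        current = nxt
        if len(path) > 4 * m.size:  # pathological safety bound
            raise RuntimeError("boundary tracing failed to close")
    return np.array(path)


def _resample_row(values: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of a profile to ``length`` samples (endpoints kept)."""
    if values.size == length:
        return values.astype(float)
    if values.size == 1:
        return np.full(length, float(values[0]))
    old = np.linspace(0.0, 1.0, values.size)
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, values)


def build_kymograph(paths: list[np.ndarray], frames: np.ndarray,
                    pixel_size: float, frame_interval: float) -> Kymograph:
    """Stack per-frame perimeter intensity profiles into a kymograph.

    Row t holds the intensities of ``frames[t]`` sampled along ``paths[t]``,
    linearly resampled to the length of the longest path in the movie so
    that all rows align even when the circumference changes.
    """
    if len(paths) == 0:
        raise ValueError("need at least one frame")
    if any(p.size == 0 for p in paths):
        raise ValueError("empty perimeter path")
    longest = max(len(p) for p in paths)
    rows = []
    for path, frame in zip(paths, frames):
        profile = frame[path[:, 0], path[:, 1]]
        rows.append(_resample_row(np.asarray(profile, dtype=float), longest))
    return Kymograph(np.vstack(rows), pixel_size, frame_interval)


def membrane_lumen_traces(masks: list[LabeledMask], frames: np.ndarray,
                          band_width: int = 3) -> IntensityTraces:
    """Mean reporter intensity at the membrane versus in the lumen.

    The membrane region of a frame is the band within ``band_width`` px
    inside the mask boundary; the lumen is the mask eroded by
    ``band_width + 2`` px.  Frames where the erosion empties the lumen are
    flagged and carry NaN in the lumen trace.
    """
    if len(masks) != len(frames):
        raise ValueError("masks and frames must align")
    membrane = np.empty(len(masks))
    lumen = np.empty(len(masks))
    empty = np.zeros(len(masks), dtype=bool)
    from skimage.morphology import disk

    band_fp = disk(band_width)
    lumen_fp = disk(band_width + 2)
    for i, (lm, frame) in enumerate(zip(masks, frames)):
        inner = ndimage.binary_erosion(lm.mask, structure=band_fp)
        band = lm.mask & ~inner
        core = ndimage.binary_erosion(lm.mask, structure=lumen_fp)
        membrane[i] = frame[band].mean() if band.any() else np.nan
        if core.any():
            lumen[i] = frame[core].mean()
        else:
            lumen[i] = np.nan
            empty[i] = True
    return IntensityTraces(membrane, lumen, band_width, lumen_empty=empty)


def elongation(mask: LabeledMask | np.ndarray) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse.

    Computed from the eigenvalues of the pixel-coordinate covariance
    matrix, with the +1/12 px² pixel-area correction on the diagonal (the
    variance of a unit square), which keeps 1-px-thick masks finite.
    """
    m = mask.mask if isinstance(mask, LabeledMask) else np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if ys.size < 4:
        raise ValueError("mask too small for moment analysis (area < 4 px)")
    coords = np.stack([ys, xs]).astype(float)
    cov = np.cov(coords, bias=True) + np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    return float(np.sqrt(evals[1] / evals[0]))


def normalized_perimeter(mask: LabeledMask | np.ndarray, pixel_size: float) -> float:
    """Circumference of the circle with the same area: pi * sqrt(4A/pi) (µm)."""
    m = mask.mask if isinstance(mask, LabeledMask) else np.asarray(mask, dtype=bool)
    area_px = int(m.sum())
    if area_px == 0:
        raise ValueError("empty mask")
    area_um2 = area_px * pixel_size ** 2
    return float(np.pi * np.sqrt(4 * area_um2 / np.pi))


def shape_series(masks: list[LabeledMask], pixel_size: float) -> ShapeSeries:
    """Per-frame area, elongation and normalized perimeter of a track."""
    areas = np.array([m.area for m in masks], dtype=float)
    return ShapeSeries(
        area_px2=areas,
        area_um2=areas * pixel_size ** 2,
        elongation=np.array([elongation(m) for m in masks]),
        normalized_perimeter_um=np.array(
            [normalized_perimeter(m, pixel_size) for m in masks]),
    )


def elongation_phase_lag(elongation_series: np.ndarray, lumen_trace: np.ndarray,
                         frame_interval: float) -> float:
    """Phase lag (s) between shape elongation and the lumen reporter signal.

    The lag maximizing the circular cross-correlation of the two
    mean-subtracted series; positive means elongation *leads* the lumen
    signal.  Periodic series make the cross-correlation periodic too, so
    the search is restricted to lags within half the dominant oscillation
    period (estimated from the series' shared spectral peak); without a
    clear spectral peak, to half the record length.
    """
    e = np.asarray(elongation_series, dtype=float)
    l = np.asarray(lumen_trace, dtype=float)
    if e.shape != l.shape or e.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    if np.ptp(e) == 0 or np.ptp(l) == 0:
        raise ValueError("constant series has undefined phase")
    e = e - e.mean()
    l = l - l.mean()
    n = e.size
    # circular cross-correlation c[k] = sum_t e[t] * l[t - k]
    corr = np.fft.irfft(np.fft.rfft(e) * np.conj(np.fft.rfft(l)), n)

    power = np.abs(np.fft.rfft(e)) ** 2 + np.abs(np.fft.rfft(l)) ** 2
    half = n // 2
    if power.size > 2:
        peak = int(np.argmax(power[1:])) + 1
        if power[peak] > 3 * np.median(power[1:]):
            half = max(1, int(np.floor(n / peak / 2)))
    shifts = np.concatenate([np.arange(0, half + 1), np.arange(-half, 0)])
    k = int(shifts[np.argmax(corr[shifts % n])])
    # e[t] ~ l[t - k]: e is l delayed by k frames, i.e. elongation lags by k
    return float(-k * frame_interval)
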
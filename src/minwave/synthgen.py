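"""Synthetic fluorescence movies and expression time courses with ground truth.

This module renders the three kinds of raw data the analysis pipeline
consumes, each with a machine-readable ground truth so every downstream
estimator can be validated without real microscopy data:

* **Liposome scenes** — an equatorial cross-section of a vesicle: a thin
  bright membrane ring in channel 0 (membrane dye) and a reporter in
  channel 1 that redistributes between the membrane and the lumen in one
  of three oscillation modes (pulsing, pole-to-pole, circling), optionally
  coupled to an area-preserving shape elongation.
* **Planar surface waves** — traveling or standing sinusoidal waves on a
  flat field, as formed by Min proteins on a supported lipid bilayer.
* **Expression kinetics** — noisy sigmoid concentration time courses of
  cell-free protein synthesis.

All rendering is deterministic given the spec's seed.  Images are built at
float precision, blurred with a Gaussian PSF, then degraded with mixed
Poisson/Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .io import ImageStack
from .kinetics import KineticModel, sigmoid

__all__ = [
    "NoiseModel",
    "LiposomeSceneSpec",
    "SlbWaveSpec",
    "KineticTruth",
    "LiposomeGroundTruth",
    "render_liposome_movie",
    "render_slb_movie",
    "simulate_kinetics",
]

LiposomeMode = Literal["none", "static_membrane", "pulsing", "pole_to_pole", "circling"]


@dataclass(frozen=True)
class NoiseModel:
    """Mixed detection noise applied after PSF blur.

    gaussian_sd: additive read noise SD (intensity units).
    poisson_scale: photons per intensity unit for shot noise; 0 disables.
    speckle_amplitude / speckle_sigma: optional per-frame spatially
    correlated speckle (zero-mean Gaussian field blurred to the given
    length scale), emulating small-scale structure such as membrane-bound
    protein clusters.
    """

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0
    speckle_amplitude: float = 0.0
    speckle_sigma: float = 2.0

    def apply(self, frames: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = frames.astype(float, copy=True)
        if self.speckle_amplitude > 0:
            speck = rng.standard_normal(out.shape)
            # blur each frame's noise field to the speckle correlation length
            sig = [0.0] * (out.ndim - 2) + [self.speckle_sigma] * 2
            speck = ndimage.gaussian_filter(speck, sigma=sig)
            speck /= max(speck.std(), 1e-12)
            out += self.speckle_amplitude * speck
        if self.poisson_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_scale) / self.poisson_scale
        if self.gaussian_sd > 0:
            out += rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return out


@dataclass(frozen=True)
class LiposomeSceneSpec:
    image_size: tuple[int, int] = (96, 96)          # (rows, cols) px
    pixel_size: float = 0.2                         # µm / px
    frame_interval: float = 2.0                     # s
    n_frames: int = 120
    center: tuple[float, float] | None = None       # (row, col) px; None = image center
    radius: float = 5.0                             # µm
    membrane_width: float = 2.0                     # px (ring FWHM-ish scale)
    mode: LiposomeMode = "pulsing"
    period: float = 50.0                            # s
    reporter_amplitude: float = 200.0
    membrane_dye_level: float = 300.0
    elongation_amplitude: float = 1.0               # >= 1; 1 = no deformation
    elongation_phase_lag: float = 0.0               # s
    psf_sigma: float = 1.0                          # px
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        r_px = self.radius / self.pixel_size
        if 2 * r_px >= min(self.image_size):
            raise ValueError("liposome diameter exceeds the field of view")
        if self.mode in ("pulsing", "pole_to_pole", "circling"):
            if self.period <= 2 * self.frame_interval:
                raise ValueError(
                    f"period {self.period}s violates Nyquist for frame interval "
                    f"{self.frame_interval}s"
                )
        if self.membrane_width >= r_px:
            raise ValueError("membrane ring thicker than the liposome radius")
        if self.elongation_amplitude < 1:
            raise ValueError("elongation_amplitude must be >= 1")


@dataclass
class LiposomeGroundTruth:
    """Per-frame truth recorded alongside a rendered liposome movie."""

    masks: np.ndarray                 # (T, Y, X) bool
    membrane_fraction: np.ndarray     # (T,) reporter fraction on the membrane
    lumen_fraction: np.ndarray        # (T,)
    elongation: np.ndarray            # (T,) major/minor axis ratio
    mode: str
    period: float

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "period_s": self.period,
            "membrane_fraction": self.membrane_fraction.tolist(),
            "lumen_fraction": self.lumen_fraction.tolist(),
            "elongation": self.elongation.tolist(),
        }


def _angular_weight(theta: np.ndarray, mode: str, phase: float) -> np.ndarray:
    """Weight of the membrane-bound reporter along the contour.

    Normalized so its angular mean is 1, which keeps the reporter budget
    split exactly (membrane_fraction, lumen_fraction) regardless of mode.
    """
    if mode in ("static_membrane", "pulsing", "none"):
        return np.ones_like(theta)
    if mode == "pole_to_pole":
        # two antiphase hemispheres; poles on the x-axis (the major axis)
        w_a = (1 + np.cos(phase)) / 2
        w_b = (1 - np.cos(phase)) / 2
        return 2 * np.where(np.cos(theta) >= 0, w_a, w_b)
    if mode == "circling":
        # von Mises hotspot advancing one turn per period; I0 normalizes mean to 1
        kappa = 4.0
        return np.exp(kappa * np.cos(theta - phase)) / special.i0(kappa)
    raise ValueError(f"unknown mode {mode!r}")


def _membrane_fraction(mode: str, phase: float) -> float:
    if mode == "none":
        return 0.0
    if mode == "static_membrane":
        return 1.0
    if mode == "pulsing":
        return 0.5 * (1 + np.cos(phase))
    # pole_to_pole / circling redistribute along the membrane at constant
    # total binding
    return 0.7


def render_liposome_movie(spec: LiposomeSceneSpec) -> tuple[ImageStack, LiposomeGroundTruth]:
    """Render a 2-channel liposome time-lapse plus its ground truth.

    Channel 0 is the membrane dye (ring intensity constant in time up to
    noise); channel 1 is the reporter, partitioned between a ring component
    and a uniform lumen component according to the oscillation mode.  The
    ring has a radial Gaussian cross-section of SD ``membrane_width / 2``
    centered on the (possibly elliptical) contour.  Elongation preserves
    cross-section area: semi-axes r*sqrt(e) and r/sqrt(e).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.image_size
    cy, cx = spec.center if spec.center is not None else ((ny - 1) / 2, (nx - 1) / 2)
    r_px = spec.radius / spec.pixel_size
    sigma_r = spec.membrane_width / 2

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)

    n = spec.n_frames
    membrane_ch = np.empty((n, ny, nx))
    reporter_ch = np.empty((n, ny, nx))
    masks = np.empty((n, ny, nx), dtype=bool)
    mem_frac = np.empty(n)
    elong = np.empty(n)

    for i in range(n):
        t = i * spec.frame_interval
        phase = 2 * np.pi * t / spec.period if spec.period > 0 else 0.0
        if spec.elongation_amplitude > 1:
            ph_e = 2 * np.pi * (t - spec.elongation_phase_lag) / spec.period
            e = 1 + (spec.elongation_amplitude - 1) * (1 + np.cos(ph_e)) / 2
        else:
            e = 1.0
        a, b = r_px * np.sqrt(e), r_px / np.sqrt(e)  # major axis along x
        rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
        dist = (rho - 1) * np.sqrt(a * b)  # approx signed distance to contour, px
        ring = np.exp(-(dist ** 2) / (2 * sigma_r ** 2))
        mask = rho <= 1
        masks[i] = mask
        elong[i] = e

        membrane_ch[i] = spec.membrane_dye_level * ring

        f = _membrane_fraction(spec.mode, phase)
        mem_frac[i] = f
        g = _angular_weight(theta, spec.mode, phase)
        area = np.pi * a * b
        perimeter = 2 * np.pi * np.sqrt(a * b)  # equal-area circle circumference
        # scale so ring pixel sum ~ f * amplitude * area, matching the lumen sum
        gain = area / (perimeter * sigma_r * np.sqrt(2 * np.pi))
        reporter = spec.reporter_amplitude * f * g * ring * gain
        reporter = reporter + spec.reporter_amplitude * (1 - f) * mask
        reporter_ch[i] = reporter

    stack = np.stack([membrane_ch, reporter_ch], axis=1)
    if spec.psf_sigma > 0:
        stack = ndimage.gaussian_filter(stack, sigma=(0, 0, spec.psf_sigma, spec.psf_sigma))
    stack = spec.noise.apply(stack, rng)

    truth = LiposomeGroundTruth(
        masks=masks,
        membrane_fraction=mem_frac,
        lumen_fraction=1.0 - mem_frac,
        elongation=elong,
        mode=spec.mode,
        period=spec.period,
    )
    image = ImageStack(stack, spec.pixel_size, spec.frame_interval,
                       ("membrane_dye", "reporter"))
    return image, truth


@dataclass(frozen=True)
class SlbWaveSpec:
    image_size: tuple[int, int] = (96, 256)   # (rows, cols) px
    pixel_size: float = 1.0                   # µm / px
    frame_interval: float = 2.0               # s
    n_frames: int = 150
    kind: Literal["traveling", "standing"] = "traveling"
    wavelength: float = 40.0                  # µm
    velocity: float = 0.5                     # µm/s (traveling)
    period: float = 47.0                      # s (standing)
    direction: float = 0.0                    # degrees, propagation direction
    amplitude: float = 100.0
    baseline: float = 50.0
    psf_sigma: float = 0.0                    # px
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if self.wavelength <= 2 * self.pixel_size:
            raise ValueError("wavelength must exceed 2 px (Nyquist)")
        if self.kind == "standing" and self.period <= 2 * self.frame_interval:
            raise ValueError("standing-wave period violates temporal Nyquist")

    @property
    def implied_period(self) -> float:
        """Temporal period: wavelength/velocity for traveling waves."""
        return self.wavelength / self.velocity if self.kind == "traveling" else self.period


def render_slb_movie(spec: SlbWaveSpec) -> ImageStack:
    """Render a single-channel planar wave movie.

    Traveling:  I(x,t) = baseline + A (1 + cos(2π(x' − v t)/λ)) / 2
    Standing:   I(x,t) = baseline + A (1 + cos(2πx'/λ))/2 · (1 + cos(2πt/T))/2

    with x' the coordinate along the propagation direction, in µm.
    PSF blur and noise are applied afterwards.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.image_size
    th = np.deg2rad(spec.direction)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    xprime = (xx * np.cos(th) + yy * np.sin(th)) * spec.pixel_size

    times = np.arange(spec.n_frames) * spec.frame_interval
    frames = np.empty((spec.n_frames, ny, nx))
    for i, t in enumerate(times):
        if spec.kind == "traveling":
            ph = 2 * np.pi * (xprime - spec.velocity * t) / spec.wavelength
            frames[i] = spec.baseline + spec.amplitude * (1 + np.cos(ph)) / 2
        else:
            sp = (1 + np.cos(2 * np.pi * xprime / spec.wavelength)) / 2
            tp = (1 + np.cos(2 * np.pi * t / spec.period)) / 2
            frames[i] = spec.baseline + spec.amplitude * sp * tp
    if spec.psf_sigma > 0:
        frames = ndimage.gaussian_filter(frames, sigma=(0, spec.psf_sigma, spec.psf_sigma))
    frames = spec.noise.apply(frames, rng)
    return ImageStack(frames, spec.pixel_size, spec.frame_interval, ("wave",))


@dataclass(frozen=True)
class KineticTruth:
    """Generating model and sampling design for a simulated expression assay."""

    model: KineticModel
    timepoints: tuple[float, ...]   # minutes, strictly increasing, >= 0
    noise_sd: float = 1.0           # µM
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_kinetics(truth: KineticTruth) -> pd.DataFrame:
    """Simulate a noisy expression time course.

    Returns a tidy table with columns ``time_min``, ``conc_uM``,
    ``replicate``; concentrations are the sigmoid model evaluated at the
    timepoints plus i.i.d. Gaussian noise, reproducible from the seed.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    t = np.asarray(truth.timepoints, dtype=float)
    clean = sigmoid(t, truth.model)
    rows = []
    for rep in range(truth.n_replicates):
        noisy = clean + rng.normal(0.0, truth.noise_sd, size=t.size)
        rows.append(pd.DataFrame({"time_min": t, "conc_uM": noisy, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)
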
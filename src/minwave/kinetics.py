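"""Sigmoid expression-kinetics fitting and weighted calibration quantification.

Cell-free protein synthesis follows a rise-then-plateau time course that is
well captured by the phenomenological Hill-type sigmoid

    y(t) = k' + k * t^n / (t^n + K^n)

where k' (µM) is the baseline, k (µM) the final yield, K (min) the
half-rise time and n the steepness.  Two derived quantities summarize the
curve: the plateau time (expression lifespan)

    T_plateau = 2K/n + K

which is where the tangent at t = K reaches the plateau level k' + k, and
the apparent translation rate, the steepness at t = K,

    v_translation = k n / (4 K).

Peptide concentrations from LC-MS are mapped to µM through a straight-line
calibration fitted with instrumental variance weighting (weights 1/σ_i² per
calibration level), optionally normalized to an internal-standard peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "KineticModel",
    "SigmoidFit",
    "CalibrationCurve",
    "QuantResult",
    "sigmoid",
    "fit_sigmoid",
    "plateau_time",
    "translation_rate",
    "fit_calibration",
    "quantify",
    "protein_concentration",
]


@dataclass(frozen=True)
class KineticModel:
    """Parameters of the expression sigmoid."""

    k_prime: float   # µM, baseline
    k: float         # µM, final yield
    K: float         # min, half-rise time
    n: float         # steepness (dimensionless)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("yield k must be >= 0")
        if self.K <= 0:
            raise ValueError("half-rise time K must be > 0")
        if self.n < 1:
            raise ValueError("steepness n must be >= 1")


def sigmoid(t, m: KineticModel):
    """Evaluate the expression sigmoid at time(s) t (minutes)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    tn = np.power(t, m.n)
    out = m.k_prime + m.k * tn / (tn + m.K ** m.n)
    return out if out.ndim else float(out)


def plateau_time(m: KineticModel) -> float:
    """Expression lifespan: T_plateau = 2K/n + K (minutes)."""
    return 2 * m.K / m.n + m.K


def translation_rate(m: KineticModel) -> float:
    """Apparent translation rate, the steepness at t = K: k n / (4K) (µM/min)."""
    return m.k * m.n / (4 * m.K)


@dataclass
class SigmoidFit:
    model: KineticModel
    covariance: np.ndarray        # 4x4, parameter order (k', k, K, n)
    residual_sd: float
    converged: bool
    n_points: int

    @property
    def plateau_time(self) -> float:
        return plateau_time(self.model)

    @property
    def translation_rate(self) -> float:
        return translation_rate(self.model)


def _sigmoid_raw(t, kp, k, K, n):
    tn = np.power(t, n)
    return kp + k * tn / (tn + K ** n)


def fit_sigmoid(t, y, sigma=None, *, n_restarts: int = 5,
                seed: int = 0) -> SigmoidFit:
    """Fit the expression sigmoid by (optionally weighted) least squares.

    Initialization: k' = min(y), k = max(y) - min(y), K = time at half
    rise, n = 4; parameters are bounded (k >= 0, K > 0, n in [1, 20]).
    ``n_restarts`` jittered initializations guard against the flat-n
    direction of the objective; the best-residual solution is kept.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 5:
        raise ValueError("need at least 5 points spanning rise and plateau")
    if np.ptp(y) == 0:
        raise ValueError("all observations equal; sigmoid is unidentifiable")
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    half = y_lo + (y_hi - y_lo) / 2
    above = t[y >= half]
    K0 = float(above[0]) if above.size and above[0] > 0 else float(np.median(t[t > 0]))
    p0_base = np.array([y_lo, y_hi - y_lo, K0, 4.0])
    lower = [-np.inf, 0.0, 1e-9, 1.0]
    upper = [np.inf, np.inf, np.inf, 20.0]

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, n_restarts)):
        p0 = p0_base.copy()
        if trial > 0:
            p0[1:3] *= rng.uniform(0.5, 2.0, size=2)
            p0[3] = rng.uniform(1.5, 8.0)
        p0 = np.clip(p0, lower, upper)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _sigmoid_raw, t, y, p0=p0, sigma=sigma,
                    bounds=(lower, upper), maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = y - _sigmoid_raw(t, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from any initialization")

    ssr, popt, pcov = best
    dof = max(t.size - 4, 1)
    model = KineticModel(k_prime=float(popt[0]), k=float(popt[1]),
                         K=float(popt[2]), n=float(popt[3]))
    return SigmoidFit(model=model, covariance=pcov,
                      residual_sd=float(np.sqrt(ssr / dof)),
                      converged=True, n_points=t.size)


@dataclass
class CalibrationCurve:
    """Weighted linear intensity -> concentration map."""

    slope: float                   # intensity per µM
    intercept: float               # intensity
    sigmas: np.ndarray             # per-level intensity SD
    concentrations: np.ndarray     # calibrated µM levels
    zero_sigma_replaced: bool = False

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.sigmas ** 2

    @property
    def conc_range(self) -> tuple[float, float]:
        return float(self.concentrations.min()), float(self.concentrations.max())

    @property
    def usable(self) -> bool:
        return self.slope > 0


def fit_calibration(concentrations, intensities, sigmas) -> CalibrationCurve:
    """Fit a straight calibration line with instrumental variance weighting.

    Minimizes sum_i w_i (y_i - a c_i - b)^2 with w_i = 1/σ_i².  Zero or
    non-finite σ at a level is replaced by the smallest positive σ in the
    set (flagged on the returned curve).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    s = np.asarray(sigmas, dtype=float).copy()
    if not (c.size == y.size == s.size):
        raise ValueError("levels, intensities and sigmas must align")
    if c.size < 3:
        raise ValueError("need at least 3 calibration levels")
    bad = ~(np.isfinite(s) & (s > 0))
    replaced = bool(bad.any())
    if bad.all():
        raise ValueError("no calibration level has a valid sigma")
    if replaced:
        s[bad] = s[~bad].min()

    wls = sm.WLS(y, sm.add_constant(c), weights=1.0 / s ** 2).fit()
    intercept, slope = wls.params
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            sigmas=s, concentrations=c,
                            zero_sigma_replaced=replaced)


@dataclass
class QuantResult:
    peptide_id: str
    concentration: float           # µM
    dilution: float
    normalized_to_internal_standard: bool
    extrapolated: bool


def quantify(intensity: float, curve: CalibrationCurve, *,
             dilution: float = 1.0, internal_standard_ratio: float | None = None,
             peptide_id: str = "") -> QuantResult:
    """Convert a measured peak intensity to a sample concentration.

    concentration = dilution * (intensity / IS_ratio - intercept) / slope.
    The internal-standard ratio (sample IS intensity over reference IS
    intensity) corrects run-to-run handling variation.  Values outside the
    calibrated range are flagged as extrapolated.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive for quantification")
    eff = intensity
    normed = internal_standard_ratio is not None
    if normed:
        if internal_standard_ratio <= 0:
            raise ValueError("internal standard ratio must be positive")
        eff = intensity / internal_standard_ratio
    conc_undiluted = (eff - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    extrapolated = not (lo <= conc_undiluted <= hi)
    return QuantResult(peptide_id=peptide_id,
                       concentration=dilution * conc_undiluted,
                       dilution=dilution,
                       normalized_to_internal_standard=normed,
                       extrapolated=extrapolated)


def protein_concentration(peptide_results: list[tuple[int, QuantResult]],
                          protein_length: int | None = None,
                          coverage_warn_fraction: float = 0.8) -> QuantResult:
    """Report protein concentration from the most C-terminal peptide.

    ``peptide_results`` pairs each peptide's position along the protein
    primary sequence (residue index of the peptide start) with its
    quantification; the peptide furthest toward the C-terminus wins.  When
    ``protein_length`` is given and the winning peptide sits before
    ``coverage_warn_fraction`` of the sequence, a warning is emitted: the
    reported value then reflects incomplete C-terminal coverage (as happens
    when no C-proximal proteolytic peptide is detectable).
    """
    if not peptide_results:
        raise ValueError("no peptides supplied")
    pos, result = max(peptide_results, key=lambda pr: pr[0])
    if protein_length is not None and pos < coverage_warn_fraction * protein_length:
        warnings.warn(
            f"most C-terminal quantified peptide starts at residue {pos} of "
            f"{protein_length}; concentration may underestimate full-length protein",
            stacklevel=2,
        )
    return result
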
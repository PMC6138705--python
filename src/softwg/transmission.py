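"""Bench-style transmission statistics.

The bench experiment sends a signal simultaneously into a reference channel
and through the device under test; the figures of merit are

* the transmission efficiency ``V_pp / V_ref`` (peak-to-peak amplitude of
  the transmitted trace over that of the reference),
* the attenuation length ``L0``, the propagation distance over which the
  amplitude falls to 1/e, obtained by an ordinary least-squares line on
  (length, ln efficiency),
* the low-pass characteristics: the -3 dB cutoff of a frequency sweep and
  the saturation duration (95% of the plateau) of a pulse-duration sweep.

Peak-to-peak amplitudes are extracted robustly: for square pulses the
median of the top-decile samples minus the median of the bottom-decile
samples (insensitive to edge ringing); for sines the span of the steady
oscillation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError, DegenerateReferenceError


@dataclass
class TraceSet:
    """A reference/transmitted voltage-trace pair plus condition metadata."""

    times: np.ndarray
    reference: np.ndarray
    transmitted: np.ndarray
    excitation: str = "square"  # "square" | "sine"
    length_cm: float = 0.0
    thickness_mm: float = 0.0
    concentration_mol_l: float = 0.0
    duration_s: float | None = None
    frequency_hz: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.transmitted = np.asarray(self.transmitted, dtype=float)
        if not (self.times.shape == self.reference.shape == self.transmitted.shape):
            raise AnalysisError("traces must share one sampling grid")
        for name in ("length_cm", "thickness_mm", "concentration_mol_l"):
            if getattr(self, name) < 0:
                raise AnalysisError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TransmissionMeasurement:
    v_pp: float
    v_ref: float

    @property
    def efficiency(self) -> float:
        return self.v_pp / self.v_ref

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.efficiency


@dataclass(frozen=True)
class AttenuationFit:
    """Log-linear attenuation fit; ``l0_cm = inf`` flags non-attenuating data."""

    l0_cm: float
    intercept: float
    stderr: float
    n_points: int
    ci95: tuple[float, float] = (math.nan, math.nan)

    @property
    def attenuating(self) -> bool:
        return math.isfinite(self.l0_cm)


@dataclass
class FrequencyResponse:
    """Efficiency versus frequency (Hz) or pulse duration (s)."""

    abscissa: np.ndarray
    efficiency: np.ndarray
    mode: str = "frequency"  # "frequency" | "duration"

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.efficiency.shape:
            raise AnalysisError("abscissa and efficiency must be matching vectors")
        if np.any(np.diff(self.abscissa) <= 0):
            raise AnalysisError("abscissa must be strictly increasing")
        if self.mode not in ("frequency", "duration"):
            raise AnalysisError(f"unknown response mode {self.mode!r}")


def _robust_span(v: np.ndarray) -> float:
    """Plateau minus baseline, each as the median of a value decile.

    Plateau samples are those within the top 10% of the trace's value range,
    baseline samples within the bottom 10%; the medians are insensitive to
    edge ringing and to the pulse's duty cycle inside the window.
    """
    vmax = float(v.max())
    vmin = float(v.min())
    span = vmax - vmin
    if span == 0.0:
        return 0.0
    plateau = np.sort(v[v >= vmin + 0.5 * span])
    top = plateau[-max(1, plateau.size // 10) :]
    base = v[v <= vmin + 0.1 * span]
    base_level = float(np.median(base)) if base.size else vmin
    return float(np.median(top) - base_level)


def peak_to_peak(v: np.ndarray, excitation: str) -> float:
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise AnalysisError("empty trace")
    if excitation == "sine":
        return float(v.max() - v.min())
    return _robust_span(v)


def transmission_efficiency(trace_set: TraceSet) -> TransmissionMeasurement:
    """V_pp / V_ref from a trace pair."""
    v_ref = peak_to_peak(trace_set.reference, trace_set.excitation)
    if v_ref <= 0.0:
        raise DegenerateReferenceError("reference trace has no peak-to-peak span")
    v_pp = peak_to_peak(trace_set.transmitted, trace_set.excitation)
    return TransmissionMeasurement(v_pp=max(v_pp, 0.0), v_ref=v_ref)


def fit_attenuation_length(lengths_cm, efficiencies) -> AttenuationFit:
    """OLS line on (length, ln efficiency); ``L0 = -1/slope``.

    The 95% confidence interval for L0 is obtained by inverting the t-based
    interval of the slope.  A non-negative slope is reported as the
    non-attenuating sentinel ``L0 = inf``.
    """
    lengths = np.asarray(lengths_cm, dtype=float)
    eff = np.asarray(efficiencies, dtype=float)
    if np.unique(lengths).size < 3:
        raise AnalysisError("need at least 3 distinct lengths")
    if np.any(eff <= 0.0):
        raise AnalysisError("efficiencies must be positive for the log fit")
    res = stats.linregress(lengths, np.log(eff))
    slope, intercept, stderr = res.slope, res.intercept, res.stderr
    n = lengths.size
    resid = np.log(eff) - (intercept + slope * lengths)
    rse = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
    if slope >= 0.0:
        return AttenuationFit(
            l0_cm=math.inf, intercept=intercept, stderr=rse, n_points=n
        )
    tcrit = stats.t.ppf(0.975, n - 2)
    s_lo = slope - tcrit * stderr
    s_hi = slope + tcrit * stderr
    lo = -1.0 / s_lo  # most negative slope -> shortest L0
    hi = math.inf if s_hi >= 0.0 else -1.0 / s_hi
    return AttenuationFit(
        l0_cm=-1.0 / slope,
        intercept=intercept,
        stderr=rse,
        n_points=n,
        ci95=(lo, hi),
    )


def _plateau(response: FrequencyResponse, n: int = 2) -> float:
    """Plateau efficiency: mean of the n points nearest the passband end."""
    if response.mode == "frequency":
        return float(np.mean(response.efficiency[:n]))
    return float(np.mean(response.efficiency[-n:]))


def characterize_low_pass(response: FrequencyResponse) -> float:
    """Cutoff frequency (Hz) or saturation duration (s) of a sweep.

    Frequency mode: the -3 dB point relative to the low-frequency plateau,
    located by log-log interpolation of the linearized single-pole form
    ``(A0/eff)^2 - 1`` (exact for an ideal one-pole response, robust on
    decade-spaced grids).  Duration mode: the smallest duration reaching 95%
    of the plateau, from a through-origin fit of ``-ln(1 - eff/A0)`` versus
    duration (exact for an ideal saturating exponential).
    """
    if response.abscissa.size < 5:
        raise AnalysisError("need at least 5 abscissa points")
    span = response.abscissa[-1] / response.abscissa[0]
    if span < 1e3:
        raise AnalysisError("sweep must span at least 3 decades")
    a0 = _plateau(response)
    if a0 <= 0.0:
        raise AnalysisError("no plateau detectable")

    if response.mode == "frequency":
        ratio = np.clip(response.efficiency / a0, 1e-9, None)
        y = (1.0 / ratio) ** 2 - 1.0
        # keep only stations where the roll-off term dominates measurement
        # noise (response at least 3 dB below the plateau)
        mask = y >= 0.5
        if np.count_nonzero(mask) < 2 or y.max() < 1.0:
            raise AnalysisError("sweep does not reach the -3 dB point")
        logf = np.log(response.abscissa[mask])
        logy = np.log(y[mask])
        slope, intercept = np.polyfit(logf, logy, 1)
        if slope <= 0:
            raise AnalysisError("no low-pass roll-off detectable")
        return float(np.exp(-intercept / slope))

    # duration mode
    r = response.efficiency / a0
    # rising region only: durations before the curve first reaches 90% of
    # the plateau (later plateau points dipping below threshold by noise
    # must not re-enter the fit)
    reached = np.nonzero(r >= 0.9)[0]
    last = reached[0] if reached.size else r.size
    mask = np.zeros_like(r, dtype=bool)
    mask[:last] = r[:last] > 0.05
    if np.count_nonzero(mask) < 2:
        raise AnalysisError("too few points in the rising region to characterize")
    rr = np.clip(r[mask], None, 0.9999)
    y = -np.log1p(-rr)
    t = response.abscissa[mask]
    # inverse-variance weights: Var(y) grows like (r / (1 - r))^2 under
    # multiplicative efficiency noise
    w = ((1.0 - rr) / rr) ** 2
    denom = float(np.sum(w * y * y))
    tau = float(np.sum(w * t * y) / denom) if denom > 0 else math.nan
    if not math.isfinite(tau) or tau <= 0:
        raise AnalysisError("no saturating trend detectable")
    return -math.log(0.05) * tau  # duration where 1 - exp(-T/tau) = 0.95


def saturation_time_constant(saturation_duration: float) -> float:
    """Convert the 95% saturation duration back to the exponential constant."""
    return saturation_duration / (-math.log(0.05))
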
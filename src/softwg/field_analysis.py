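"""Reduction of simulation probe data to transmission summaries.

Three reductions mirror the standard presentation of waveguide-confinement
results: a normalized axial energy-density profile (how fast the guided
energy decays along the tube), transverse cross-section amplitude maps at
the source / center / output stations, and signal-front arrival times used
to compare propagation speed between the waveguide and the homogeneous
control.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .geometry import MaterialGrid


@dataclass
class ProbeRecord:
    """Time series of one sampled quantity at one probe location.

    ``quantity`` names a field component (``"Ex"`` ... ``"Hz"``), the
    electric-field magnitude ``"Emag"``, or ``"plane_energy"`` for
    transverse-plane-integrated energy density at an axial station.
    """

    location: tuple[int, int, int]
    quantity: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise AnalysisError("time and value vectors must have equal length")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise AnalysisError("time vector must be strictly increasing")


@dataclass
class EnergyProfile:
    """Normalized peak energy density u(z) along the tube axis."""

    positions: np.ndarray  # metres
    values: np.ndarray  # dimensionless, u(reference) == 1
    reference_index: int

    def __post_init__(self):
        if np.any(self.values < 0):
            raise AnalysisError("energy density cannot be negative")


@dataclass
class CrossSectionMap:
    """Peak electric-field amplitude over one transverse plane."""

    station: str
    amplitude: np.ndarray  # 2D, >= 0
    cell_size: float

    def peak_radius(self) -> float:
        """Radial distance (m) of the amplitude maximum from the tube axis."""
        n0, n1 = self.amplitude.shape
        i, j = np.unravel_index(int(np.argmax(self.amplitude)), self.amplitude.shape)
        u = (i + 0.5) * self.cell_size - n0 * self.cell_size / 2.0
        v = (j + 0.5) * self.cell_size - n1 * self.cell_size / 2.0
        return float(np.hypot(u, v))


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones_like(times, dtype=bool)
    t0, t1 = window
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise AnalysisError("window lies outside the record span")
    return mask


def energy_density_profile(
    records: list[ProbeRecord],
    grid: MaterialGrid,
    window: tuple[float, float] | None = None,
    reference: int | str = 0,
) -> EnergyProfile:
    """Peak-over-time axial energy profile, normalized at the source station.

    ``records`` are per-axial-station ``plane_energy`` time series (the
    transverse-plane sum of 0.5 eps |E|^2 + 0.5 mu |H|^2); each station's
    value is the time-peak inside ``window``, divided by the value at the
    ``reference`` station (the source plane).  ``reference="max"`` selects
    the most energetic station, which is the source plane when the full
    axial range including absorbing boundaries is supplied.
    """
    if not records:
        raise AnalysisError("no records supplied")
    axis = grid.axis
    peaks = []
    positions = []
    for rec in records:
        mask = _window_mask(rec.times, window)
        peaks.append(float(rec.values[mask].max()))
        positions.append((rec.location[axis] + 0.5) * grid.cell_size)
    peaks = np.asarray(peaks)
    if reference == "max":
        reference = int(np.argmax(peaks))
    ref = peaks[reference]
    if ref <= 0.0:
        raise AnalysisError("reference station carries no energy")
    return EnergyProfile(
        positions=np.asarray(positions), values=peaks / ref, reference_index=int(reference)
    )


def cross_section_map(
    snapshot: np.ndarray, station: str, cell_size: float
) -> CrossSectionMap:
    """Wrap a per-pixel peak |E| plane into a :class:`CrossSectionMap`."""
    snap = np.asarray(snapshot, dtype=float)
    if snap.ndim != 2:
        raise AnalysisError("snapshot must be a 2D transverse plane")
    return CrossSectionMap(station=station, amplitude=np.abs(snap), cell_size=cell_size)


def front_arrival_time(record: ProbeRecord, threshold: float = 0.05) -> float:
    """First time |value| exceeds ``threshold`` times the record maximum.

    The default 5% threshold operationalizes the onset ("motivation") of the
    signal at a station; comparing the same threshold between waveguide and
    control runs gives the speed-up statistic.
    """
    if not 0.0 < threshold < 1.0:
        raise AnalysisError("threshold fraction must lie in (0, 1)")
    mag = np.abs(record.values)
    peak = mag.max()
    if peak == 0.0:
        raise AnalysisError("record is identically zero; arrival undefined")
    idx = int(np.argmax(mag >= threshold * peak))
    return float(record.times[idx])
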
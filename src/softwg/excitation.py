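"""Excitation waveforms and source placements.

Three waveform families drive both the FDTD runs and the synthetic bench
experiment:

* a Gaussian pulse ``E(t) = exp(-4 pi (t - t0)^2 / tau^2)`` with defaults
  ``tau = 2.40 ns`` and ``t0 = 1.92 ns``,
* a single-frequency sine specified by its vacuum wavelength (default
  1.44 m, i.e. ~208.2 MHz) or frequency,
* a trapezoidal square-pulse train with 2.5 ns edges and 2.0 V peak-to-peak
  plateau, matching the bench generator settings.

Source placement supports the two layouts used in the simulations: a single
axially polarized point source on the tube axis, and a ring of eight radially
polarized dipoles spaced 45 degrees apart at mid-shell radius in one
cross-section.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import c as C0

from .errors import ConfigurationError, PlacementError
from .geometry import TubeGeometry


@dataclass(frozen=True)
class GaussianPulseSpec:
    """Gaussian pulse; ``tau`` controls the width, ``t0`` the center."""

    tau: float = 2.40e-9
    t0: float = 1.92e-9
    amplitude: float = 1.0
    polarization: str = "radial"

    def __post_init__(self):
        if self.tau <= 0.0:
            raise ConfigurationError("tau must be positive")

    def bandwidth_3db(self) -> float:
        """-3 dB (half-power) full width of the amplitude spectrum, Hz.

        The transform of exp(-4 pi t^2 / tau^2) is Gaussian in f with
        |S(f)| = exp(-pi^2 f^2 tau^2 / (4 pi)); the amplitude falls to
        1/sqrt(2) at f = sqrt(2 ln 2 / pi) / tau on either side.
        """
        return 2.0 * math.sqrt(2.0 * math.log(2.0) / math.pi) / self.tau


@dataclass(frozen=True)
class SineSpec:
    """Single-frequency sine given by vacuum wavelength or frequency.

    The wavelength is interpreted in vacuum (f = c0 / lambda); pass
    ``frequency`` directly to override that interpretation.
    """

    wavelength: float | None = 1.44
    frequency: float | None = None
    amplitude: float = 1.0
    polarization: str = "axial"

    def __post_init__(self):
        if self.frequency is None and (self.wavelength is None or self.wavelength <= 0):
            raise ConfigurationError("need a positive wavelength or a frequency")
        if self.frequency is not None and self.frequency <= 0:
            raise ConfigurationError("frequency must be positive")

    @property
    def f(self) -> float:
        if self.frequency is not None:
            return self.frequency
        return C0 / self.wavelength

    @property
    def period(self) -> float:
        return 1.0 / self.f


@dataclass(frozen=True)
class SquarePulseSpec:
    """Trapezoidal square-pulse train.

    ``amplitude`` is the plateau height (the bench pulses are unipolar with a
    2.0 V peak-to-peak swing); the rise and fall ramps of ``edge_time`` lie
    inside ``duration``.  ``repetition_frequency`` may be None for a single
    pulse.
    """

    duration: float
    repetition_frequency: float | None = None
    amplitude: float = 2.0
    edge_time: float = 2.5e-9

    def __post_init__(self):
        if self.duration <= 2.0 * self.edge_time:
            raise ConfigurationError(
                f"duration {self.duration} must exceed twice the edge time "
                f"{self.edge_time}"
            )
        if self.repetition_frequency is not None:
            if self.duration * self.repetition_frequency >= 1.0:
                raise ConfigurationError("duty cycle must be below one")


def gaussian_waveform(t, spec: GaussianPulseSpec):
    """Evaluate the Gaussian pulse at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    return spec.amplitude * np.exp(-4.0 * np.pi * (t - spec.t0) ** 2 / spec.tau**2)


def sine_waveform(t, spec: SineSpec, ramp_periods: float = 0.0):
    """Evaluate the sine at time(s) ``t``.

    ``ramp_periods > 0`` applies a cosine taper from zero over that many
    periods, used in simulations to reach steady state without a hard start.
    """
    t = np.asarray(t, dtype=float)
    out = spec.amplitude * np.sin(2.0 * np.pi * spec.f * t)
    if ramp_periods > 0.0:
        t_ramp = ramp_periods * spec.period
        ramp = np.where(t < t_ramp, 0.5 * (1.0 - np.cos(np.pi * t / t_ramp)), 1.0)
        out = out * ramp
    return out


def square_waveform(t, spec: SquarePulseSpec):
    """Evaluate the trapezoidal pulse train at time(s) ``t``.

    Each pulse rises linearly over ``edge_time``, holds the plateau, and
    falls over ``edge_time``, so the single-pulse integral is
    ``amplitude * (duration - edge_time)``.
    """
    t = np.asarray(t, dtype=float)
    if spec.repetition_frequency is not None:
        tp = np.mod(t, 1.0 / spec.repetition_frequency)
    else:
        tp = t
    e, d, a = spec.edge_time, spec.duration, spec.amplitude
    up = np.clip(tp / e, 0.0, 1.0)
    down = np.clip((d - tp) / e, 0.0, 1.0)
    return a * np.minimum(up, down) * (tp < d)


@dataclass(frozen=True)
class SourcePlacement:
    """Where sources sit in the grid.

    ``mode`` is ``"axial"`` (one axially polarized point on the tube axis) or
    ``"ring"`` (eight radially polarized dipoles, 45 degrees apart, sharing
    one cross-section at mid-shell radius ``(d + D)/4`` unless overridden).
    """

    mode: str = "ring"
    axial_index: int | None = None
    ring_radius_mm: float | None = None

    def __post_init__(self):
        if self.mode not in ("axial", "ring"):
            raise ConfigurationError(f"unknown placement mode {self.mode!r}")


@dataclass(frozen=True)
class PlacedSource:
    """One source cell with a unit polarization vector."""

    cell: tuple[int, int, int]
    polarization: tuple[float, float, float]


def place_sources(
    placement: SourcePlacement,
    geometry: TubeGeometry,
    dims: tuple[int, int, int],
    cell_size: float,
) -> list[PlacedSource]:
    """Resolve a placement to grid cells and polarization unit vectors.

    Ring positions are snapped to the nearest cell center; polarization
    vectors are the exact radial directions (their sum over the ring is the
    zero vector).  The default axial station is just inside the tube mouth
    (two cells past the internode start).
    """
    axis = geometry.axis
    trans_axes = tuple(a for a in range(3) if a != axis)
    dx = float(cell_size)
    centers = [dims[a] * dx / 2.0 for a in range(3)]

    L = geometry.internode_length_mm * 1e-3
    z_start_cell = int(round((centers[axis] - L / 2.0) / dx - 0.5))
    k = placement.axial_index if placement.axial_index is not None else z_start_cell + 2
    if not 0 <= k < dims[axis]:
        raise PlacementError(f"axial index {k} outside grid of {dims[axis]} cells")

    def snap(a: int, coord: float) -> int:
        idx = int(round(coord / dx - 0.5))
        if not 0 <= idx < dims[a]:
            raise PlacementError("source position outside grid interior")
        return idx

    sources: list[PlacedSource] = []
    if placement.mode == "axial":
        cell = [0, 0, 0]
        cell[axis] = k
        for a in trans_axes:
            cell[a] = snap(a, centers[a])
        pol = [0.0, 0.0, 0.0]
        pol[axis] = 1.0
        sources.append(PlacedSource(tuple(cell), tuple(pol)))
        return sources

    radius_mm = (
        placement.ring_radius_mm
        if placement.ring_radius_mm is not None
        else 0.25 * (geometry.inner_diameter_mm + geometry.outer_diameter_mm)
    )
    radius = radius_mm * 1e-3
    n_sq = dims[trans_axes[0]] if dims[trans_axes[0]] == dims[trans_axes[1]] else None
    base: list[tuple[int, int]] = []
    for m in range(8):
        theta = 2.0 * np.pi * m / 8.0
        if n_sq is not None and m >= 2:
            # exact quarter-turn of the snapped base cells: keeps the ring's
            # discrete four-fold symmetry even when a position lands on a
            # cell boundary
            u_prev, v_prev = base[m - 2]
            uv = (n_sq - 1 - v_prev, u_prev)
        else:
            uv = (
                snap(trans_axes[0], centers[trans_axes[0]] + radius * math.cos(theta)),
                snap(trans_axes[1], centers[trans_axes[1]] + radius * math.sin(theta)),
            )
        base.append(uv)
        cell = [0, 0, 0]
        cell[axis] = k
        cell[trans_axes[0]], cell[trans_axes[1]] = uv
        pol = [0.0, 0.0, 0.0]
        pol[trans_axes[0]] = math.cos(theta)
        pol[trans_axes[1]] = math.sin(theta)
        sources.append(PlacedSource(tuple(cell), tuple(pol)))
    return sources
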
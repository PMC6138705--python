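"""Leapfrog Maxwell solver on the Yee lattice with lossy media and PML.

:class:`Solver` owns the update coefficients and PML accumulators for one
material grid; :class:`Simulation` adds sources, probes and monitors and
runs a complete time loop.  Both are deterministic: identical inputs
produce bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.constants import epsilon_0, mu_0

from ..errors import ConfigurationError, InstabilityError, PlacementError
from ..excitation import PlacedSource
from ..field_analysis import ProbeRecord
from ..geometry import MaterialGrid
from .grid import GridSpec
from .kernels import update_e as _update_e, update_h as _update_h
from .pml import cpml_coefficients

_E_COMPONENTS = ("Ex", "Ey", "Ez")
_H_COMPONENTS = ("Hx", "Hy", "Hz")


@dataclass
class FieldState:
    """All six Yee field components plus the current simulation time."""

    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    hx: np.ndarray
    hy: np.ndarray
    hz: np.ndarray
    time: float = 0.0
    step: int = 0

    @classmethod
    def zeros(cls, dims: tuple[int, int, int]) -> "FieldState":
        return cls(*(np.zeros(dims) for _ in range(6)))

    @property
    def e_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.ex, self.ey, self.ez

    @property
    def h_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.hx, self.hy, self.hz

    def is_finite(self) -> bool:
        return all(
            np.isfinite(f).all()
            for f in (self.ex, self.ey, self.ez, self.hx, self.hy, self.hz)
        )

    def max_abs(self) -> float:
        return max(float(np.abs(f).max()) for f in (*self.e_fields, *self.h_fields))

    def copy(self) -> "FieldState":
        return FieldState(
            self.ex.copy(), self.ey.copy(), self.ez.copy(),
            self.hx.copy(), self.hy.copy(), self.hz.copy(),
            self.time, self.step,
        )


class Solver:
    """Update coefficients + PML state for one (material grid, grid spec) pair."""

    def __init__(self, material: MaterialGrid, spec: GridSpec):
        if tuple(material.dims) != tuple(spec.dims):
            raise ConfigurationError(
                f"material dims {material.dims} do not match spec dims {spec.dims}"
            )
        if abs(material.cell_size - spec.cell_size) > 1e-12 * spec.cell_size:
            raise ConfigurationError("material and spec cell sizes differ")
        if not spec.courant_ok():
            raise ConfigurationError("grid spec violates the Courant bound")
        self.material = material
        self.spec = spec
        eps = epsilon_0 * material.eps_r
        half = material.sigma * spec.dt / (2.0 * eps)
        self.ca = (1.0 - half) / (1.0 + half)
        self.cb = (spec.dt / eps) / (1.0 + half)
        self.db = spec.dt / mu_0
        self.inv_dx = 1.0 / spec.cell_size

        coeffs = []
        for a in range(3):
            if spec.periodic[a]:
                n = spec.dims[a]
                coeffs.append(
                    (np.ones(n), np.zeros(n), np.ones(n), np.zeros(n))
                )
            else:
                coeffs.append(
                    cpml_coefficients(spec.dims[a], spec.cell_size, spec.dt, spec.pml)
                )
        (self.be_x, self.ce_x, self.bh_x, self.ch_x) = coeffs[0]
        (self.be_y, self.ce_y, self.bh_y, self.ch_y) = coeffs[1]
        (self.be_z, self.ce_z, self.bh_z, self.ch_z) = coeffs[2]
        self._psi_e = [np.zeros(spec.dims) for _ in range(6)]
        self._psi_h = [np.zeros(spec.dims) for _ in range(6)]

    def enforce_pec(self, state: FieldState) -> None:
        """Zero tangential E on non-periodic outer walls (done once at init)."""
        per = self.spec.periodic
        if not per[0]:
            for f in (state.ey, state.ez):
                f[0, :, :] = 0.0
                f[-1, :, :] = 0.0
        if not per[1]:
            for f in (state.ex, state.ez):
                f[:, 0, :] = 0.0
                f[:, -1, :] = 0.0
        if not per[2]:
            for f in (state.ex, state.ey):
                f[:, :, 0] = 0.0
                f[:, :, -1] = 0.0

    def update_h(self, state: FieldState) -> None:
        _update_h(
            state.ex, state.ey, state.ez, state.hx, state.hy, state.hz,
            self.db, self.inv_dx, *self._psi_h,
            self.bh_x, self.ch_x, self.bh_y, self.ch_y, self.bh_z, self.ch_z,
            *self.spec.periodic,
        )

    def update_e(self, state: FieldState) -> None:
        _update_e(
            state.ex, state.ey, state.ez, state.hx, state.hy, state.hz,
            self.ca, self.cb, self.inv_dx, *self._psi_e,
            self.be_x, self.ce_x, self.be_y, self.ce_y, self.be_z, self.ce_z,
            *self.spec.periodic,
        )

    def inject(self, state: FieldState, cell, axis: int, current_density: float) -> None:
        """Soft (additive current-density) source term on one E component."""
        comp = (state.ex, state.ey, state.ez)[axis]
        comp[cell] -= self.cb[cell] * current_density

    def step(
        self,
        state: FieldState,
        injections: Sequence[tuple[tuple[int, int, int], int, float]] = (),
    ) -> FieldState:
        """One leapfrog step: H to t + dt/2, then E to t + dt, then sources."""
        self.update_h(state)
        self.update_e(state)
        for cell, axis, j in injections:
            self.inject(state, cell, axis, j)
        state.time += self.spec.dt
        state.step += 1
        return state


def step_fields(state: FieldState, material: MaterialGrid, spec: GridSpec) -> FieldState:
    """Single-step convenience wrapper (builds a fresh :class:`Solver`).

    For time loops construct one :class:`Solver` and call :meth:`Solver.step`
    repeatedly so coefficients and PML accumulators persist.
    """
    return Solver(material, spec).step(state)


def em_energy(state: FieldState, material: MaterialGrid) -> float:
    """Pointwise EM energy 0.5 eps |E|^2 + 0.5 mu0 |H|^2 summed over the grid."""
    dx3 = material.cell_size**3
    eps = epsilon_0 * material.eps_r
    ue = 0.5 * float(np.sum(eps * (state.ex**2 + state.ey**2 + state.ez**2)))
    uh = 0.5 * mu_0 * float(np.sum(state.hx**2 + state.hy**2 + state.hz**2))
    return (ue + uh) * dx3

def yee_energy(
    e_fields: tuple[np.ndarray, np.ndarray, np.ndarray],
    h_before: tuple[np.ndarray, np.ndarray, np.ndarray],
    h_after: tuple[np.ndarray, np.ndarray, np.ndarray],
    material: MaterialGrid,
) -> float:
    """Leapfrog-compatible discrete energy.

    Pairs E at an integer step with the product of the bracketing H
    half-steps; this quadratic form is exactly conserved by the lossless
    PEC-bounded scheme and non-increasing when sigma >= 0.
    """
    dx3 = material.cell_size**3
    eps = epsilon_0 * material.eps_r
    ue = 0.5 * float(np.sum(eps * sum(e * e for e in e_fields)))
    uh = 0.5 * mu_0 * float(sum(np.sum(hb * ha) for hb, ha in zip(h_before, h_after)))
    return (ue + uh) * dx3


@dataclass(frozen=True)
class SourceDriver:
    """A placed source plus its waveform, scaled to a current density (A/m^2)."""

    placed: PlacedSource
    waveform: Callable[[np.ndarray], np.ndarray]
    scale: float = 1.0


@dataclass(frozen=True)
class Probe:
    cell: tuple[int, int, int]
    quantity: str = "Emag"


@dataclass
class SimulationResult:
    probes: list[ProbeRecord]
    plane_energy: list[ProbeRecord] | None
    station_maps: dict[str, np.ndarray]
    spec: GridSpec
    diagnostics: dict


class Simulation:
    """A complete run: sources, probes and monitors around a :class:`Solver`.

    ``stations`` maps labels (e.g. ``"source"``, ``"center"``, ``"output"``)
    to axial cell indices; for each one the per-pixel running maximum of |E|
    over the monitor window is collected.  ``axial_monitor=True`` records the
    transverse-plane-integrated energy density at every axial station (PML
    cells excluded from the sums) every ``monitor_stride`` steps.
    """

    def __init__(
        self,
        material: MaterialGrid,
        spec: GridSpec,
        sources: Sequence[SourceDriver] = (),
        probes: Sequence[Probe] = (),
        axial_monitor: bool = False,
        monitor_stride: int = 4,
        monitor_start: float = 0.0,
        stations: dict[str, int] | None = None,
        check_interval: int = 200,
    ):
        self.solver = Solver(material, spec)
        self.material = material
        self.spec = spec
        self.sources = list(sources)
        self.probes = list(probes)
        self.axial_monitor = axial_monitor
        self.monitor_stride = int(monitor_stride)
        self.monitor_start = float(monitor_start)
        self.stations = dict(stations or {})
        self.check_interval = int(check_interval)

        for drv in self.sources:
            self._check_interior(drv.placed.cell, "source")
        for p in self.probes:
            if p.quantity not in (*_E_COMPONENTS, *_H_COMPONENTS, "Emag"):
                raise ConfigurationError(f"unknown probe quantity {p.quantity!r}")
            self._check_interior(p.cell, "probe")
        axis = material.axis
        for label, k in self.stations.items():
            cell = [d // 2 for d in spec.dims]
            cell[axis] = k
            self._check_interior(tuple(cell), f"station {label!r}")

    def _check_interior(self, cell, what: str) -> None:
        t = self.spec.pml.thickness
        for a in range(3):
            lo = 0 if self.spec.periodic[a] else t
            hi = self.spec.dims[a] - (0 if self.spec.periodic[a] else t)
            if not lo <= cell[a] < hi:
                raise PlacementError(
                    f"{what} at {tuple(cell)} lies inside the PML/outside the grid"
                )

    # -- monitors ---------------------------------------------------------
    def _plane_energy(self, state: FieldState) -> np.ndarray:
        axis = self.material.axis
        t = self.spec.pml.thickness
        sl = [slice(None)] * 3
        for a in range(3):
            if a != axis and not self.spec.periodic[a] and t > 0:
                sl[a] = slice(t, self.spec.dims[a] - t)
        sl = tuple(sl)
        eps = epsilon_0 * self.material.eps_r[sl]
        red_axes = tuple(a for a in range(3) if a != axis)
        ue = 0.5 * np.sum(
            eps * (state.ex[sl] ** 2 + state.ey[sl] ** 2 + state.ez[sl] ** 2),
            axis=red_axes,
        )
        uh = 0.5 * mu_0 * np.sum(
            state.hx[sl] ** 2 + state.hy[sl] ** 2 + state.hz[sl] ** 2, axis=red_axes
        )
        return (ue + uh) * self.material.cell_size**3

    def _station_plane(self, state: FieldState, k: int) -> np.ndarray:
        axis = self.material.axis
        sl = [slice(None)] * 3
        sl[axis] = k
        sl = tuple(sl)
        return np.sqrt(state.ex[sl] ** 2 + state.ey[sl] ** 2 + state.ez[sl] ** 2)

    def _sample_probe(self, state: FieldState, p: Probe) -> float:
        fields = dict(zip((*_E_COMPONENTS, *_H_COMPONENTS), (*state.e_fields, *state.h_fields)))
        if p.quantity == "Emag":
            return float(
                np.sqrt(sum(fields[c][p.cell] ** 2 for c in _E_COMPONENTS))
            )
        return float(fields[p.quantity][p.cell])

    # -- main loop --------------------------------------------------------
    def run(self, steps: int | None = None) -> SimulationResult:
        n_steps = self.spec.steps if steps is None else int(steps)
        dt = self.spec.dt
        state = FieldState.zeros(self.spec.dims)

        # source current densities at half-step times
        t_half = (np.arange(n_steps) + 0.5) * dt
        drive = [
            (drv.placed.cell, drv.placed.polarization, drv.scale * np.asarray(drv.waveform(t_half)))
            for drv in self.sources
        ]

        probe_vals = np.zeros((len(self.probes), n_steps))
        plane_rows: list[np.ndarray] = []
        plane_times: list[float] = []
        station_max = {
            label: np.zeros(self._station_plane(state, k).shape)
            for label, k in self.stations.items()
        }

        for n in range(n_steps):
            injections = []
            for cell, pol, vals in drive:
                v = vals[n]
                if v == 0.0:
                    continue
                for a in range(3):
                    if pol[a] != 0.0:
                        injections.append((cell, a, pol[a] * v))
            self.solver.step(state, injections)

            for pi, p in enumerate(self.probes):
                probe_vals[pi, n] = self._sample_probe(state, p)
            in_window = state.time >= self.monitor_start
            if self.axial_monitor and in_window and n % self.monitor_stride == 0:
                plane_rows.append(self._plane_energy(state))
                plane_times.append(state.time)
            if self.stations and in_window:
                for label, k in self.stations.items():
                    np.maximum(
                        station_max[label], self._station_plane(state, k), out=station_max[label]
                    )
            if (n + 1) % self.check_interval == 0 and not state.is_finite():
                raise InstabilityError(n + 1)

        if n_steps and not state.is_finite():
            raise InstabilityError(n_steps)

        times = (np.arange(n_steps) + 1) * dt
        records = [
            ProbeRecord(location=p.cell, quantity=p.quantity, times=times, values=probe_vals[i])
            for i, p in enumerate(self.probes)
        ]
        plane_records = None
        if self.axial_monitor and plane_rows:
            rows = np.asarray(plane_rows)
            ts = np.asarray(plane_times)
            axis = self.material.axis
            plane_records = []
            for k in range(self.spec.dims[axis]):
                loc = [d // 2 for d in self.spec.dims]
                loc[axis] = k
                plane_records.append(
                    ProbeRecord(
                        location=tuple(loc),
                        quantity="plane_energy",
                        times=ts,
                        values=rows[:, k],
                    )
                )
        return SimulationResult(
            probes=records,
            plane_energy=plane_records,
            station_maps=station_max,
            spec=self.spec,
            diagnostics={
                "courant_number": self.spec.courant_number,
                "steps": n_steps,
                "final_max_abs_field": state.max_abs(),
            },
        )


def run_simulation(
    material: MaterialGrid,
    spec: GridSpec,
    sources: Sequence[SourceDriver],
    probes: Sequence[Probe],
    **kwargs,
) -> list[ProbeRecord]:
    """Run a simulation and return one :class:`ProbeRecord` per probe."""
    sim = Simulation(material, spec, sources=sources, probes=probes, **kwargs)
    return sim.run().probes
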
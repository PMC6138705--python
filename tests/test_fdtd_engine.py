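"""Grid specification, leapfrog updates, stability and analytic oracles."""
import math

import numpy as np
import pytest
from scipy.constants import c as C0, epsilon_0, mu_0

from softwg.errors import ConfigurationError, InstabilityError, PlacementError
from softwg.excitation import GaussianPulseSpec, PlacedSource, gaussian_waveform
from softwg.fdtd import (
    FieldState,
    PmlSpec,
    Probe,
    Simulation,
    Solver,
    SourceDriver,
    analytic_attenuation_constant,
    analytic_dipole_field,
    complex_wavenumber,
    dipole_field_amplitude,
    make_grid_spec,
    run_simulation,
    step_fields,
    yee_energy,
)
from softwg.fdtd.oracles import hertzian_dipole_phasor

from conftest import uniform_grid


class TestGridSpec:
    def test_default_time_step_couples_to_cell_size(self):
        spec = make_grid_spec(2e-3, (32, 32, 32), 10)
        assert spec.dt == pytest.approx(3.3356409519815207e-12, rel=1e-12)
        assert spec.dt == pytest.approx(2e-3 / (2 * C0), rel=1e-15)

    def test_courant_number_is_half_and_stable(self):
        spec = make_grid_spec(2e-3, (32, 32, 32), 10)
        assert spec.courant_number == pytest.approx(0.5)
        assert spec.courant_ok()
        assert spec.courant_number <= 1 / math.sqrt(3)

    def test_unequal_cell_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            make_grid_spec((2e-3, 1e-3, 2e-3), (32, 32, 32), 10)
        # equal tuple is fine
        assert make_grid_spec((2e-3, 2e-3, 2e-3), (32, 32, 32), 10).cell_size == 2e-3

    def test_dims_too_small_for_pml(self):
        with pytest.raises(ConfigurationError):
            make_grid_spec(2e-3, (16, 32, 32), 10, pml=PmlSpec(thickness=10))

    def test_unstable_time_step_rejected(self):
        with pytest.raises(ConfigurationError):
            make_grid_spec(2e-3, (32, 32, 32), 10, dt=2e-3 / C0)


class TestStepFields:
    def test_zero_state_is_fixed_point(self):
        dims = (20, 20, 20)
        spec = make_grid_spec(2e-3, dims, 5, pml=PmlSpec(thickness=4))
        grid = uniform_grid(dims, 2e-3, 136.0, 1.454)
        state = FieldState.zeros(dims)
        solver = Solver(grid, spec)
        for _ in range(5):
            solver.step(state)
        assert state.max_abs() == 0.0
        assert state.step == 5

    def test_step_fields_convenience_wrapper(self):
        dims = (20, 20, 20)
        spec = make_grid_spec(2e-3, dims, 1, pml=PmlSpec(thickness=4))
        grid = uniform_grid(dims, 2e-3)
        out = step_fields(FieldState.zeros(dims), grid, spec)
        assert out.time == pytest.approx(spec.dt)

    def test_vacuum_pulse_travels_at_c0(self):
        """Plane-pulse peak transit over 100 cells matches c0 within 1%."""
        dx = 2e-3
        nz = 220
        dims = (4, 4, nz)
        tau = 20 * dx / C0
        pulse = GaussianPulseSpec(tau=tau, t0=1.6 * tau)
        steps = 560
        spec = make_grid_spec(dx, dims, steps, pml=PmlSpec(thickness=10),
                              periodic=(True, True, False))
        grid = uniform_grid(dims, dx)
        drivers = [
            SourceDriver(PlacedSource((i, j, 30), (1.0, 0.0, 0.0)),
                         lambda t: gaussian_waveform(t, pulse))
            for i in range(4) for j in range(4)
        ]
        probes = [Probe((0, 0, 60), "Ex"), Probe((0, 0, 160), "Ex")]
        recs = run_simulation(grid, spec, drivers, probes)
        t_peak = []
        for rec in recs:
            i = int(np.argmax(np.abs(rec.values)))
            # parabolic sub-step interpolation around the peak
            y0, y1, y2 = np.abs(rec.values[i - 1 : i + 2])
            frac = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
            t_peak.append(rec.times[i] + frac * spec.dt)
        speed = 100 * dx / (t_peak[1] - t_peak[0])
        assert speed == pytest.approx(C0, rel=0.01)

    def test_instability_reported_with_step_index(self):
        dims = (16, 16, 16)
        spec = make_grid_spec(2e-3, dims, 30, pml=PmlSpec(thickness=0))
        grid = uniform_grid(dims, 2e-3)
        bad = SourceDriver(
            PlacedSource((8, 8, 8), (0.0, 0.0, 1.0)), lambda t: np.full_like(t, np.nan)
        )
        sim = Simulation(grid, spec, sources=[bad], check_interval=10)
        with pytest.raises(InstabilityError) as err:
            sim.run()
        assert err.value.step == 10


class TestSimulation:
    def test_identical_runs_are_bit_identical(self):
        dims = (24, 24, 40)
        dx = 2e-3
        spec = make_grid_spec(dx, dims, 60, pml=PmlSpec(thickness=6))
        grid = uniform_grid(dims, dx, 136.0, 0.487)
        pulse = GaussianPulseSpec(tau=40 * spec.dt, t0=80 * spec.dt)
        src = SourceDriver(
            PlacedSource((12, 12, 10), (0.0, 0.0, 1.0)), lambda t: gaussian_waveform(t, pulse)
        )
        probe = Probe((12, 12, 30), "Emag")
        a = run_simulation(grid, spec, [src], [probe])[0]
        b = run_simulation(grid, spec, [src], [probe])[0]
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.max() > 0

    def test_empty_source_list_gives_zero_records(self):
        dims = (20, 20, 20)
        spec = make_grid_spec(2e-3, dims, 20, pml=PmlSpec(thickness=4))
        grid = uniform_grid(dims, 2e-3)
        recs = run_simulation(grid, spec, [], [Probe((10, 10, 10), "Emag")])
        assert np.all(recs[0].values == 0.0)

    def test_probe_inside_pml_rejected(self):
        dims = (24, 24, 24)
        spec = make_grid_spec(2e-3, dims, 10, pml=PmlSpec(thickness=6))
        grid = uniform_grid(dims, 2e-3)
        with pytest.raises(PlacementError):
            Simulation(grid, spec, probes=[Probe((2, 12, 12), "Ez")])

    def test_source_inside_pml_rejected(self):
        dims = (24, 24, 24)
        spec = make_grid_spec(2e-3, dims, 10, pml=PmlSpec(thickness=6))
        grid = uniform_grid(dims, 2e-3)
        src = SourceDriver(PlacedSource((12, 12, 1), (0.0, 0.0, 1.0)), lambda t: t * 0)
        with pytest.raises(PlacementError):
            Simulation(grid, spec, sources=[src])


class TestStabilityAndEnergy:
    DIMS = (12, 12, 12)
    DX = 2e-3

    def _random_e_state(self, rng, solver):
        state = FieldState.zeros(self.DIMS)
        for f in state.e_fields:
            f[...] = rng.uniform(-1.0, 1.0, self.DIMS)
        solver.enforce_pec(state)
        return state

    def test_lossless_pec_energy_conserved_over_1e4_steps(self, rng):
        spec = make_grid_spec(self.DX, self.DIMS, 0, pml=PmlSpec(thickness=0))
        grid = uniform_grid(self.DIMS, self.DX, 1.0, 0.0)
        solver = Solver(grid, spec)
        state = self._random_e_state(rng, solver)
        m0 = state.max_abs()
        u0 = None
        for n in range(10_000):
            hb = tuple(h.copy() for h in state.h_fields) if n % 1000 == 0 else None
            solver.update_h(state)
            if hb is not None:
                u = yee_energy(state.e_fields, hb, state.h_fields, grid)
                u0 = u if u0 is None else u0
                assert u == pytest.approx(u0, rel=1e-9)
            solver.update_e(state)
        assert state.is_finite()
        # fields remain bounded (linear interference can exceed the initial
        # sup-norm, but the conserved energy caps the excursion)
        assert state.max_abs() <= 8 * m0

    def test_lossy_energy_non_increasing(self, rng):
        spec = make_grid_spec(self.DX, self.DIMS, 0, pml=PmlSpec(thickness=0))
        grid = uniform_grid(self.DIMS, self.DX, 136.0, 1.454)
        solver = Solver(grid, spec)
        state = self._random_e_state(rng, solver)
        prev = None
        first = None
        for _ in range(500):
            hb = tuple(h.copy() for h in state.h_fields)
            solver.update_h(state)
            u = yee_energy(state.e_fields, hb, state.h_fields, grid)
            if prev is not None:
                assert u <= prev * (1 + 1e-12)
            prev = u
            first = first if first is not None else u
            solver.update_e(state)
        assert prev < 0.5 * first  # conduction genuinely dissipates


class TestOracles:
    def test_attenuation_zero_conductivity(self):
        assert analytic_attenuation_constant(1e8, 136.0, 0.0) == 0.0

    def test_attenuation_good_conductor_limit(self):
        f, eps_r, sigma = 1e3, 80.0, 5.0  # sigma/(omega eps) ~ 1e6
        alpha = analytic_attenuation_constant(f, eps_r, sigma)
        assert alpha == pytest.approx(math.sqrt(math.pi * f * mu_0 * sigma), rel=0.01)

    def test_attenuation_cross_checked_against_complex_root(self):
        f = C0 / 1.44
        alpha = analytic_attenuation_constant(f, 136.0, 1.454)
        k = complex_wavenumber(f, 136.0, 1.454)
        assert alpha == pytest.approx(-k.imag, rel=1e-12)
        assert alpha == pytest.approx(21.6158, rel=1e-4)

    def test_dipole_far_field_inverse_distance(self):
        lam = 1.0
        f = C0 / lam
        a1 = dipole_field_amplitude((100 * lam, 0, 0), 1e-3, f)
        a2 = dipole_field_amplitude((200 * lam, 0, 0), 1e-3, f)
        assert a2 / a1 == pytest.approx(0.5, rel=0.01)

    def test_dipole_transverse_field_vanishes_on_axis(self):
        _, e_theta, _ = hertzian_dipole_phasor(5.0, 0.0, 1e-3, C0 / 1.0)
        assert abs(e_theta) == 0.0

    def test_far_field_impedance_is_eta0(self):
        lam = 1.0
        f = C0 / lam
        E, H = analytic_dipole_field((300 * lam, 0, 0), 1.23e-10, 1e-3, f)
        # sample at several times to catch non-zero instants
        best = 0.0
        for t in np.linspace(0, 1 / f, 17):
            E, H = analytic_dipole_field((300 * lam, 0, 0), t, 1e-3, f)
            if np.linalg.norm(H) > best:
                best = np.linalg.norm(H)
                ratio = np.linalg.norm(E) / np.linalg.norm(H)
        assert ratio == pytest.approx(math.sqrt(mu_0 / epsilon_0), rel=0.01)

    def test_observation_at_dipole_rejected(self):
        with pytest.raises(Exception):
            analytic_dipole_field((0.0, 0.0, 0.0), 0.0, 1e-3, 1e8)
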
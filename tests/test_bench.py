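"""Synthetic bench generator: determinism, generative identities, trends."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from softwg.bench import (
    BenchModelParams,
    Condition,
    generate_condition_sweep,
    generate_frequency_and_duration_sweeps,
    generate_length_sweep,
    generate_trace_pair,
)
from softwg.errors import AnalysisError, ConfigurationError
from softwg.excitation import SineSpec, SquarePulseSpec
from softwg.transmission import fit_attenuation_length, transmission_efficiency

NOISELESS = BenchModelParams(noise=0.0)


class TestParams:
    def test_l0_table_exact_at_grid_points(self):
        p = BenchModelParams()
        for dur, l0 in {1e-7: 251.0, 1e-6: 229.0, 1e-5: 131.0, 1e-4: 10.0, 1e-3: 6.1}.items():
            assert p.l0_for(dur) == pytest.approx(l0, rel=1e-12)

    def test_trend_factor_is_one_at_reference(self):
        p = BenchModelParams()
        assert p.trend_factor(2.0, 0.15) == pytest.approx(1.0)

    @given(
        st.floats(min_value=0.2, max_value=5.0),
        st.floats(min_value=0.2, max_value=5.0),
        st.floats(min_value=2e-4, max_value=2.0),
        st.floats(min_value=2e-4, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_trend_factor_monotone_and_bounded(self, t1, t2, c1, c2):
        p = BenchModelParams()
        g = p.trend_factor(t1, c1)
        assert 0.0 < g < 2.0
        if t2 >= t1:
            assert p.trend_factor(t2, c1) >= g
        if c2 >= c1:
            assert p.trend_factor(t1, c2) >= g

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            BenchModelParams(a0=1.5)
        with pytest.raises(ConfigurationError):
            BenchModelParams(noise=-0.1)

    def test_per_concentration_cutoff_table(self):
        p = BenchModelParams(fc_by_concentration={0.01: 1e4, 0.15: 5e4})
        assert p.cutoff_for(0.012) == 1e4
        assert p.cutoff_for(0.2) == 5e4


class TestDeterminism:
    def test_same_seed_reproduces_traces_bitwise(self):
        spec = SquarePulseSpec(duration=1e-5, edge_time=1e-7)
        p = BenchModelParams(seed=42)
        a = generate_trace_pair(spec, p)
        b = generate_trace_pair(spec, p)
        np.testing.assert_array_equal(a.transmitted, b.transmitted)

    def test_same_seed_reproduces_sweeps(self):
        a = generate_length_sweep(BenchModelParams(), seed=5)
        b = generate_length_sweep(BenchModelParams(), seed=5)
        assert a.frame.equals(b.frame)
        c = generate_frequency_and_duration_sweeps(BenchModelParams(), seed=5)
        d = generate_frequency_and_duration_sweeps(BenchModelParams(), seed=5)
        assert c.frame.equals(d.frame)


class TestTracePairs:
    def test_sine_well_below_cutoff_recovers_plateau(self):
        trace = generate_trace_pair(
            SineSpec(frequency=3.0),
            NOISELESS,
            Condition(length_cm=0.0, apply_trends=False),
        )
        eff = transmission_efficiency(trace).efficiency
        assert eff == pytest.approx(0.70, rel=1e-4)

    def test_long_square_pulse_keeps_plateau_shape(self):
        """A 1 ms pulse stays square: flat plateau, efficiency near A0."""
        spec = SquarePulseSpec(duration=1e-3, edge_time=1e-6)
        trace = generate_trace_pair(
            spec, NOISELESS, Condition(length_cm=0.0, apply_trends=False)
        )
        eff = transmission_efficiency(trace).efficiency
        assert eff == pytest.approx(0.70, rel=0.02)
        # plateau flatness: relative spread of the central half of the pulse
        sel = (trace.times > 0.4e-3) & (trace.times < 0.8e-3)
        plateau = trace.transmitted[sel]
        assert plateau.std() / plateau.mean() < 0.01

    def test_trace_level_matches_summary_saturation_curve(self):
        """Square pulses through the trace path agree with the closed form."""
        p = NOISELESS
        for duration in (1e-5, 3e-5, 1e-4):
            spec = SquarePulseSpec(duration=duration, edge_time=1e-7)
            trace = generate_trace_pair(spec, p, Condition(length_cm=0.0, apply_trends=False))
            eff = transmission_efficiency(trace).efficiency
            closed = p.a0 * (1 - math.exp(-duration / p.t_sat_s))
            assert eff == pytest.approx(closed, rel=0.05)

    def test_aliasing_sample_rate_rejected(self):
        spec = SquarePulseSpec(duration=1e-5, edge_time=2.5e-9)
        with pytest.raises(ConfigurationError):
            generate_trace_pair(spec, NOISELESS, sample_rate=1e6)

    def test_trace_metadata_carried(self):
        spec = SquarePulseSpec(duration=1e-5, edge_time=1e-7)
        cond = Condition(length_cm=4.0, thickness_mm=1.0, concentration_mol_l=0.1)
        trace = generate_trace_pair(spec, NOISELESS, cond)
        assert trace.length_cm == 4.0
        assert trace.duration_s == 1e-5
        assert trace.excitation == "square"


class TestSweeps:
    def test_noiseless_length_sweep_is_log_linear(self):
        ds = generate_length_sweep(NOISELESS, durations_s=(1e-5,))
        sub = ds.frame
        slope = np.polyfit(sub.length_cm, np.log(sub.efficiency), 1)[0]
        assert -1 / slope == pytest.approx(131.0, rel=1e-9)

    def test_length_sweep_monotone_trends(self):
        ds = generate_length_sweep(NOISELESS)
        f = ds.frame
        for dur, sub in f.groupby("duration_s"):
            eff = sub.sort_values("length_cm").efficiency.to_numpy()
            assert np.all(np.diff(eff) < 0)
        # longer duration -> lower efficiency at fixed length
        for length, sub in f.groupby("length_cm"):
            eff = sub.sort_values("duration_s").efficiency.to_numpy()
            assert np.all(np.diff(eff) < 0)

    def test_noisy_sweep_l0_recovered_within_interval(self):
        ds = generate_length_sweep(BenchModelParams(), durations_s=(1e-5,), seed=11)
        fit = fit_attenuation_length(ds.frame.length_cm, ds.frame.efficiency)
        lo, hi = fit.ci95
        assert lo <= 131.0 <= hi

    def test_too_few_lengths_rejected(self):
        with pytest.raises(AnalysisError):
            generate_length_sweep(NOISELESS, lengths_cm=(2.0, 4.0))

    def test_frequency_sweep_identities(self):
        p = NOISELESS
        ds = generate_frequency_and_duration_sweeps(
            p, frequencies_hz=(1e2, 1e3, 3e4, 1e6, 1e8), durations_s=(1e-3,)
        )
        f = ds.frame
        at_fc = f[(f.kind == "frequency") & (f.abscissa == 3e4)].efficiency.iloc[0]
        assert at_fc == pytest.approx(0.7 / math.sqrt(2), rel=1e-12)
        long_t = f[f.kind == "duration"].efficiency.iloc[0]
        assert long_t == pytest.approx(0.7, rel=1e-9)

    def test_response_monotonicity(self):
        ds = generate_frequency_and_duration_sweeps(NOISELESS, fine_duration_grid=True)
        f = ds.frame
        freq = f[f.kind == "frequency"].sort_values("abscissa").efficiency.to_numpy()
        assert np.all(np.diff(freq) < 0)
        dur = f[f.kind == "duration"].sort_values("abscissa").efficiency.to_numpy()
        # strictly rising until saturation closes the gap within float precision
        assert np.all(np.diff(dur) >= 0)
        assert np.all(np.diff(dur[:10]) > 0)

    def test_condition_sweep_trends(self):
        ds_t = generate_condition_sweep(NOISELESS, thicknesses_mm=(0.2, 1.0, 2.0, 5.0))
        eff_t = ds_t.frame.sort_values("value").efficiency.to_numpy()
        assert np.all(np.diff(eff_t) > 0)
        ds_c = generate_condition_sweep(
            NOISELESS, concentrations_mol_l=(2e-4, 2e-3, 2e-2, 0.2, 2.0)
        )
        eff_c = ds_c.frame.sort_values("value").efficiency.to_numpy()
        assert np.all(np.diff(eff_c) > 0)

    def test_condition_sweep_requires_exactly_one_variable(self):
        with pytest.raises(AnalysisError):
            generate_condition_sweep(NOISELESS)
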
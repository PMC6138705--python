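"""Excitation waveforms and source placement."""
import math

import numpy as np
import pytest
from scipy.constants import c as C0

from softwg.errors import ConfigurationError, PlacementError
from softwg.excitation import (
    GaussianPulseSpec,
    SineSpec,
    SourcePlacement,
    SquarePulseSpec,
    TubeGeometry,
    gaussian_waveform,
    place_sources,
    sine_waveform,
    square_waveform,
)

# exp(-4*pi*(1.92/2.40)^2) evaluated independently with sympy at 20 digits
GAUSSIAN_AT_ZERO = 3.2151151668886746e-4


class TestGaussianWaveform:
    def test_peak_at_center(self):
        spec = GaussianPulseSpec()
        assert gaussian_waveform(spec.t0, spec) == pytest.approx(1.0)

    def test_half_width_value(self):
        spec = GaussianPulseSpec()
        for sign in (-1, 1):
            val = gaussian_waveform(spec.t0 + sign * spec.tau / 2, spec)
            assert val == pytest.approx(math.exp(-math.pi), rel=1e-12)

    def test_default_value_at_time_origin(self):
        spec = GaussianPulseSpec()
        assert gaussian_waveform(0.0, spec) == pytest.approx(GAUSSIAN_AT_ZERO, rel=1e-12)

    def test_spectrum_width_matches_closed_form(self):
        """FFT -3 dB width agrees with the analytic Gaussian transform."""
        spec = GaussianPulseSpec()
        dt = spec.tau / 400
        t = np.arange(0, 16e-9, dt)
        s = np.abs(np.fft.rfft(gaussian_waveform(t, spec)))
        f = np.fft.rfftfreq(t.size, dt)
        s /= s[0]
        # one-sided -3 dB point; closed-form full width is twice that
        f3 = np.interp(-1 / math.sqrt(2), -s, f)
        assert 2 * f3 == pytest.approx(spec.bandwidth_3db(), rel=0.02)

    def test_invalid_width_rejected(self):
        with pytest.raises(ConfigurationError):
            GaussianPulseSpec(tau=0.0)


class TestSineWaveform:
    def test_zero_at_origin_and_peak_at_quarter_period(self):
        spec = SineSpec(amplitude=2.5)
        assert sine_waveform(0.0, spec) == 0.0
        assert sine_waveform(1.44 / (4 * C0), spec) == pytest.approx(2.5, rel=1e-12)

    def test_default_wavelength_frequency(self):
        assert SineSpec().f == pytest.approx(C0 / 1.44, rel=1e-15)
        assert SineSpec().f == pytest.approx(208.19e6, rel=1e-3)

    def test_frequency_override(self):
        assert SineSpec(frequency=1e6).f == 1e6

    def test_ramp_reaches_full_amplitude(self):
        spec = SineSpec(frequency=1e6)
        t = 5.25 / spec.f  # beyond a 3-period ramp, at a crest
        assert sine_waveform(t, spec, ramp_periods=3.0) == pytest.approx(1.0, rel=1e-9)
        t_in = 0.25 / spec.f
        assert abs(sine_waveform(t_in, spec, ramp_periods=3.0)) < 0.1


class TestSquareWaveform:
    def test_plateau_and_gap(self):
        spec = SquarePulseSpec(duration=1e-3, repetition_frequency=100.0)
        assert square_waveform(0.5e-3, spec) == pytest.approx(2.0)
        assert square_waveform(5e-3, spec) == 0.0

    def test_single_pulse_integral_is_trapezoid_area(self):
        spec = SquarePulseSpec(duration=1e-6, edge_time=1e-7, amplitude=2.0)
        t = np.linspace(0, 3e-6, 600_001)
        area = np.trapezoid(square_waveform(t, spec), t)
        assert area == pytest.approx(2.0 * (1e-6 - 1e-7), rel=1e-4)

    def test_fundamental_approaches_ideal_square_coefficient(self):
        """50% duty, vanishing edges: fundamental -> 4/pi * (A/2)."""
        period = 1e-3
        spec = SquarePulseSpec(
            duration=period / 2, repetition_frequency=1 / period, edge_time=1e-8, amplitude=2.0
        )
        t = np.linspace(0, period, 2_000_000, endpoint=False)
        v = square_waveform(t, spec)
        c1 = 2 * np.abs(np.mean(v * np.exp(-2j * np.pi * t / period)))
        assert c1 == pytest.approx(4 / math.pi * (2.0 / 2), rel=0.01)

    def test_duration_must_exceed_edges(self):
        with pytest.raises(ConfigurationError):
            SquarePulseSpec(duration=4e-9, edge_time=2.5e-9)

    def test_duty_cycle_below_one(self):
        with pytest.raises(ConfigurationError):
            SquarePulseSpec(duration=1e-2, repetition_frequency=100.0)


class TestPlacement:
    GEO = TubeGeometry()
    DIMS = (64, 64, 148)
    DX = 2e-3

    def test_ring_has_eight_sources_at_45_degrees(self):
        placed = place_sources(SourcePlacement(mode="ring"), self.GEO, self.DIMS, self.DX)
        assert len(placed) == 8
        angles = sorted(
            math.atan2(p.polarization[1], p.polarization[0]) % (2 * math.pi) for p in placed
        )
        gaps = np.diff(angles + [angles[0] + 2 * math.pi])
        np.testing.assert_allclose(gaps, math.pi / 4, rtol=1e-12)

    def test_ring_polarizations_sum_to_zero(self):
        placed = place_sources(SourcePlacement(mode="ring"), self.GEO, self.DIMS, self.DX)
        total = np.sum([p.polarization for p in placed], axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_ring_radius_is_mid_shell(self):
        placed = place_sources(SourcePlacement(mode="ring"), self.GEO, self.DIMS, self.DX)
        cx = self.DIMS[0] * self.DX / 2
        for p in placed:
            x = (p.cell[0] + 0.5) * self.DX - cx
            y = (p.cell[1] + 0.5) * self.DX - cx
            r = math.hypot(x, y)
            assert abs(r - 0.036) <= self.DX  # (d + D)/4 = 36 mm

    def test_ring_cells_invariant_under_quarter_turn(self):
        placed = place_sources(SourcePlacement(mode="ring"), self.GEO, self.DIMS, self.DX)
        cells = {p.cell[:2] for p in placed}
        n = self.DIMS[0]
        rotated = {(j, n - 1 - i) for i, j in cells}
        assert rotated == cells

    def test_axial_source_on_medial_axis(self):
        placed = place_sources(SourcePlacement(mode="axial"), self.GEO, self.DIMS, self.DX)
        assert len(placed) == 1
        (p,) = placed
        assert p.polarization == (0.0, 0.0, 1.0)
        assert p.cell[0] in (self.DIMS[0] // 2 - 1, self.DIMS[0] // 2)
        assert p.cell[1] in (self.DIMS[1] // 2 - 1, self.DIMS[1] // 2)

    def test_placement_outside_grid_rejected(self):
        with pytest.raises(PlacementError):
            place_sources(
                SourcePlacement(mode="axial", axial_index=10_000), self.GEO, self.DIMS, self.DX
            )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            SourcePlacement(mode="helix")
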
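"""Pulse construction, differentiation and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optocochlea.errors import GridError, InvalidParameterError, ResolutionError
from optocochlea.pulse import (PulseWaveform, apply_detector_response,
                               make_flat_top, make_gaussian,
                               period_to_frequency, power_derivative,
                               pulse_metrics, read_waveform_csv,
                               write_waveform_csv)


class TestFlatTop:
    @pytest.mark.parametrize(
        "duration,peak,rise,fall",
        [(100e-6, 0.15, 2e-6, 2e-6),   # 100 us at 150 mW -> 15 uJ
         (30e-6, 0.2, 1e-6, 1e-6),     # 30 us at 200 mW -> 6 uJ
         (5e-6, 1.2, 1e-6, 1e-6)],
    )
    def test_energy_equals_peak_times_duration(self, duration, peak, rise, fall):
        # trapezoid with plateau = duration - (rise+fall)/2 has exactly this area
        w = make_flat_top(duration, peak, rise, fall)
        assert w.energy == pytest.approx(peak * duration, rel=5e-4)

    def test_plateau_sits_at_peak_power(self):
        w = make_flat_top(100e-6, 0.15, 2e-6, 2e-6)
        assert w.P.max() == pytest.approx(0.15)
        mid = (w.t > 10e-6) & (w.t < 90e-6)
        assert np.all(w.P[mid] == pytest.approx(0.15))

    def test_fwhm_equals_nominal_duration(self):
        w = make_flat_top(30e-6, 0.2, 1e-6, 1e-6)
        assert pulse_metrics(w)["fwhm"] == pytest.approx(30e-6, rel=1e-3)

    def test_onset_at_pre_delay(self):
        w = make_flat_top(30e-6, 0.2, 1e-6, 1e-6, pre_delay=10e-6)
        assert np.all(w.P[w.t < 10e-6] == 0.0)
        assert w.P[np.searchsorted(w.t, 11.5e-6)] > 0

    @pytest.mark.parametrize("duration,peak", [(10e-6, 0.0), (-1e-6, 0.1), (2e-6, 0.1)])
    def test_invalid_parameters_raise(self, duration, peak):
        with pytest.raises(InvalidParameterError):
            make_flat_top(duration, peak, rise_time=1e-6, fall_time=1e-6)

    def test_unresolvable_edges_raise(self):
        with pytest.raises(ResolutionError):
            make_flat_top(100e-6, 0.15, rise_time=1e-6, fall_time=1e-6, dt=1e-6)


class TestGaussian:
    def test_peak_power_closed_form(self):
        # area of a Gaussian: peak * fwhm * sqrt(pi / (4 ln 2))
        fwhm, energy = 5e-9, 6e-6
        w = make_gaussian(fwhm, energy, dt=0.5e-9)
        expected_peak = energy / (fwhm * math.sqrt(math.pi / (4 * math.log(2))))
        assert w.P.max() == pytest.approx(expected_peak, rel=5e-3)

    def test_energy_normalised(self):
        w = make_gaussian(5e-9, 6e-6, dt=0.5e-9)
        assert w.energy == pytest.approx(6e-6, rel=1e-3)

    def test_fwhm_within_one_sample(self):
        w = make_gaussian(5e-9, 6e-6, dt=0.5e-9)
        assert abs(pulse_metrics(w)["fwhm"] - 5e-9) <= w.dt

    def test_zero_energy_gives_zero_waveform(self):
        w = make_gaussian(5e-9, 0.0, dt=0.5e-9)
        assert np.all(w.P == 0.0)

    def test_linearity_in_energy(self):
        w1 = make_gaussian(5e-9, 3e-6, dt=0.5e-9)
        w2 = make_gaussian(5e-9, 6e-6, dt=0.5e-9)
        np.testing.assert_allclose(w2.P, 2.0 * w1.P, rtol=1e-12)

    def test_under_resolved_fwhm_raises(self):
        with pytest.raises(ResolutionError):
            make_gaussian(1e-9, 1e-6, dt=1e-9)


class TestPowerDerivative:
    def test_constant_power_zero_slope(self):
        t = np.linspace(0, 1e-3, 101)
        d = power_derivative(PulseWaveform(t, np.full_like(t, 0.5)))
        np.testing.assert_allclose(d.dPdt, 0.0, atol=1e-12)

    def test_linear_ramp_recovers_slope(self):
        t = np.linspace(0, 1e-3, 101)
        d = power_derivative(PulseWaveform(t, 7.0 * t))
        np.testing.assert_allclose(d.dPdt[1:-1], 7.0, rtol=1e-9)

    def test_flat_top_extrema_at_edges(self):
        w = make_flat_top(100e-6, 0.15, rise_time=2e-6, fall_time=2e-6)
        d = power_derivative(w)
        assert d.max_dPdt == pytest.approx(0.15 / 2e-6, rel=0.02)
        assert d.min_dPdt == pytest.approx(-0.15 / 2e-6, rel=0.02)
        assert w.t[np.argmax(d.dPdt)] < 2.5e-6           # inside the rise
        assert 98e-6 < w.t[np.argmin(d.dPdt)] < 103e-6   # inside the fall

    def test_derivative_integrates_to_zero(self):
        w = make_flat_top(100e-6, 0.15, 2e-6, 2e-6)
        d = power_derivative(w)
        residual = np.trapezoid(d.dPdt, w.t)
        assert abs(residual) < 1e-6 * d.max_dPdt

    def test_non_uniform_grid_raises(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(GridError):
            power_derivative(PulseWaveform(t, np.zeros_like(t)))


class TestMetrics:
    def test_symmetric_pulse_has_antisymmetric_extrema(self):
        m = pulse_metrics(make_flat_top(50e-6, 0.1, 2e-6, 2e-6))
        assert m["max_dPdt"] == pytest.approx(-m["min_dPdt"], rel=1e-6)

    def test_constant_peak_power_shares_max_slope(self):
        # fixed plateau power and rise time -> identical max dP/dt at any duration
        slopes = [pulse_metrics(make_flat_top(d, 0.15))["max_dPdt"]
                  for d in (1e-4, 1e-3, 1e-2)]
        assert max(slopes) == pytest.approx(min(slopes), rel=1e-9)

    def test_constant_energy_max_slope_decreases_with_duration(self):
        durations = [1e-5, 3e-5, 1e-4, 3e-4]
        slopes = [pulse_metrics(make_flat_top(d, 6e-6 / d))["max_dPdt"]
                  for d in durations]
        assert all(a > b for a, b in zip(slopes, slopes[1:]))

    def test_all_zero_waveform_fwhm_is_nan(self):
        t = np.linspace(0, 1e-3, 51)
        m = pulse_metrics(PulseWaveform(t, np.zeros_like(t)))
        assert math.isnan(m["fwhm"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(duration=st.floats(1e-5, 1e-3), peak=st.floats(1e-3, 10.0))
    def test_energy_matches_quadrature(self, duration, peak):
        w = make_flat_top(duration, peak)
        assert pulse_metrics(w)["energy"] == pytest.approx(
            np.trapezoid(w.P, w.t), rel=1e-12)


class TestPeriodToFrequency:
    @pytest.mark.parametrize("interval,freq",
                             [(80e-6, 12.5e3), (125e-6, 8e3), (1.0, 1.0)])
    def test_examples(self, interval, freq):
        assert period_to_frequency(interval) == pytest.approx(freq)

    @pytest.mark.parametrize("bad", [0.0, -1e-6])
    def test_non_positive_interval_raises(self, bad):
        with pytest.raises(InvalidParameterError):
            period_to_frequency(bad)


def test_csv_round_trip(tmp_path):
    w = make_flat_top(30e-6, 0.2, 1e-6, 1e-6)
    path = tmp_path / "pulse.csv"
    write_waveform_csv(w, path)
    assert path.read_text().splitlines()[0] == "time_s,power_W"
    back = read_waveform_csv(path)
    np.testing.assert_allclose(back.P, w.P)
    np.testing.assert_allclose(back.t, w.t)


def test_detector_response_rise_time():
    # step through a 25 ns first-order filter: 10-90% rise ~ 25 ns
    t = np.arange(0, 2e-6, 1e-9)
    step = PulseWaveform(t, np.where(t > 0.5e-6, 1.0, 0.0))
    filtered = apply_detector_response(step, rise_time=25e-9)
    t10 = t[np.argmax(filtered.P >= 0.1)]
    t90 = t[np.argmax(filtered.P >= 0.9)]
    assert (t90 - t10) == pytest.approx(25e-9, rel=0.15)
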
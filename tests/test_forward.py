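"""Acoustic forward solver: source building, wave propagation, measurement."""

import math

import numpy as np
import pytest

from optocochlea.confinement import WATER, MediumProperties
from optocochlea.errors import InvalidParameterError, ResolutionError
from optocochlea.forward import (FieldPoint, PressureTrace,
                                 apply_measurement_chain, build_heating_source,
                                 build_spherical_source, extrema_interval,
                                 initial_pressure, pressure_at_point,
                                 read_trace_csv, spl_re_1uPa, write_trace_csv)
from optocochlea.pulse import PulseWaveform, make_flat_top, make_gaussian

R_FIBER = 52.5e-6


class TestHeatingSource:
    def test_absorbed_fraction_conservation(self, source_mu10):
        # sum(A_e dV) = 1 - exp(-mu_a L) to well under 0.5%
        mu_m = 10.0 * 100.0
        expected = 1.0 - math.exp(-mu_m * source_mu10.axial_extent)
        assert source_mu10.absorbed_fraction() == pytest.approx(expected, rel=5e-3)

    def test_absorbed_fraction_at_5mm_cutoff(self):
        src = build_heating_source(R_FIBER, 10.0, axial_cutoff=5e-3)
        assert src.absorbed_fraction() == pytest.approx(0.993, abs=0.001)

    def test_absorbed_fraction_below_one(self, source_mu10):
        assert source_mu10.absorbed_fraction() < 1.0

    def test_surface_density_proportional_to_mu_a(self):
        lo = build_heating_source(R_FIBER, 10.0, axial_cutoff=5e-3)
        hi = build_heating_source(R_FIBER, 20.0, axial_cutoff=5e-3)
        assert hi.surface_density() == pytest.approx(
            2.0 * lo.surface_density(), rel=0.02)

    def test_axial_decay_monotone(self, source_mu10):
        on_axis = source_mu10.A_e[source_mu10.r == source_mu10.r.min()]
        assert np.all(np.diff(on_axis) <= 0)

    def test_too_coarse_resolution_raises(self):
        with pytest.raises(ResolutionError):
            build_heating_source(R_FIBER, 10.0, voxels_per_scale=4)

    def test_too_short_cutoff_raises(self):
        with pytest.raises(InvalidParameterError):
            build_heating_source(R_FIBER, 10.0, axial_cutoff=1e-4)


class TestInitialPressure:
    def test_product(self):
        assert initial_pressure(1e6, 0.11) == pytest.approx(1.1e5)
        assert initial_pressure(0.0, 0.11) == 0.0

    def test_grueneisen_identity_cross_check(self):
        medium = MediumProperties()
        gamma = medium.grueneisen_from_constants()
        assert initial_pressure(1e6, gamma) == pytest.approx(
            initial_pressure(1e6, medium.grueneisen), rel=0.05)


def _sphere_oracle(trace_t, pulse, radius, d_obs, medium):
    """Closed-form N-wave of a uniformly heated sphere, convolved with P(t)/E.

    Independent of the solver: for a temporal delta the outgoing wave at
    distance d from the center is p0 (d - c t)/(2 d) on |d - c t| < a with
    p0 = Gamma E / V; a finite pulse convolves that with P(t)/E.
    """
    c, G = medium.c, medium.grueneisen
    E = pulse.energy
    V = 4.0 / 3.0 * math.pi * radius**3
    p0 = G * E / V
    dt = trace_t[1] - trace_t[0]
    tt = np.arange(trace_t.size) * dt
    p_delta = np.where(np.abs(d_obs - c * tt) < radius,
                       p0 * (d_obs - c * tt) / (2.0 * d_obs), 0.0)
    P_norm = np.interp(trace_t, pulse.t, pulse.P, right=0.0) / E
    return np.convolve(P_norm, p_delta)[: trace_t.size] * dt


class TestWavePropagation:
    def test_matches_heated_sphere_n_wave(self, water):
        a, depth, d_obs = 0.2e-3, 0.6e-3, 2.0e-3
        src = build_spherical_source(a, depth, voxel_size=a / 50)
        pulse = make_gaussian(20e-9, 6e-6, dt=1e-9)
        trace = pressure_at_point(src, pulse, FieldPoint(depth + d_obs), water)
        exact = _sphere_oracle(trace.t, pulse, a, d_obs, water)
        err = np.max(np.abs(trace.p - exact)) / np.max(np.abs(exact))
        assert err < 0.03

    def test_flat_top_polarity_and_interval(self, source_mu10, water):
        duration = 100e-6
        pulse = make_flat_top(duration, 6e-6 / duration)
        trace = pressure_at_point(source_mu10, pulse, FieldPoint(1e-4), water)
        onset, offset = trace.peak_positive, trace.peak_negative
        assert onset > 0 and offset < 0
        # onset leads: positive extremum at the rise, negative at the fall
        assert trace.t[np.argmax(trace.p)] < trace.t[np.argmin(trace.p)]
        assert abs(extrema_interval(trace) - duration) <= 2 * trace.dt

    def test_plateau_is_silent(self, source_mu10, water):
        # constant heating radiates nothing: |p| < 1% of peak mid-pulse
        duration = 200e-6
        pulse = make_flat_top(duration, 6e-6 / duration)
        trace = pressure_at_point(source_mu10, pulse, FieldPoint(1e-4), water)
        mid = (trace.t > 50e-6) & (trace.t < 150e-6)
        assert np.max(np.abs(trace.p[mid])) < 0.01 * trace.peak_abs

    def test_linearity_in_pulse_energy(self, source_mu10, water):
        p1 = pressure_at_point(source_mu10, make_gaussian(1e-6, 3e-6),
                               FieldPoint(1e-3), water)
        p2 = pressure_at_point(source_mu10, make_gaussian(1e-6, 6e-6),
                               FieldPoint(1e-3), water)
        np.testing.assert_allclose(p2.p, 2.0 * p1.p, rtol=1e-9, atol=1e-12)

    def test_time_shift_equivariance(self, source_mu10, water):
        pulse = make_gaussian(1e-6, 6e-6, dt=20e-9)
        delay = 200 * 20e-9
        shifted = make_gaussian(1e-6, 6e-6, dt=20e-9, pre_delay=delay)
        tr0 = pressure_at_point(source_mu10, pulse, FieldPoint(1e-3), water)
        tr1 = pressure_at_point(source_mu10, shifted, FieldPoint(1e-3), water)
        k = int(round(delay / tr0.dt))
        n = min(tr0.p.size, tr1.p.size - k)
        np.testing.assert_allclose(tr1.p[k:k + n], tr0.p[:n],
                                   rtol=1e-6, atol=1e-9 * tr0.peak_abs)

    def test_far_field_inverse_distance_decay(self, water):
        src = build_heating_source(R_FIBER, 100.0)
        pulse = make_gaussian(1e-6, 6e-6, dt=20e-9)
        products = []
        for d in (5e-3, 15e-3, 50e-3):
            tr = pressure_at_point(src, pulse, FieldPoint(d), water)
            products.append(tr.peak_abs * d)
        ref = products[0]
        assert all(abs(p - ref) / ref < 0.05 for p in products)

    def test_near_field_flagged(self, source_mu10, water):
        pulse = make_flat_top(30e-6, 0.2)
        inside = pressure_at_point(source_mu10, pulse, FieldPoint(1e-4), water)
        outside = pressure_at_point(source_mu10, pulse, FieldPoint(20e-3), water)
        assert inside.meta["near_field"] is True
        assert outside.meta["near_field"] is False

    def test_under_resolved_rise_raises(self, source_mu10, water):
        t = np.arange(0, 50e-6, 1e-6)
        P = np.interp(t, [0, 2e-6, 30e-6, 32e-6, 50e-6], [0, 0.2, 0.2, 0, 0])
        with pytest.raises(ResolutionError):
            pressure_at_point(source_mu10, PulseWaveform(t, P),
                              FieldPoint(1e-4), water)

    def test_lateral_offset_supported(self, source_mu10, water):
        pulse = make_flat_top(30e-6, 0.2)
        tr = pressure_at_point(source_mu10, pulse,
                               FieldPoint(0.0, 1e-4), water)
        assert tr.peak_abs > 0


class TestMeasurementChain:
    def _tone(self, freq, fs=2e6, span=5e-3):
        t = np.arange(0.0, span, 1.0 / fs)
        return PressureTrace(t, np.sin(2 * math.pi * freq * t))

    def test_passband_tone_preserved(self):
        out = apply_measurement_chain(self._tone(5e3))
        mid = out.p[out.p.size // 4: -out.p.size // 4]
        amplitude = math.sqrt(2.0) * np.sqrt(np.mean(mid**2))
        assert amplitude == pytest.approx(1.0, rel=0.01)

    def test_click_peak_reduced_but_timing_kept(self):
        fs = 20e6
        t = np.arange(0.0, 2e-3, 1.0 / fs)
        t0 = 1e-3
        click = np.exp(-0.5 * ((t - t0) / 2e-6) ** 2)
        click -= click.mean()
        out = apply_measurement_chain(PressureTrace(t, click))
        assert out.peak_abs < 1.0
        t_peak = out.t[np.argmax(out.p)]
        assert abs(t_peak - t0) <= 1.0 / 102e3

    def test_resampling_band_limited_trace_consistent(self):
        out1 = apply_measurement_chain(self._tone(5e3))
        out2 = apply_measurement_chain(self._tone(5e3), sampling_rate=51e3)
        p1 = np.interp(out2.t, out1.t, out1.p)
        np.testing.assert_allclose(p1, out2.p, atol=0.02)

    def test_invalid_rates_raise(self):
        tone = self._tone(5e3, fs=2e5)
        with pytest.raises(InvalidParameterError):
            apply_measurement_chain(tone, sampling_rate=4e5)
        with pytest.raises(InvalidParameterError):
            apply_measurement_chain(tone, bandwidth=1.5e5)


class TestSPL:
    @pytest.mark.parametrize("pressure,db", [
        (1e-6, 0.0), (100.0, 160.0), (3.1623, 130.0)])
    def test_reference_values(self, pressure, db):
        assert spl_re_1uPa(pressure) == pytest.approx(db, abs=0.01)

    def test_non_positive_pressure_raises(self):
        with pytest.raises(InvalidParameterError):
            spl_re_1uPa(0.0)


def test_trace_csv_round_trip(tmp_path):
    t = np.linspace(0, 1e-3, 101)
    trace = PressureTrace(t, np.sin(1e4 * t))
    path = tmp_path / "trace.csv"
    write_trace_csv(trace, path)
    back = read_trace_csv(path)
    np.testing.assert_allclose(back.p, trace.p)
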
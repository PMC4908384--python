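"""Laser pulse temporal profiles and their numerical time derivative.

The optoacoustic source term is driven by the first time derivative of the
optical power P(t): a flat-top pulse radiates one pressure transient at its
rising edge and one of opposite sign at its falling edge, while the constant
plateau radiates nothing.  This module builds the two pulse families used
throughout the package (flat-top pulses of adjustable duration, and
nanosecond Gaussian pulses), differentiates them the same way a measured
photodiode trace would be differentiated (mean of forward and backward
difference), and extracts the scalar metrics the parameter sweeps need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError, InvalidParameterError, ResolutionError

__all__ = [
    "PulseWaveform",
    "DerivativeTrace",
    "make_flat_top",
    "make_gaussian",
    "power_derivative",
    "pulse_metrics",
    "period_to_frequency",
    "apply_detector_response",
    "read_waveform_csv",
    "write_waveform_csv",
]

_GRID_RTOL = 1e-6


@dataclass
class PulseWaveform:
    """Sampled optical power versus time on a uniform grid.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing and uniform.
    P : ndarray
        Optical power in watts, non-negative, zero at both record ends.
    meta : dict
        Free-form provenance (label, nominal duration / energy, ...).
    """

    t: np.ndarray
    P: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.P.shape:
            raise GridError("t and P must be 1-D arrays of equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0:
                raise GridError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def energy(self) -> float:
        """Pulse energy in joules (trapezoid quadrature)."""
        return float(np.trapezoid(self.P, self.t))

    def has_uniform_grid(self, rtol: float = _GRID_RTOL) -> bool:
        steps = np.diff(self.t)
        return bool(np.all(np.abs(steps - steps[0]) <= rtol * steps[0]))


@dataclass
class DerivativeTrace:
    """Numerical dP/dt on the same grid as the source waveform."""

    t: np.ndarray
    dPdt: np.ndarray
    max_dPdt: float = 0.0
    min_dPdt: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dPdt = np.asarray(self.dPdt, dtype=float)
        self.max_dPdt = float(self.dPdt.max()) if self.dPdt.size else 0.0
        self.min_dPdt = float(self.dPdt.min()) if self.dPdt.size else 0.0


def _default_dt(duration: float, edge: float) -> float:
    # resolve both the overall envelope and the fastest edge; 1 ns floor
    return max(1e-9, min(duration / 1000.0, edge / 20.0))


def make_flat_top(
    duration: float,
    peak_power: float,
    rise_time: float = 1e-6,
    fall_time: float = 1e-6,
    dt: float | None = None,
    pre_delay: float = 0.0,
    tail: float | None = None,
) -> PulseWaveform:
    """Trapezoidal "flat-top" pulse of a given FWHM duration.

    The plateau sits at ``peak_power``; the linear rise starts at
    ``pre_delay``.  The plateau length is chosen as
    ``duration - (rise_time + fall_time)/2`` so that both the full width at
    half maximum and the energy ``peak_power * duration`` come out exact for
    the ideal trapezoid.

    Parameters are in SI units (seconds, watts).
    """
    if duration <= 0 or peak_power <= 0:
        raise InvalidParameterError("duration and peak_power must be positive")
    if rise_time <= 0 or fall_time <= 0:
        raise InvalidParameterError("rise_time and fall_time must be positive")
    if duration <= rise_time + fall_time:
        raise InvalidParameterError("duration must exceed rise_time + fall_time")
    if pre_delay < 0:
        raise InvalidParameterError("pre_delay must be non-negative")
    if dt is None:
        dt = _default_dt(duration, min(rise_time, fall_time))
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if rise_time < 2 * dt or fall_time < 2 * dt:
        raise ResolutionError("dt too coarse to resolve the rise/fall edges")

    plateau = duration - 0.5 * (rise_time + fall_time)
    t_on = pre_delay
    t_plateau = t_on + rise_time
    t_fall = t_plateau + plateau
    t_off = t_fall + fall_time
    if tail is None:
        tail = max(2 * dt, 0.02 * duration)
    n = int(math.ceil((t_off + tail) / dt)) + 1
    t = np.arange(n) * dt
    P = np.interp(t, [0.0, t_on, t_plateau, t_fall, t_off],
                  [0.0, 0.0, peak_power, peak_power, 0.0])
    P[t >= t_off] = 0.0
    meta = {
        "label": "flat_top",
        "nominal_duration_s": duration,
        "nominal_energy_J": peak_power * duration,
        "peak_power_W": peak_power,
        "rise_time_s": rise_time,
        "fall_time_s": fall_time,
        "pre_delay_s": pre_delay,
    }
    return PulseWaveform(t, P, meta)


def make_gaussian(
    fwhm: float,
    energy: float,
    dt: float | None = None,
    pre_delay: float = 0.0,
    tail: float | None = None,
) -> PulseWaveform:
    """Gaussian pulse of given FWHM and integral energy.

    Models Q-switched/OPO nanosecond pulses.  The sampled trace is
    renormalised by trapezoid quadrature so its energy matches ``energy``
    to machine precision; ``energy = 0`` returns an all-zero record.
    """
    if fwhm <= 0:
        raise InvalidParameterError("fwhm must be positive")
    if energy < 0:
        raise InvalidParameterError("energy must be non-negative")
    if dt is None:
        dt = max(1e-12, fwhm / 50.0)
    if fwhm < 2 * dt:
        raise ResolutionError("fwhm must be at least 2 samples (fwhm >= 2*dt)")
    half_span = 4.0 * fwhm  # exp(-4 ln2 * 16) ~ 1e-20: effectively zero
    t0 = pre_delay + half_span
    if tail is None:
        tail = 2 * dt
    n = int(math.ceil((t0 + half_span + tail) / dt)) + 1
    t = np.arange(n) * dt
    if energy == 0.0:
        P = np.zeros_like(t)
    else:
        sigma2 = fwhm**2 / (8.0 * math.log(2.0))
        P = np.exp(-0.5 * (t - t0) ** 2 / sigma2)
        P *= energy / np.trapezoid(P, t)
    meta = {
        "label": "gaussian",
        "nominal_duration_s": fwhm,
        "nominal_energy_J": energy,
        "center_s": t0,
        "pre_delay_s": pre_delay,
    }
    return PulseWaveform(t, P, meta)


def power_derivative(w: PulseWaveform) -> DerivativeTrace:
    """dP/dt as the mean of forward and backward differences.

    At interior samples the mean of forward and backward difference equals
    the central difference; the two record endpoints use the one-sided
    difference.  Requires a uniform grid with at least three samples.
    """
    if w.t.size < 3:
        raise GridError("need at least 3 samples to differentiate")
    if not w.has_uniform_grid():
        raise GridError("power_derivative requires a uniform time grid")
    dPdt = np.gradient(w.P, w.dt)
    return DerivativeTrace(w.t, dPdt)


def _fwhm(t: np.ndarray, P: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation at the crossings."""
    peak = P.max()
    if peak <= 0:
        return math.nan
    half = 0.5 * peak
    above = P >= half
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    # leading crossing
    if i0 == 0:
        t_lead = t[0]
    else:
        f = (half - P[i0 - 1]) / (P[i0] - P[i0 - 1])
        t_lead = t[i0 - 1] + f * (t[i0] - t[i0 - 1])
    # trailing crossing
    if i1 == len(P) - 1:
        t_trail = t[-1]
    else:
        f = (P[i1] - half) / (P[i1] - P[i1 + 1])
        t_trail = t[i1] + f * (t[i1 + 1] - t[i1])
    return float(t_trail - t_lead)


def pulse_metrics(w: PulseWaveform) -> dict:
    """Scalar pulse descriptors: energy, peak power, FWHM, dP/dt extrema.

    FWHM is measured at half of the peak power with linear interpolation
    between samples; an all-zero waveform yields ``fwhm = nan``.
    """
    d = power_derivative(w)
    return {
        "energy": w.energy,
        "peak_power": float(w.P.max()),
        "fwhm": _fwhm(w.t, w.P),
        "max_dPdt": d.max_dPdt,
        "min_dPdt": d.min_dPdt,
    }


def period_to_frequency(interval: float) -> float:
    """Frequency (Hz) of an excitation period: 80 us -> 12.5 kHz."""
    if interval <= 0:
        raise InvalidParameterError("interval must be positive")
    return 1.0 / interval


def apply_detector_response(w: PulseWaveform, rise_time: float = 25e-9) -> PulseWaveform:
    """First-order low-pass emulating a photodiode of given 10-90% rise time.

    The time constant is ``rise_time / ln 9``; applied causally with a
    one-pole recursive filter, as a real detector would.
    """
    if rise_time <= 0:
        raise InvalidParameterError("rise_time must be positive")
    from scipy.signal import lfilter

    tau = rise_time / math.log(9.0)
    alpha = w.dt / (tau + w.dt)
    y = lfilter([alpha], [1.0, alpha - 1.0], w.P)
    meta = dict(w.meta)
    meta["detector_rise_s"] = rise_time
    return PulseWaveform(w.t.copy(), y, meta)


def write_waveform_csv(w: PulseWaveform, path) -> None:
    """Write a two-column CSV (time_s, power_W) with a header line."""
    pd.DataFrame({"time_s": w.t, "power_W": w.P}).to_csv(path, index=False)


def read_waveform_csv(path, detector_rise: float | None = None) -> PulseWaveform:
    """Read a (time_s, power_W) CSV; optionally apply the detector response."""
    df = pd.read_csv(path)
    for col in ("time_s", "power_W"):
        if col not in df.columns:
            raise GridError(f"waveform CSV must have a header with column '{col}'")
    w = PulseWaveform(df["time_s"].to_numpy(), df["power_W"].to_numpy(),
                      {"label": "from_csv"})
    if detector_rise is not None:
        w = apply_detector_response(w, detector_rise)
    return w
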
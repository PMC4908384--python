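"""Seeded synthetic measurements emulating the study's raw data.

Three measurement channels are emulated so that every analysis stage can be
exercised without any recorded data: photodiode power traces (band-limited
by the detector's 25 ns rise time), hydrophone recordings (noisy single
shots averaged over many laser pulses), and spectrometer ink-dilution
series (transmission with multiplicative noise, opaque dilutions flagged as
outside the measurement range).

Every generator is a pure function of its parameters and an integer seed.
A single `NoiseSpec.seed` feeds one `numpy` Generator per call; replicate
averaging draws replicates sequentially from that stream, so outputs are
bit-reproducible for fixed (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .forward import PressureTrace
from .pulse import PulseWaveform, apply_detector_response

__all__ = [
    "NoiseSpec",
    "generate_photodiode_trace",
    "generate_hydrophone_recording",
    "generate_ink_series",
    "STUDY_INK_CONCENTRATIONS",
    "DEFAULT_INK_SLOPE",
    "WATER_MU_A_1300NM",
    "TRANSMISSION_FLOOR",
]

#: ink dilution ladder used in the study, % v/v
STUDY_INK_CONCENTRATIONS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0)
#: cm^-1 per % ink: takes pure water (1.34 cm^-1) to ~77 cm^-1 at 5%
DEFAULT_INK_SLOPE = 15.13
#: cm^-1, pure water at 1300 nm
WATER_MU_A_1300NM = 1.34
#: transmissions below this are unmeasurable and flagged for extrapolation
TRANSMISSION_FLOOR = 1e-4


@dataclass
class NoiseSpec:
    """Noise/averaging description for a synthetic measurement.

    ``sigma`` is the single-shot noise standard deviation in the units of
    the signal it applies to (watts for photodiode traces, pascals for
    hydrophone traces, relative for transmission).
    """

    sigma: float = 0.0
    seed: int = 0
    n_averages: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be non-negative")
        if self.n_averages < 1:
            raise InvalidParameterError("n_averages must be >= 1")


def generate_photodiode_trace(
    pulse: PulseWaveform,
    noise: NoiseSpec,
    detector_rise: float = 25e-9,
) -> PulseWaveform:
    """Detector view of an ideal pulse: 25 ns first-order rise, plus noise."""
    filtered = apply_detector_response(pulse, detector_rise)
    if noise.sigma == 0:
        return filtered
    rng = np.random.default_rng(noise.seed)
    P = filtered.P + rng.normal(0.0, noise.sigma, filtered.P.shape)
    meta = dict(filtered.meta)
    meta.update({"noise_sigma_W": noise.sigma, "seed": noise.seed})
    return PulseWaveform(filtered.t, P, meta)


def generate_hydrophone_recording(
    true_trace: PressureTrace,
    noise: NoiseSpec,
    chunk: int = 256,
) -> PressureTrace:
    """Average of ``n_averages`` independent noisy shots of a true trace.

    Residual noise falls as sigma / sqrt(n_averages); shots are drawn
    sequentially from one seeded stream (in chunks, which does not change
    the draw order).
    """
    if noise.sigma == 0 and noise.n_averages >= 1:
        if noise.n_averages == 1:
            return true_trace
    rng = np.random.default_rng(noise.seed)
    n = true_trace.p.size
    acc = np.zeros(n)
    remaining = noise.n_averages
    while remaining > 0:
        m = min(chunk, remaining)
        acc += rng.normal(0.0, noise.sigma, (m, n)).sum(axis=0)
        remaining -= m
    p = true_trace.p + acc / noise.n_averages
    meta = dict(true_trace.meta)
    meta.update({"noise_sigma_Pa": noise.sigma, "n_averages": noise.n_averages,
                 "seed": noise.seed})
    return PressureTrace(true_trace.t, p, meta)


def generate_ink_series(
    concentrations=STUDY_INK_CONCENTRATIONS,
    slope: float = DEFAULT_INK_SLOPE,
    intercept: float = WATER_MU_A_1300NM,
    pathlength: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Spectrometer transmission series for an ink dilution ladder.

    mu_a = slope * c + intercept (cm^-1), transmission = exp(-mu_a * L)
    with multiplicative noise of relative sigma ``noise.sigma``.  Dilutions
    whose (noisy) transmission falls below the measurement floor are
    flagged ``outside_range`` -- their mu_a must be obtained by linear
    extrapolation of the calibration fit, not from Lambert-Beer inversion.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("concentrations must be non-negative")
    if pathlength <= 0:
        raise InvalidParameterError("pathlength must be positive")
    mu_true = slope * c + intercept
    T = np.exp(-mu_true * pathlength)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        T = T * (1.0 + rng.normal(0.0, noise.sigma, T.shape))
        T = np.clip(T, 1e-300, None)
    return pd.DataFrame({
        "concentration_pct": c,
        "mu_a_true_cm1": mu_true,
        "transmission": T,
        "pathlength_cm": pathlength,
        "outside_range": T < TRANSMISSION_FLOOR,
    })
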
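"""The four parameter studies: scripted sweeps over the study conditions.

Each sweep simulates, per grid point, the full chain: laser pulse ->
Beer-Lambert heating source -> retarded-time pressure at the hydrophone
point -> 100 kHz / 102 kHz measurement chain -> shot-averaged noisy
recording -> CAP surrogate.  Results are tabulated one row per sweep point
with derived diagnostics (derivative-law regression, onset-amplitude
constancy, absorption-curve argmax) attached as ``info``.

Sweeps:
  1. constant pulse energy (6 uJ), duration 5 ns - 400 us;
  2. constant plateau power (150 mW), duration 10 us - 10 ms;
  3./4. absorption coefficient 1.34 - 124 cm^-1 at fixed 6 uJ nanosecond
     pulses (wavelength- or ink-controlled; the solver only sees mu_a).
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .absorption import calibrate_from_series
from .cap import cap_response, merge_threshold
from .confinement import MediumProperties, classify_regime, source_geometry_class
from .config import ExperimentConfig, load_config, save_config
from .errors import ConfigError
from .forward import (FieldPoint, apply_measurement_chain, build_heating_source,
                      extrema_interval, pressure_at_point, spl_re_1uPa)
from .pulse import PulseWaveform, make_flat_top, make_gaussian, pulse_metrics
from .synthetic import NoiseSpec, generate_hydrophone_recording, generate_ink_series

log = logging.getLogger("optocochlea")

__all__ = [
    "SweepResult",
    "sweep_constant_energy",
    "sweep_constant_power",
    "sweep_absorption",
    "run_all",
    "simulate_reference_spl",
]

#: FWHM of the nanosecond (OPO) pulses used for the absorption studies, s
NS_PULSE_FWHM = 4e-9


@dataclass
class SweepResult:
    """One row per sweep point plus sweep-level diagnostics."""

    table: pd.DataFrame
    info: dict = field(default_factory=dict)


def _point_seed(base_seed: int, sweep_id: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(sweep_id), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _make_sweep_pulse(duration: float, *, energy: float | None = None,
                      peak_power: float | None = None,
                      cfg: ExperimentConfig) -> PulseWaveform:
    """Pulse for a sweep point: flat-top when the edges fit, else Gaussian.

    Sub-edge durations correspond to the Q-switched laser and are modelled
    as Gaussian pulses of that FWHM.
    """
    edges = cfg.rise_time_s + cfg.fall_time_s
    if duration > edges:
        if peak_power is None:
            peak_power = energy / duration
        return make_flat_top(duration, peak_power, cfg.rise_time_s,
                             cfg.fall_time_s)
    if energy is None:
        energy = peak_power * duration
    return make_gaussian(duration, energy)


def _simulate_point(pulse: PulseWaveform, mu_a: float, cfg: ExperimentConfig,
                    seed: int, source_cache: dict) -> dict:
    key = (round(mu_a, 9), cfg.voxels_per_scale, cfg.fiber_radius_m)
    if key not in source_cache:
        source_cache[key] = build_heating_source(
            cfg.fiber_radius_m, mu_a, voxels_per_scale=cfg.voxels_per_scale)
    source = source_cache[key]
    medium = MediumProperties(grueneisen=cfg.grueneisen, mu_a=mu_a)
    fieldpt = FieldPoint(cfg.distance_m, cfg.lateral_offset_m)

    metrics = pulse_metrics(pulse)
    trace = pressure_at_point(source, pulse, fieldpt, medium)
    measured = apply_measurement_chain(trace, cfg.bandwidth_hz, cfg.sampling_hz)
    noise = NoiseSpec(cfg.hydrophone_sigma_pa, seed, cfg.n_averages)
    recording = generate_hydrophone_recording(measured, noise)
    cap = cap_response(recording, cfg.cap_integration_time_s,
                       tuple(cfg.cap_band_hz))
    report = classify_regime(metrics["fwhm"], mu_a, cfg.fiber_radius_m, medium)
    residual_sigma = cfg.hydrophone_sigma_pa / math.sqrt(cfg.n_averages)
    detection_floor = 3.0 * residual_sigma
    return {
        "duration_s": metrics["fwhm"],
        "energy_J": metrics["energy"],
        "peak_power_W": metrics["peak_power"],
        "max_dPdt_W_per_s": metrics["max_dPdt"],
        "min_dPdt_W_per_s": metrics["min_dPdt"],
        "mu_a_cm1": mu_a,
        "regime": report.regime,
        "geometry_class": report.geometry_class,
        "peak_pressure_Pa": trace.peak_positive,
        "peak_negative_Pa": trace.peak_negative,
        "peak_abs_Pa": trace.peak_abs,
        "onset_offset_interval_s": extrema_interval(trace),
        "measured_peak_Pa": measured.peak_abs,
        "recorded_peak_Pa": recording.peak_abs,
        "spl_db_re_1uPa": spl_re_1uPa(trace.peak_abs),
        "spl_measured_db_re_1uPa": spl_re_1uPa(measured.peak_abs),
        "cap_n1p1_au": cap.n1p1_amplitude,
        "cap_peak_count": len(cap.peaks),
        "detection_floor_Pa": detection_floor,
        "detectable": bool(measured.peak_abs >= detection_floor),
        "seed": seed,
    }


def _derivative_regression(df: pd.DataFrame) -> dict:
    """OLS of onset peak pressure on max dP/dt over flat-top points."""
    sel = df[df["pulse_shape"] == "flat_top"]
    if len(sel) < 3:
        return {}
    res = stats.linregress(sel["max_dPdt_W_per_s"], sel["peak_pressure_Pa"])
    return {"slope_Pa_per_W_per_s": float(res.slope),
            "intercept_Pa": float(res.intercept),
            "r_squared": float(res.rvalue**2)}


def sweep_constant_energy(
    energy: float = 6e-6,
    durations=None,
    config: ExperimentConfig | None = None,
) -> SweepResult:
    """Vary pulse duration at fixed pulse energy (study condition 1).

    At constant energy the plateau power -- and with it the maximum of
    dP/dt -- falls as 1/duration, so the onset pressure amplitude falls
    with duration; the regression of peak pressure on max dP/dt is the
    sweep's main diagnostic.
    """
    cfg = config or ExperimentConfig()
    if durations is None:
        durations = cfg.energy_sweep_durations_s
    durations = sorted(float(d) for d in durations)
    mu_a = cfg.resolved_mu_a()
    cache: dict = {}
    rows = []
    for i, d in enumerate(durations):
        pulse = _make_sweep_pulse(d, energy=energy, cfg=cfg)
        row = _simulate_point(pulse, mu_a, cfg, _point_seed(cfg.seed, 1, i), cache)
        row["pulse_shape"] = pulse.meta["label"]
        row["nominal_duration_s"] = d
        rows.append(row)
        log.info("constant-energy %.3g s: %.3g Pa", d, row["peak_pressure_Pa"])
    df = pd.DataFrame(rows)
    info = {"sweep": "constant_energy", "energy_J": energy,
            "mu_a_cm1": mu_a,
            "derivative_regression": _derivative_regression(df)}
    return SweepResult(df, info)


def sweep_constant_power(
    peak_power: float = 0.15,
    durations=None,
    config: ExperimentConfig | None = None,
) -> SweepResult:
    """Vary pulse duration at fixed plateau power (study condition 2).

    The rising edge is identical for every duration, so the onset pressure
    transient is too: its amplitude should be constant across the sweep,
    while the onset-offset interval tracks the pulse duration exactly.
    """
    cfg = config or ExperimentConfig()
    if durations is None:
        durations = cfg.power_sweep_durations_s
    durations = sorted(float(d) for d in durations)
    mu_a = cfg.resolved_mu_a()
    cache: dict = {}
    rows = []
    for i, d in enumerate(durations):
        pulse = _make_sweep_pulse(d, peak_power=peak_power, cfg=cfg)
        row = _simulate_point(pulse, mu_a, cfg, _point_seed(cfg.seed, 2, i), cache)
        row["pulse_shape"] = pulse.meta["label"]
        row["nominal_duration_s"] = d
        rows.append(row)
        log.info("constant-power %.3g s: %.3g Pa", d, row["peak_pressure_Pa"])
    df = pd.DataFrame(rows)
    onset = df["peak_pressure_Pa"]
    info = {"sweep": "constant_power", "peak_power_W": peak_power,
            "mu_a_cm1": mu_a,
            "onset_variation": float((onset.max() - onset.min()) / onset.mean())}
    return SweepResult(df, info)


def sweep_absorption(
    mu_a_grid=None,
    config: ExperimentConfig | None = None,
) -> SweepResult:
    """Vary the absorption coefficient at fixed nanosecond pulses (3/4).

    Reports the location of the amplitude maximum over the grid and the
    dimensionless mu_a * r product there.  The comparison with the
    measured reversal points is a diagnostic: the linear model does not
    include the near-field wave-geometry physics behind the measured
    high-absorption amplitude drop.
    """
    cfg = config or ExperimentConfig()
    if mu_a_grid is None:
        mu_a_grid = cfg.absorption_sweep_mu_a_cm1
    grid = sorted(float(m) for m in mu_a_grid)
    if any(m <= 0 for m in grid):
        raise ConfigError("mu_a grid must be positive")
    cache: dict = {}
    rows = []
    for i, mu_a in enumerate(grid):
        pulse = make_gaussian(NS_PULSE_FWHM, cfg.pulse_energy_j)
        row = _simulate_point(pulse, mu_a, cfg, _point_seed(cfg.seed, 3, i), cache)
        row["pulse_shape"] = pulse.meta["label"]
        row["nominal_duration_s"] = NS_PULSE_FWHM
        rows.append(row)
        log.info("absorption %.3g cm^-1: %.3g Pa", mu_a, row["peak_pressure_Pa"])
    df = pd.DataFrame(rows)
    i_max = int(df["peak_abs_Pa"].idxmax())
    mu_at_max = float(df.loc[i_max, "mu_a_cm1"])
    product, cls = source_geometry_class(mu_at_max, cfg.fiber_radius_m)
    info = {"sweep": "absorption", "pulse_energy_J": cfg.pulse_energy_j,
            "argmax_mu_a_cm1": mu_at_max,
            "mu_a_times_r_at_argmax": product,
            "geometry_class_at_argmax": cls}
    return SweepResult(df, info)


def simulate_reference_spl(config: ExperimentConfig | None = None,
                           mu_a: float = 10.0,
                           duration: float = 30e-6) -> dict:
    """Peak SPL at 0.1 mm for the reference configuration.

    6 uJ flat-top of the given duration, mu_a in cm^-1; returns the peak
    SPL of the raw simulated pressure and of the measurement-chain output.
    """
    cfg = config or ExperimentConfig()
    pulse = make_flat_top(duration, cfg.pulse_energy_j / duration,
                          cfg.rise_time_s, cfg.fall_time_s)
    source = build_heating_source(cfg.fiber_radius_m, mu_a,
                                  voxels_per_scale=cfg.voxels_per_scale)
    medium = MediumProperties(grueneisen=cfg.grueneisen, mu_a=mu_a)
    trace = pressure_at_point(source, pulse,
                              FieldPoint(cfg.distance_m, cfg.lateral_offset_m),
                              medium)
    measured = apply_measurement_chain(trace, cfg.bandwidth_hz, cfg.sampling_hz)
    return {
        "peak_pressure_Pa": trace.peak_abs,
        "spl_db_re_1uPa": spl_re_1uPa(trace.peak_abs),
        "measured_peak_Pa": measured.peak_abs,
        "spl_measured_db_re_1uPa": spl_re_1uPa(measured.peak_abs),
        "n_voxels": int(source.r.size),
    }


def run_all(config=None, out_dir="results", seed: int | None = None) -> dict:
    """Run every study, write CSV/JSON reports, return the summary dict.

    ``config`` may be an ``ExperimentConfig``, a YAML path, or None for
    defaults; ``seed`` overrides the config seed.  Outputs are
    deterministic for a fixed (config, seed).
    """
    t_start = time.time()
    if config is None:
        cfg = ExperimentConfig()
    elif isinstance(config, ExperimentConfig):
        cfg = config
    else:
        cfg = load_config(config)
    if seed is not None:
        cfg.seed = int(seed)
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    log.info("constant-energy sweep ...")
    energy = sweep_constant_energy(cfg.pulse_energy_j, config=cfg)
    log.info("constant-power sweep ...")
    power = sweep_constant_power(cfg.peak_power_w, config=cfg)
    log.info("absorption sweep ...")
    absorption = sweep_absorption(config=cfg)

    log.info("ink calibration ...")
    ink = generate_ink_series(noise=NoiseSpec(0.005, _point_seed(cfg.seed, 4, 0)))
    cal = calibrate_from_series(ink)

    ref = simulate_reference_spl(cfg)
    threshold = merge_threshold(cfg.cap_integration_time_s,
                                tuple(cfg.cap_band_hz))

    energy.table.to_csv(out / "energy_sweep.csv", index=False)
    power.table.to_csv(out / "power_sweep.csv", index=False)
    absorption.table.to_csv(out / "absorption_sweep.csv", index=False)
    ink.to_csv(out / "ink_series.csv", index=False)
    save_config(cfg, out / "config_used.yaml")

    from .confinement import (smallest_dimension, stress_confinement_limit,
                              thermal_confinement_limit, WATER)
    delta = smallest_dimension(cfg.resolved_mu_a(), cfg.fiber_radius_m)
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "runtime_s": None,
        "confinement": {
            "delta_um": delta * 1e6,
            "tau_th_ms": thermal_confinement_limit(delta, WATER.kappa) * 1e3,
            "tau_p_ns": stress_confinement_limit(delta, WATER.c) * 1e9,
        },
        "reference_point": ref,
        "constant_energy": energy.info,
        "constant_power": power.info,
        "absorption": absorption.info,
        "ink_calibration": {"slope_cm1_per_pct": cal.slope,
                            "intercept_cm1": cal.intercept,
                            "r_squared": cal.r_squared},
        "cap_merge_threshold_ms": threshold * 1e3,
    }
    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    if cfg.make_plots:
        _write_plots(out, energy, power, absorption)
    log.info("run_all finished in %.1f s", summary["runtime_s"])
    return summary


def _write_plots(out: Path, energy: SweepResult, power: SweepResult,
                 absorption: SweepResult) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].loglog(energy.table["nominal_duration_s"],
                   energy.table["peak_abs_Pa"], "o-")
    axes[0].set(xlabel="pulse duration (s)", ylabel="peak pressure (Pa)",
                title="constant energy")
    axes[1].semilogx(power.table["nominal_duration_s"],
                     power.table["peak_pressure_Pa"], "o-")
    axes[1].set(xlabel="pulse duration (s)", ylabel="onset peak (Pa)",
                title="constant peak power")
    axes[2].semilogx(absorption.table["mu_a_cm1"],
                     absorption.table["peak_abs_Pa"], "o-")
    axes[2].set(xlabel=r"$\mu_a$ (cm$^{-1}$)", ylabel="peak pressure (Pa)",
                title="absorption sweep")
    fig.tight_layout()
    fig.savefig(out / "sweeps.png", dpi=120)
    plt.close(fig)
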
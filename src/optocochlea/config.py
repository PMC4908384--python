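"""Experiment configuration: defaults, YAML loading, validation.

The defaults reproduce the study conditions: a 105 um core fiber (52.5 um
radius), 6 uJ pulse energy / 150 mW plateau power, a hydrophone-like field
point 0.1 mm beyond the tip on the beam axis, a 100 kHz amplifier sampled
at 102 kHz, recordings averaged over 10^4 shots, and the 1860 nm
stimulation wavelength whose water absorption sets the duration sweeps.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    # source / geometry
    fiber_radius_m: float = 52.5e-6
    distance_m: float = 1e-4          # axial offset of the field point
    lateral_offset_m: float = 0.0
    wavelength_nm: float = 1860.0     # sets mu_a when mu_a_cm1 is None
    mu_a_cm1: float | None = None
    voxels_per_scale: int = 10

    # laser
    pulse_energy_j: float = 6e-6
    peak_power_w: float = 0.15
    rise_time_s: float = 1e-6
    fall_time_s: float = 1e-6

    # medium
    grueneisen: float = 0.11

    # measurement chain
    bandwidth_hz: float = 100e3
    sampling_hz: float = 102e3

    # hydrophone noise / averaging
    hydrophone_sigma_pa: float = 3.0
    n_averages: int = 10000
    photodiode_sigma_frac: float = 0.005
    seed: int = 0

    # CAP surrogate
    cap_integration_time_s: float = 0.35e-3
    cap_band_hz: tuple = (5.0, 5000.0)

    # sweep grids
    energy_sweep_durations_s: tuple = (
        5e-9, 5e-6, 1e-5, 2e-5, 3e-5, 4e-5, 5e-5, 1e-4, 2e-4, 4e-4)
    power_sweep_durations_s: tuple = (
        1e-5, 4e-5, 1e-4, 4e-4, 1e-3, 2e-3, 5e-3, 1e-2)
    absorption_sweep_mu_a_cm1: tuple = (
        1.34, 2.0, 4.0, 8.89, 16.0, 30.0, 57.5, 77.0, 100.0, 124.0)

    # reporting
    make_plots: bool = False

    def resolved_mu_a(self) -> float:
        """mu_a in cm^-1: explicit value, or water absorption at the wavelength."""
        if self.mu_a_cm1 is not None:
            return float(self.mu_a_cm1)
        from .absorption import lookup_mu_a, water_spectrum
        return lookup_mu_a(water_spectrum(), self.wavelength_nm)


_FIELD_NAMES = {f.name for f in fields(ExperimentConfig)}
_TUPLE_FIELDS = {"cap_band_hz", "energy_sweep_durations_s",
                 "power_sweep_durations_s", "absorption_sweep_mu_a_cm1"}


def load_config(path=None, overrides: dict | None = None) -> ExperimentConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys raise a ``ConfigError`` naming the offending key.
    """
    data: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        data[key] = tuple(data[key])
    return ExperimentConfig(**data)


def save_config(cfg: ExperimentConfig, path) -> None:
    d = asdict(cfg)
    for key in _TUPLE_FIELDS:
        d[key] = list(d[key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
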
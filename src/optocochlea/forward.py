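"""Optoacoustic pressure at a field point from a voxelized heating source.

The model is the linear photoacoustic wave equation for an inviscid,
acoustically homogeneous fluid, driven by the heating rate
H(x, t) = A_e(x) P(t), where A_e is the volumetric optical energy
deposition per unit pulse energy (1/m^3) and P(t) the optical power.  Its
retarded-potential solution at a field point x is

    p(x, t) = Gamma / (4 pi c^2) * integral dV' A_e(x') P'(t - R/c) / R,

with R = |x - x'| and Gamma the Grueneisen coefficient.  Pressure is
therefore driven by the *slope* of the optical power: a flat-top pulse
radiates a positive transient at its onset, a negative one at its offset,
and nothing during the constant plateau.

Numerically, the volume integral is evaluated by depositing each voxel's
weight A_e dV / R into a delay histogram g(tau) at tau = R/c (linear
splitting between adjacent bins, equivalent to linear interpolation of P'
at the retarded time) and convolving g with the sampled P'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .confinement import CM_TO_M, WATER, MediumProperties
from .errors import GridError, InvalidParameterError, ResolutionError
from .pulse import PulseWaveform, power_derivative

__all__ = [
    "SourceGrid",
    "FieldPoint",
    "PressureTrace",
    "build_heating_source",
    "build_spherical_source",
    "initial_pressure",
    "pressure_at_point",
    "apply_measurement_chain",
    "spl_re_1uPa",
    "extrema_interval",
    "read_trace_csv",
    "write_trace_csv",
]

P_REF = 1e-6  # underwater SPL reference, Pa


@dataclass
class SourceGrid:
    """Axisymmetric voxelized energy deposition (ring voxels).

    ``A_e`` is the deposition density per unit pulse energy (1/m^3), so the
    absorbed energy fraction is sum(A_e * volume).  Ring voxels are centred
    at radius ``r`` and axial position ``z`` (z = 0 at the fiber tip,
    increasing along the beam).
    """

    r: np.ndarray          # ring radial centers, m
    z: np.ndarray          # ring axial centers, m
    A_e: np.ndarray        # deposition per unit energy, 1/m^3
    volume: np.ndarray     # ring volumes, m^3
    fiber_radius: float
    mu_a: float            # cm^-1 (0 for non-Beer-Lambert sources)
    axial_extent: float    # m
    voxel_size: float      # m, characteristic linear cell size
    meta: dict = field(default_factory=dict)

    def absorbed_fraction(self) -> float:
        """Fraction of the pulse energy deposited in the grid."""
        return float(np.sum(self.A_e * self.volume))

    def surface_density(self) -> float:
        """Mean on-axis deposition density (1/m^3) in the first axial slab."""
        first = self.z == self.z.min()
        return float(np.average(self.A_e[first], weights=self.volume[first]))


@dataclass
class FieldPoint:
    """Observation point relative to the fiber tip (on the beam axis at 0,0).

    ``axial_offset`` is measured along the beam from the tip (positive into
    the medium); ``lateral_offset`` is perpendicular to the axis.
    """

    axial_offset: float
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise InvalidParameterError("field point must be away from the tip")

    @property
    def distance(self) -> float:
        return math.hypot(self.axial_offset, self.lateral_offset)


@dataclass
class PressureTrace:
    """Pressure versus time at a field point."""

    t: np.ndarray
    p: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape or self.t.ndim != 1:
            raise GridError("t and p must be 1-D arrays of equal length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def peak_positive(self) -> float:
        return float(self.p.max())

    @property
    def peak_negative(self) -> float:
        return float(self.p.min())

    @property
    def peak_abs(self) -> float:
        return float(np.abs(self.p).max())


def build_heating_source(
    fiber_radius: float,
    mu_a: float,
    axial_cutoff: float | None = None,
    voxels_per_scale: int = 10,
    pulse_energy: float | None = None,
) -> SourceGrid:
    """Beer-Lambert deposition of a top-hat beam from a fiber tip.

    The fluence is uniform across the fiber core and decays as
    exp(-mu_a z) along the axis; the per-cell deposition uses the exact
    cell-averaged exponential so the absorbed-fraction invariant
    sum(A_e dV) = 1 - exp(-mu_a L) holds to rounding error.

    mu_a in cm^-1; lengths in m.  ``voxels_per_scale`` cells resolve the
    smaller of the penetration depth and the fiber radius (minimum 5).
    """
    if fiber_radius <= 0 or mu_a <= 0:
        raise InvalidParameterError("fiber_radius and mu_a must be positive")
    if voxels_per_scale < 5:
        raise ResolutionError("need at least 5 voxels per min(1/mu_a, r)")
    mu_m = mu_a / CM_TO_M
    penetration = 1.0 / mu_m
    default_cutoff = min(5.0 * penetration, 5e-3)
    if axial_cutoff is None:
        axial_cutoff = default_cutoff
    elif axial_cutoff < min(3.0 * penetration, 5e-3):
        raise InvalidParameterError(
            "axial_cutoff must cover >= 3 penetration depths (or 5 mm)")
    scale = min(penetration, fiber_radius)
    h = scale / voxels_per_scale

    n_r = max(voxels_per_scale, int(math.ceil(fiber_radius / h)))
    r_edges = np.linspace(0.0, fiber_radius, n_r + 1)
    n_z = int(math.ceil(axial_cutoff / h))
    z_edges = np.linspace(0.0, axial_cutoff, n_z + 1)

    r_c = 0.5 * (r_edges[:-1] + r_edges[1:])
    ring_area = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    dz = z_edges[1] - z_edges[0]
    # exact cell-averaged exponential deposition per unit energy
    slab = (np.exp(-mu_m * z_edges[:-1]) - np.exp(-mu_m * z_edges[1:]))
    a_z = slab / (dz * math.pi * fiber_radius**2)      # 1/m^3 per axial cell

    R, Z = np.meshgrid(r_c, 0.5 * (z_edges[:-1] + z_edges[1:]), indexing="ij")
    A, _ = np.meshgrid(ring_area, a_z, indexing="ij")
    A_e = np.broadcast_to(a_z, (n_r, n_z)).ravel()
    vol = (A * dz).ravel()
    return SourceGrid(
        r=R.ravel(), z=Z.ravel(), A_e=A_e.copy(), volume=vol,
        fiber_radius=fiber_radius, mu_a=mu_a, axial_extent=axial_cutoff,
        voxel_size=h,
        meta={"pulse_energy_J": pulse_energy, "voxels_per_scale": voxels_per_scale},
    )


def build_spherical_source(
    radius: float,
    center_depth: float,
    voxel_size: float | None = None,
) -> SourceGrid:
    """Uniformly heated sphere, a validation geometry with a closed-form wave.

    All of the pulse energy is deposited uniformly inside a sphere of the
    given radius centred on the axis at ``center_depth``; cells straddling
    the surface get a linear partial-volume weight.  Used to cross-check
    the solver against the analytic spherical N-wave.
    """
    if radius <= 0 or center_depth <= 0:
        raise InvalidParameterError("radius and center_depth must be positive")
    if voxel_size is None:
        voxel_size = radius / 40.0
    h = voxel_size
    n_r = int(math.ceil(radius / h))
    r_edges = np.linspace(0.0, radius, n_r + 1)
    z_lo, z_hi = center_depth - radius, center_depth + radius
    n_z = int(math.ceil((z_hi - z_lo) / h))
    z_edges = np.linspace(z_lo, z_hi, n_z + 1)
    r_c = 0.5 * (r_edges[:-1] + r_edges[1:])
    z_c = 0.5 * (z_edges[:-1] + z_edges[1:])
    dz = z_edges[1] - z_edges[0]
    ring_area = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    R, Z = np.meshgrid(r_c, z_c, indexing="ij")
    A, _ = np.meshgrid(ring_area, z_c, indexing="ij")
    rho = np.sqrt(R**2 + (Z - center_depth) ** 2)
    w = np.clip((radius - rho) / h + 0.5, 0.0, 1.0)   # partial-volume antialias
    vol = A * dz
    total = float(np.sum(w * vol))
    A_e = (w / total).ravel()
    return SourceGrid(
        r=R.ravel(), z=Z.ravel(), A_e=A_e, volume=vol.ravel(),
        fiber_radius=radius, mu_a=0.0, axial_extent=z_hi,
        voxel_size=h, meta={"geometry": "sphere", "radius_m": radius,
                            "center_depth_m": center_depth},
    )


def initial_pressure(A_e_density: float, grueneisen: float) -> float:
    """Stress-confined initial pressure p0 = Gamma * A_e (Pa).

    ``A_e_density`` here is the absolute deposited energy density in J/m^3.
    """
    if A_e_density < 0 or grueneisen < 0:
        raise InvalidParameterError("inputs must be non-negative")
    return grueneisen * A_e_density


def _rise_time_estimate(w: PulseWaveform) -> float:
    """10-90% rise time of the leading edge."""
    peak = w.P.max()
    if peak <= 0:
        raise InvalidParameterError("pulse has no power")
    i_hi = int(np.argmax(w.P >= 0.9 * peak))
    below = np.nonzero(w.P[:i_hi + 1] <= 0.1 * peak)[0]
    i_lo = int(below[-1]) if below.size else 0
    return max(w.t[i_hi] - w.t[i_lo], w.dt)


def pressure_at_point(
    source: SourceGrid,
    pulse: PulseWaveform,
    fieldpt: FieldPoint,
    medium: MediumProperties = WATER,
    n_phi: int = 24,
) -> PressureTrace:
    """Retarded-time volume integral of the optoacoustic wave at one point.

    The pulse grid is refined automatically so that c*dt is below half the
    voxel size; the pulse must resolve its own rise with >= 10 samples.  A
    field point inside the source volume is allowed but flagged
    ``near_field`` in the trace metadata (the 1/R weight of the enclosing
    voxel is clamped at half a voxel).
    """
    if not pulse.has_uniform_grid():
        raise GridError("pulse must be on a uniform grid")
    c = medium.c
    rise = _rise_time_estimate(pulse)
    if pulse.dt > rise / 10.0:
        raise ResolutionError(
            f"pulse grid dt={pulse.dt:.3g}s does not resolve the "
            f"{rise:.3g}s rise time with >= 10 samples")

    # refine so geometric delays are resolved: c*dt < voxel/2
    dt_needed = source.voxel_size / (2.0 * c)
    if pulse.dt > dt_needed:
        k = int(math.ceil(pulse.dt / dt_needed))
        t_fine = pulse.t[0] + np.arange((pulse.t.size - 1) * k + 1) * (pulse.dt / k)
        P_fine = np.interp(t_fine, pulse.t, pulse.P)
        work = PulseWaveform(t_fine, P_fine, dict(pulse.meta))
    else:
        work = pulse
    dt = work.dt
    dPdt = power_derivative(work).dPdt

    # geometry: distances from every ring (or ring segment) to the field point
    zf = fieldpt.axial_offset
    lat = fieldpt.lateral_offset
    if lat == 0.0:
        R = np.sqrt(source.r**2 + (source.z - zf) ** 2)
        w = source.A_e * source.volume
    else:
        phi = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
        x = source.r[:, None] * np.cos(phi)[None, :]
        y = source.r[:, None] * np.sin(phi)[None, :]
        R = np.sqrt((x - lat) ** 2 + y**2 + (source.z[:, None] - zf) ** 2).ravel()
        w = np.repeat(source.A_e * source.volume / n_phi, n_phi)

    near_field = bool(R.min() < source.voxel_size)
    R = np.maximum(R, source.voxel_size / 2.0)
    weights = w / R
    tau = R / c

    # deposit weights into a delay histogram with linear bin splitting
    pos = tau / dt
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    g = np.zeros(int(i0.max()) + 2)
    np.add.at(g, i0, weights * (1.0 - frac))
    np.add.at(g, i0 + 1, weights * frac)

    prefactor = medium.grueneisen / (4.0 * math.pi * c**2)
    p = prefactor * signal.oaconvolve(dPdt, g)
    t_out = work.t[0] + np.arange(p.size) * dt
    return PressureTrace(
        t_out, p,
        meta={"near_field": near_field, "dt_s": dt,
              "distance_m": fieldpt.distance,
              "pulse_label": pulse.meta.get("label"),
              "mu_a_cm1": source.mu_a},
    )


def apply_measurement_chain(
    trace: PressureTrace,
    bandwidth: float = 100e3,
    sampling_rate: float = 102e3,
    order: int = 4,
) -> PressureTrace:
    """Amplifier low-pass plus data-acquisition resampling.

    A zero-phase Butterworth low-pass at ``bandwidth`` (default 100 kHz,
    the conditioning-amplifier limit) followed by resampling at
    ``sampling_rate`` (default 102 kHz).  Zero-phase filtering keeps event
    timing; sampling the already band-limited trace is alias-free.
    """
    fs = 1.0 / trace.dt
    if sampling_rate > fs:
        raise InvalidParameterError("sampling_rate cannot exceed the trace rate")
    if bandwidth >= fs / 2.0:
        raise InvalidParameterError("bandwidth must be below the trace Nyquist")
    # zero-pad so the filter settles and short transients stay representable
    # at the coarse output rate (pressure is zero outside the solved window)
    pad_time = max(8.0 / bandwidth, 16.0 / sampling_rate)
    n_pad = int(math.ceil(pad_time / trace.dt))
    x = np.concatenate([np.zeros(n_pad), trace.p, np.zeros(n_pad)])
    t_work = trace.t[0] - n_pad * trace.dt + np.arange(x.size) * trace.dt
    fs_work = fs
    # stage the decimation: a 100 kHz corner on a GHz-rate trace is
    # numerically fragile in one step, so halve towards ~40x the corner
    while fs_work > 50.0 * bandwidth and x.size > 32:
        k = min(8, max(2, int(fs_work / (25.0 * bandwidth))))
        sos_aa = signal.butter(4, 0.4 * fs_work / k, btype="low",
                               fs=fs_work, output="sos")
        x = signal.sosfiltfilt(sos_aa, x)[::k]
        t_work = t_work[::k]
        fs_work /= k
    sos = signal.butter(order, bandwidth, btype="low", fs=fs_work, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    dt_out = 1.0 / sampling_rate
    t_new = np.arange(t_work[0], t_work[-1], dt_out)
    p_new = np.interp(t_new, t_work, filtered)
    meta = dict(trace.meta)
    meta.update({"bandwidth_hz": bandwidth, "sampling_hz": sampling_rate,
                 "measurement_chain": True})
    return PressureTrace(t_new, p_new, meta)


def spl_re_1uPa(peak_pressure: float) -> float:
    """Sound pressure level in dB re 1 uPa (underwater reference)."""
    if peak_pressure <= 0:
        raise InvalidParameterError("peak pressure must be positive")
    return 20.0 * math.log10(peak_pressure / P_REF)


def extrema_interval(trace: PressureTrace) -> float:
    """Time between the global positive and negative pressure extrema.

    For a flat-top pulse this is the onset-to-offset interval, which equals
    the pulse duration.
    """
    t_pos = trace.t[int(np.argmax(trace.p))]
    t_neg = trace.t[int(np.argmin(trace.p))]
    return abs(float(t_neg - t_pos))


def write_trace_csv(trace: PressureTrace, path) -> None:
    pd.DataFrame({"time_s": trace.t, "pressure_Pa": trace.p}).to_csv(path, index=False)


def read_trace_csv(path) -> PressureTrace:
    df = pd.read_csv(path)
    return PressureTrace(df["time_s"].to_numpy(), df["pressure_Pa"].to_numpy(),
                         {"label": "from_csv"})
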
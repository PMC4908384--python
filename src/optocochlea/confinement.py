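"""Thermal/stress confinement criteria and optoacoustic source geometry.

Two time scales govern how efficiently a laser pulse converts absorbed heat
into pressure: the heat-diffusion time out of the heated volume
(tau_th = delta^2 / 4 kappa) and the acoustic transit time across it
(tau_p = delta / c), with delta the smallest dimension of the heated volume
-- the lesser of the optical penetration depth 1/mu_a and the fiber radius.
A pulse shorter than tau_p is stress-confined, one shorter than tau_th only
is thermally confined, and longer pulses are unconfined.  A separate,
dimensionless product mu_a * r classifies the shape of the heated zone:
a thin disk at the fiber tip for strong absorption (mu_a r >> 1) or an
extended cylinder along the beam for weak absorption (mu_a r << 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "MediumProperties",
    "ConfinementReport",
    "WATER",
    "smallest_dimension",
    "thermal_confinement_limit",
    "stress_confinement_limit",
    "classify_regime",
    "source_geometry_class",
]

CM_TO_M = 1e-2  # mu_a is carried in cm^-1; lengths in m


@dataclass
class MediumProperties:
    """Thermophysical constants of the absorbing fluid (water-like defaults).

    c : speed of sound, m/s
    kappa : thermal diffusivity, m^2/s
    beta : volumetric thermal expansion coefficient, 1/K
    C_p : specific heat at constant pressure, J/(kg K)
    rho : density, kg/m^3
    grueneisen : dimensionless Grueneisen coefficient (beta c^2 / C_p)
    mu_a : optical absorption coefficient, cm^-1
    """

    c: float = 1484.0
    kappa: float = 1.4e-7
    beta: float = 2.07e-4
    C_p: float = 4181.0
    rho: float = 998.0
    grueneisen: float = 0.11
    mu_a: float = 1.34

    def __post_init__(self) -> None:
        for name in ("c", "kappa", "beta", "C_p", "rho", "grueneisen"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.mu_a < 0:
            raise InvalidParameterError("mu_a must be non-negative")

    def grueneisen_from_constants(self) -> float:
        """Gamma = beta c^2 / C_p, the thermo-acoustic efficiency."""
        return self.beta * self.c**2 / self.C_p


#: Water near 20 degC; Grueneisen 0.11 (= beta c^2 / C_p within ~1%).
WATER = MediumProperties()


@dataclass
class ConfinementReport:
    """Confinement times, regime label and source-geometry class."""

    delta: float          # smallest heated dimension, m
    tau_th: float         # thermal confinement limit, s
    tau_p: float          # stress confinement limit, s
    regime: str           # 'stress' | 'thermal' | 'none'
    mu_a_times_r: float   # dimensionless geometry product
    geometry_class: str   # 'disk' | 'cylinder' | 'transition'


def smallest_dimension(mu_a: float, fiber_radius: float) -> float:
    """Smallest dimension of the heated volume, m.

    The lesser of the axial light penetration depth 1/mu_a and the fiber
    radius; for mu_a = 0 the radius alone sets the scale.
    """
    if mu_a < 0:
        raise InvalidParameterError("mu_a must be non-negative")
    if fiber_radius <= 0:
        raise InvalidParameterError("fiber_radius must be positive")
    if mu_a == 0:
        return fiber_radius
    penetration = 1.0 / (mu_a / CM_TO_M)
    return min(penetration, fiber_radius)


def thermal_confinement_limit(delta: float, kappa: float) -> float:
    """Longest pulse still thermally confined: tau_th = delta^2 / (4 kappa)."""
    if delta <= 0 or kappa <= 0:
        raise InvalidParameterError("delta and kappa must be positive")
    return delta**2 / (4.0 * kappa)


def stress_confinement_limit(delta: float, c: float) -> float:
    """Longest pulse still stress confined: tau_p = delta / c."""
    if delta <= 0 or c <= 0:
        raise InvalidParameterError("delta and c must be positive")
    return delta / c


def source_geometry_class(mu_a: float, fiber_radius: float) -> tuple[float, str]:
    """Classify the heated zone via the product mu_a * fiber_radius.

    Returns (mu_a_times_r, class): 'cylinder' below 0.1, 'disk' above 10,
    'transition' in between.  The thresholds bracket the asymptotic
    "much less / much greater than one" regimes.
    """
    if mu_a < 0:
        raise InvalidParameterError("mu_a must be non-negative")
    if fiber_radius <= 0:
        raise InvalidParameterError("fiber_radius must be positive")
    product = (mu_a / CM_TO_M) * fiber_radius
    if product < 0.1:
        cls = "cylinder"
    elif product > 10.0:
        cls = "disk"
    else:
        cls = "transition"
    return product, cls


def classify_regime(
    pulse_duration: float,
    mu_a: float,
    fiber_radius: float,
    medium: MediumProperties = WATER,
) -> ConfinementReport:
    """Full confinement report for a pulse duration and source geometry.

    Boundaries are inclusive toward the tighter regime: a pulse exactly at
    tau_th still counts as thermally confined.
    """
    if pulse_duration <= 0:
        raise InvalidParameterError("pulse_duration must be positive")
    delta = smallest_dimension(mu_a, fiber_radius)
    tau_th = thermal_confinement_limit(delta, medium.kappa)
    tau_p = stress_confinement_limit(delta, medium.c)
    if pulse_duration <= tau_p:
        regime = "stress"
    elif pulse_duration <= tau_th:
        regime = "thermal"
    else:
        regime = "none"
    product, cls = source_geometry_class(mu_a, fiber_radius)
    return ConfinementReport(delta, tau_th, tau_p, regime, product, cls)
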
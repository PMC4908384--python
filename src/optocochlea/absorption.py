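"""Optical absorption: Lambert-Beer, a bundled water table, ink calibration.

The optoacoustic amplitude is controlled by the absorption coefficient
mu_a(lambda) of the fluid in front of the fiber tip.  Two ways of varying
mu_a are supported, mirroring the two experimental knobs: sweeping the
wavelength against the near-infrared water spectrum, and adding India ink
at a fixed wavelength, where mu_a grows linearly with ink concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError, MeasurementRangeError

__all__ = [
    "AbsorptionSpectrum",
    "InkCalibration",
    "beer_lambert_mu",
    "water_spectrum",
    "lookup_mu_a",
    "fit_ink_calibration",
    "ink_mu_a",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_ink_series_csv",
]


@dataclass
class AbsorptionSpectrum:
    """Tabulated absorption coefficient versus wavelength.

    wavelength in nm (strictly increasing), mu_a in cm^-1 (non-negative).
    """

    wavelength: np.ndarray
    mu_a: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        if self.wavelength.shape != self.mu_a.shape or self.wavelength.ndim != 1:
            raise InvalidParameterError("wavelength and mu_a must be 1-D, same length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        if np.any(self.mu_a < 0):
            raise InvalidParameterError("mu_a must be non-negative")


@dataclass
class InkCalibration:
    """Linear concentration -> absorption calibration for an ink dilution series."""

    concentrations: np.ndarray   # % v/v
    mu_a: np.ndarray             # cm^-1 (measured or predicted)
    slope: float                 # cm^-1 per %
    intercept: float             # cm^-1 (solvent absorption)
    r_squared: float
    extrapolated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


# Near-infrared absorption of pure liquid water, cm^-1, at 12 support nodes
# spanning the 845-2100 nm stimulation window.  Values follow the standard
# water-absorption literature (Hale & Querry-type compilations); the 1300 nm
# node (1.34 cm^-1) and the 845 nm node (0.039 cm^-1) are the two anchors
# used throughout the analysis.
_WATER_NM = np.array(
    [845.0, 970.0, 1064.0, 1197.0, 1300.0, 1370.0,
     1450.0, 1550.0, 1700.0, 1860.0, 1940.0, 2100.0])
_WATER_MUA = np.array(
    [0.039, 0.45, 0.14, 1.04, 1.34, 5.5,
     28.8, 9.8, 5.9, 32.0, 120.0, 24.0])


def water_spectrum() -> AbsorptionSpectrum:
    """The bundled near-infrared water absorption table (845-2100 nm)."""
    return AbsorptionSpectrum(_WATER_NM.copy(), _WATER_MUA.copy())


def beer_lambert_mu(transmission: float, pathlength: float = 1.0) -> float:
    """Absorption coefficient from a transmission measurement.

    mu_a = -ln(T) / L with T the transmitted fraction and L the optical
    pathlength in cm.  Transmissions at or below zero cannot be inverted and
    are reported as outside the measurement range.
    """
    if pathlength <= 0:
        raise InvalidParameterError("pathlength must be positive")
    if transmission <= 0:
        raise MeasurementRangeError(
            "transmission <= 0 is outside the measurement range")
    if transmission > 1:
        raise InvalidParameterError("transmission cannot exceed 1")
    return -math.log(transmission) / pathlength


def lookup_mu_a(spec: AbsorptionSpectrum, wavelength: float) -> float:
    """Interpolate mu_a at a wavelength, linear in log(mu_a).

    Water absorption spans three decades over this window, so interpolation
    is done on log(mu_a) versus wavelength; table nodes are returned exactly
    and extrapolation outside the table raises.
    """
    lo, hi = spec.wavelength[0], spec.wavelength[-1]
    if not (lo <= wavelength <= hi):
        raise MeasurementRangeError(
            f"wavelength {wavelength} nm outside table range [{lo}, {hi}] nm")
    if np.any(spec.mu_a <= 0):
        # fall back to linear interpolation if a node is exactly zero
        return float(np.interp(wavelength, spec.wavelength, spec.mu_a))
    return float(np.exp(np.interp(wavelength, spec.wavelength, np.log(spec.mu_a))))


def fit_ink_calibration(
    concentrations,
    mu_a,
    extrapolated_mask=None,
) -> InkCalibration:
    """Ordinary least squares of mu_a on ink concentration.

    Points flagged in ``extrapolated_mask`` (e.g. dilutions too opaque for
    the spectrometer) are excluded from the fit and replaced by the fitted
    line's prediction; R^2 is computed on the fitted points only.
    """
    c = np.asarray(concentrations, dtype=float)
    m = np.asarray(mu_a, dtype=float)
    if extrapolated_mask is None:
        mask = np.zeros(c.shape, dtype=bool)
    else:
        mask = np.asarray(extrapolated_mask, dtype=bool)
    if c.shape != m.shape or c.shape != mask.shape:
        raise InvalidParameterError("inputs must share one shape")
    use = ~mask
    if use.sum() < 3:
        raise InsufficientDataError("need at least 3 non-extrapolated points")
    slope, intercept = np.polyfit(c[use], m[use], 1)
    fitted = slope * c + intercept
    resid = m[use] - fitted[use]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((m[use] - m[use].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    mu_out = m.copy()
    mu_out[mask] = fitted[mask]
    return InkCalibration(c, mu_out, float(slope), float(intercept), float(r2), mask)


def ink_mu_a(cal: InkCalibration, concentration: float) -> float:
    """Predicted absorption coefficient (cm^-1) at an ink concentration (%)."""
    if concentration < 0:
        raise InvalidParameterError("concentration must be non-negative")
    return cal.slope * concentration + cal.intercept


def calibrate_from_series(series: pd.DataFrame) -> InkCalibration:
    """Fit an ink calibration from a transmission series table.

    Expects columns ``concentration_pct``, ``transmission``,
    ``pathlength_cm`` and optionally ``outside_range`` (points too opaque
    for the spectrometer, excluded from the fit and linearly extrapolated).
    """
    c = series["concentration_pct"].to_numpy(dtype=float)
    T = series["transmission"].to_numpy(dtype=float)
    L = series["pathlength_cm"].to_numpy(dtype=float)
    if "outside_range" in series.columns:
        mask = series["outside_range"].to_numpy(dtype=bool)
    else:
        mask = np.zeros(c.shape, dtype=bool)
    mu = np.full(c.shape, np.nan)
    for i in range(c.size):
        if not mask[i]:
            mu[i] = beer_lambert_mu(T[i], L[i])
    mu[mask] = 0.0  # placeholder; replaced by the fit's prediction
    return fit_ink_calibration(c, mu, mask)


def write_spectrum_csv(spec: AbsorptionSpectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelength,
                  "mu_a_cm1": spec.mu_a}).to_csv(path, index=False)


def read_spectrum_csv(path) -> AbsorptionSpectrum:
    df = pd.read_csv(path)
    return AbsorptionSpectrum(df["wavelength_nm"].to_numpy(),
                              df["mu_a_cm1"].to_numpy())


def read_ink_series_csv(path) -> pd.DataFrame:
    """Read an ink dilution series CSV (concentration_pct, transmission, pathlength_cm)."""
    df = pd.read_csv(path)
    for col in ("concentration_pct", "transmission", "pathlength_cm"):
        if col not in df.columns:
            raise InvalidParameterError(f"ink series CSV missing column '{col}'")
    return df
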
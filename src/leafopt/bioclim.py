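"""Bioclimate drivers: pressure, daytime temperature, growing-season means,
canopy-averaged light and Rubisco kinetics.

These are the environmental inputs every trait model consumes. All functions
are numpy ufunc-friendly: they accept scalars or arrays and broadcast.

Conventions
-----------
* elevation in m, latitude and solar declination in degrees
* temperatures in degrees C at the API surface, Kelvin only internally
* ``patm`` in kPa; partial pressures (ca, Gamma*, K, Po) in Pa
* instantaneous PAR (R0) in umol photon m-2 s-1; daily totals in
  mol photon m-2 day-1
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .constants import GAS_CONSTANT, P0_KPA, T_REF_K, PhysioConstants
from .exceptions import DegenerateSiteError, PhysicalDomainError, PolarDayError

__all__ = [
    "SiteEnvironment",
    "air_pressure",
    "ambient_co2",
    "daytime_temperature",
    "growing_season_stats",
    "par_to_daily_mol",
    "canopy_light",
    "water_viscosity",
    "viscosity_ratio",
    "rubisco_kinetics",
]

# International-standard-atmosphere constants for the barometric formula.
_GRAVITY = 9.80665          # m s-2
_MOLAR_MASS_AIR = 0.0289644  # kg mol-1
_LAPSE_RATE = 0.0065        # K m-1
_T0_K = 288.15              # K, reference sea-level temperature
_R_UNIV = 8.31446           # J mol-1 K-1 (barometric formula only)


@dataclass(frozen=True)
class SiteEnvironment:
    """One site's location and growing-season bioclimate (the model drivers).

    ``patm`` and ``ca`` are derived from elevation and the ambient CO2 mole
    fraction unless supplied explicitly (e.g. when reproducing an external
    data set that reports measured pressure).
    """

    site_id: str
    elevation: float          # m
    latitude: float           # degrees
    tg: float                 # deg C, growing-season mean temperature
    tdj: float                # deg C, July mean daytime temperature
    d0: float                 # kPa, growing-season mean VPD
    r0: float                 # umol photon m-2 s-1, growing-season mean PAR
    lai: float                # m2 m-2
    r_lai: float              # mol photon m-2 day-1, canopy-averaged PAR
    f: float                  # growing-season fraction of the year
    alpha_p: float            # AET/PET moisture index
    patm: float = None        # kPa
    ca: float = None          # Pa

    def __post_init__(self):
        if self.patm is None:
            object.__setattr__(self, "patm", float(air_pressure(self.elevation)))
        if self.ca is None:
            object.__setattr__(self, "ca", float(ambient_co2(self.patm)))
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"{self.site_id}: f={self.f} outside (0, 1]")
        if self.d0 <= 0:
            raise ValueError(f"{self.site_id}: D0 must be positive")
        if self.alpha_p < 0 or self.lai < 0:
            raise ValueError(f"{self.site_id}: alpha_p and LAI must be >= 0")

    def replace(self, **kw) -> "SiteEnvironment":
        return replace(self, **kw)

    def with_elevation(self, elevation: float,
                       co2_ppm: float | None = None) -> "SiteEnvironment":
        """Move the site vertically, recomputing pressure and ca."""
        patm = float(air_pressure(elevation))
        kw = {} if co2_ppm is None else {"co2_ppm": co2_ppm}
        return self.replace(elevation=elevation, patm=patm,
                            ca=float(ambient_co2(patm, **kw)))


def air_pressure(elevation):
    """Atmospheric pressure (kPa) from elevation via the barometric formula.

    Standard-atmosphere constant-lapse form: p = p0 (1 - L z / T0)^(g M / R L)
    with p0 = 101.325 kPa, L = 0.0065 K m-1, T0 = 288.15 K. Monotone
    decreasing in elevation.
    """
    elevation = np.asarray(elevation, dtype=float)
    if np.any(elevation < -500.0):
        raise ValueError("elevation below -500 m is outside the supported domain")
    exponent = _GRAVITY * _MOLAR_MASS_AIR / (_R_UNIV * _LAPSE_RATE)
    return P0_KPA * (1.0 - _LAPSE_RATE * elevation / _T0_K) ** exponent


def ambient_co2(patm, co2_ppm: float = 410.0):
    """Ambient CO2 partial pressure (Pa) at pressure ``patm`` (kPa).

    A fixed mole fraction (default 410 ppm, ~2018-2019 global mean) times
    total pressure: ca declines with elevation alongside patm.
    """
    return np.asarray(patm, dtype=float) * 1000.0 * co2_ppm * 1e-6


def daytime_temperature(tmax, tmin, latitude, solar_declination):
    """Mean daytime temperature (deg C) from a sine-curve diurnal cycle.

    With x = -tan(lat) tan(decl), the daytime mean is a weighted combination
    of the daily extremes::

        Td = Tmax [1/2 + sqrt(1-x^2) / (2 arccos x)]
           + Tmin [1/2 - sqrt(1-x^2) / (2 arccos x)]

    Raises :class:`PolarDayError` when |x| >= 1 (sun never rises or sets).
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("Tmax must be >= Tmin")
    x = -np.tan(np.radians(latitude)) * np.tan(np.radians(solar_declination))
    if np.any(np.abs(x) >= 1.0):
        raise PolarDayError(
            "polar day/night: |tan(latitude) tan(declination)| >= 1")
    w = np.sqrt(1.0 - x ** 2) / (2.0 * np.arccos(x))
    return tmax * (0.5 + w) + tmin * (0.5 - w)


class GrowingSeason(NamedTuple):
    tg: float   # deg C
    d0: float   # kPa
    r0: float   # umol m-2 s-1
    f: float    # fraction of the year


def growing_season_stats(temperature, vpd=None, par=None,
                         base_temperature: float = 0.0) -> GrowingSeason:
    """Growing-season means of daily temperature, VPD and PAR.

    The growing season is the set of days with temperature above
    ``base_temperature`` (default 0 deg C); ``f`` is its share of the series
    length. The series should cover whole years.

    Raises :class:`DegenerateSiteError` when no day qualifies.
    """
    temperature = np.asarray(temperature, dtype=float)
    if temperature.ndim != 1 or temperature.size == 0:
        raise ValueError("temperature must be a non-empty 1-D series")
    mask = temperature > base_temperature
    n_grow = int(mask.sum())
    if n_grow == 0:
        raise DegenerateSiteError(
            f"no day above {base_temperature} deg C: site has no growing season")

    def _mean(series):
        if series is None:
            return float("nan")
        series = np.asarray(series, dtype=float)
        if series.shape != temperature.shape:
            raise ValueError("all daily series must share the temperature shape")
        return float(series[mask].mean())

    return GrowingSeason(
        tg=float(temperature[mask].mean()),
        d0=_mean(vpd),
        r0=_mean(par),
        f=n_grow / temperature.size,
    )


def par_to_daily_mol(r0, daylight_hours: float = 12.0):
    """Convert mean daytime PAR (umol m-2 s-1) to a daily total (mol m-2 d-1).

    Uses a fixed daylight duration (default 12 h); the inverse conversion is
    ``r0 = daily / (3600 * daylight_hours * 1e-6)``.
    """
    return np.asarray(r0, dtype=float) * 1e-6 * daylight_hours * 3600.0


def canopy_light(r0, lai, extinction_k: float = 0.5,
                 daylight_hours: float = 12.0):
    """Canopy-averaged daily PAR, R_LAI (mol photon m-2 day-1).

    Beer-Lambert averaging over canopy depth: the mean light on a leaf in a
    canopy of leaf area index L under extinction coefficient k is the
    above-canopy daily total times (1 - exp(-kL)) / (kL). The factor tends
    to 1 as L -> 0 and decreases strictly with L, so canopy averaging can
    never create light.
    """
    if extinction_k <= 0:
        raise ValueError("extinction_k must be positive")
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be >= 0")
    r_daily = par_to_daily_mol(r0, daylight_hours)
    kl = extinction_k * lai
    # expm1 keeps the LAI -> 0 limit exact to rounding
    factor = np.where(kl > 0, -np.expm1(-kl) / np.where(kl > 0, kl, 1.0), 1.0)
    return r_daily * factor


def water_viscosity(temperature):
    """Dynamic viscosity of liquid water (mPa s) via the Vogel equation.

    eta(T) = 0.024263 * 10^(247.8 / (T_K - 140)); accurate to ~1% over
    0-100 deg C, ample for the viscosity *ratio* the chi model needs.
    """
    tk = np.asarray(temperature, dtype=float) + 273.15
    return 2.4263e-2 * 10.0 ** (247.8 / (tk - 140.0))


def viscosity_ratio(temperature):
    """Viscosity of water at ``temperature`` relative to 25 deg C."""
    return water_viscosity(temperature) / water_viscosity(25.0)


class RubiscoKinetics(NamedTuple):
    gammastar: float  # Pa, photorespiratory compensation point
    kc: float         # Pa
    ko: float         # Pa
    po: float         # Pa, ambient O2 partial pressure
    k: float          # Pa, effective Michaelis coefficient
    eta_rel: float    # water viscosity relative to 25 deg C


def _arrhenius(ratio25, dha, temperature):
    tk = np.asarray(temperature, dtype=float) + 273.15
    return ratio25 * np.exp(dha * (tk - T_REF_K) / (T_REF_K * GAS_CONSTANT * tk))


def rubisco_kinetics(temperature, patm,
                     constants: PhysioConstants | None = None) -> RubiscoKinetics:
    """Temperature- and pressure-dependent photosynthesis parameters.

    Kc and Ko follow Arrhenius scaling from their 25 deg C reference values;
    Gamma* additionally scales linearly with total pressure (it tracks the
    O2 partial pressure). The effective Michaelis coefficient combines them:
    K = Kc (1 + Po / Ko).

    Temperatures outside [-10, 45] deg C trigger an extrapolation warning,
    not an error. ``patm`` in kPa.
    """
    constants = constants or PhysioConstants()
    temperature = np.asarray(temperature, dtype=float)
    patm = np.asarray(patm, dtype=float)
    if np.any(patm <= 0):
        raise PhysicalDomainError("patm must be positive")
    if np.any((temperature < -10.0) | (temperature > 45.0)):
        warnings.warn("temperature outside [-10, 45] deg C: kinetic "
                      "parameters are extrapolated", stacklevel=2)
    kc = _arrhenius(constants.kc25, constants.dha_kc, temperature)
    ko = _arrhenius(constants.ko25, constants.dha_ko, temperature)
    gammastar = (_arrhenius(constants.gammastar25, constants.dha_gammastar,
                            temperature) * patm / P0_KPA)
    po = constants.o2_mole_fraction * patm * 1000.0
    k = kc * (1.0 + po / ko)
    return RubiscoKinetics(gammastar=gammastar, kc=kc, ko=ko, po=po, k=k,
                           eta_rel=viscosity_ratio(temperature))
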
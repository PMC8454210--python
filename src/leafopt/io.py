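"""CSV schemas, strict validation and the monthly-climatology derivation.

Tables travel as UTF-8 comma-separated files with a mandatory header and
'.' decimals. Two input schemas are validated on read:

sites.csv
    ``site_id, elevation_m, latitude_deg`` plus either the derived
    bioclimate columns (``tg, tdj, d0, r0, lai, r_lai, f, alpha_p`` and
    optionally ``patm, ca``) or a 12-month climatology
    (``tmax_01..tmax_12, tmin_01.., vap_01.., sun_01.., pre_01..`` with
    ``lai``, ``alpha_p``) from which the bioclimate is derived.

traits.csv
    ``site_id, species, growth_form, leaf_habit, n_fixer`` plus any of
    ``ma, narea, vcmax, vcmax25, d13c, chi``.

Validation failures name the file and the offending column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bioclim import (SiteEnvironment, air_pressure, ambient_co2, canopy_light,
                      daytime_temperature, growing_season_stats)
from .constants import PhysioConstants
from .exceptions import SchemaError

__all__ = ["MonthlyClimatology", "read_sites", "write_sites", "read_traits",
           "sites_from_frame", "derive_bioclim"]

_DEFAULT = PhysioConstants()

SITE_KEY_COLUMNS = ("site_id", "elevation_m", "latitude_deg")
BIOCLIM_COLUMNS = ("tg", "tdj", "d0", "r0", "lai", "r_lai", "f", "alpha_p")
MONTHLY_PREFIXES = ("tmax", "tmin", "vap", "sun", "pre")
TRAIT_KEY_COLUMNS = ("site_id", "species")
TRAIT_VALUE_COLUMNS = ("ma", "narea", "vcmax", "vcmax25", "d13c", "chi")

#: average solar declination per month (degrees), mid-month values
_DECLINATION = (-20.9, -13.0, -2.4, 9.4, 18.8, 23.1,
                21.2, 13.5, 2.2, -9.6, -18.9, -23.0)


@dataclass(frozen=True)
class MonthlyClimatology:
    """Twelve months of climate normals for one site.

    Arrays of length 12: daily maximum and minimum temperature (deg C),
    water vapour pressure (kPa), sunshine-hours fraction (0-1) and
    precipitation (mm).
    """

    tmax: np.ndarray
    tmin: np.ndarray
    vapor_pressure: np.ndarray
    sunshine_fraction: np.ndarray
    precipitation: np.ndarray

    def __post_init__(self):
        for name in ("tmax", "tmin", "vapor_pressure", "sunshine_fraction",
                     "precipitation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
        if np.any(self.tmax < self.tmin):
            raise ValueError("Tmax must be >= Tmin in every month")
        if np.any((self.sunshine_fraction < 0) | (self.sunshine_fraction > 1)):
            raise ValueError("sunshine_fraction must lie in [0, 1]")
        if np.any(self.precipitation < 0):
            raise ValueError("precipitation must be >= 0")


def _require(df: pd.DataFrame, columns, path: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(str(path), col)


def read_sites(path: str | Path,
               constants: PhysioConstants | None = None) -> pd.DataFrame:
    """Load and validate sites.csv, deriving bioclimate where needed."""
    constants = constants or _DEFAULT
    df = pd.read_csv(path)
    _require(df, SITE_KEY_COLUMNS, path)
    has_bioclim = all(c in df.columns for c in BIOCLIM_COLUMNS)
    has_monthly = all(f"{p}_{m:02d}" in df.columns
                      for p in MONTHLY_PREFIXES for m in range(1, 13))
    if not has_bioclim and not has_monthly:
        missing = next(c for c in BIOCLIM_COLUMNS if c not in df.columns)
        raise SchemaError(str(path), missing,
                          f"{path}: neither bioclimate column {missing!r} nor "
                          "a full monthly climatology present")
    if not has_bioclim:
        df = _derive_from_monthly(df, path, constants)
    if "patm" not in df.columns:
        df["patm"] = air_pressure(df["elevation_m"].to_numpy(dtype=float))
    if "ca" not in df.columns:
        df["ca"] = ambient_co2(df["patm"].to_numpy(dtype=float),
                               constants.co2_mole_fraction * 1e6)
    return df


def _derive_from_monthly(df: pd.DataFrame, path, constants) -> pd.DataFrame:
    _require(df, ("lai", "alpha_p"), path)
    rows = []
    for _, row in df.iterrows():
        clim = MonthlyClimatology(
            tmax=row[[f"tmax_{m:02d}" for m in range(1, 13)]].to_numpy(float),
            tmin=row[[f"tmin_{m:02d}" for m in range(1, 13)]].to_numpy(float),
            vapor_pressure=row[[f"vap_{m:02d}" for m in range(1, 13)]].to_numpy(float),
            sunshine_fraction=row[[f"sun_{m:02d}" for m in range(1, 13)]].to_numpy(float),
            precipitation=row[[f"pre_{m:02d}" for m in range(1, 13)]].to_numpy(float),
        )
        derived = derive_bioclim(clim, float(row["latitude_deg"]),
                                 lai=float(row["lai"]), constants=constants)
        rows.append(derived)
    return pd.concat([df.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


def _saturation_vp(temperature):
    t = np.asarray(temperature, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def derive_bioclim(clim: MonthlyClimatology, latitude: float,
                   lai: float = 0.0,
                   constants: PhysioConstants | None = None,
                   par_clear_sky: float = 800.0) -> dict:
    """Growing-season bioclimate from a monthly climatology.

    Monthly normals are linearly interpolated to a 365-day series
    (mid-month anchors, periodic), then averaged over days with mean
    temperature above the growing-season baseline. Daily PAR uses a simple
    sunshine-duration scaling of a clear-sky value,
    ``R0 = par_clear_sky * (0.25 + 0.50 * sunshine_fraction)``
    (Angstrom-Prescott coefficients). July daytime temperature comes from
    the sine-curve diurnal model at the July declination.
    """
    constants = constants or _DEFAULT
    mid = (np.arange(12) + 0.5) * 365.0 / 12.0
    days = np.arange(365, dtype=float)

    def interp(monthly):
        # periodic interpolation between mid-month anchors
        xp = np.concatenate([[mid[-1] - 365.0], mid, [mid[0] + 365.0]])
        fp = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
        return np.interp(days, xp, fp)

    tmean = interp((clim.tmax + clim.tmin) / 2.0)
    vap = interp(clim.vapor_pressure)
    sun = interp(clim.sunshine_fraction)
    vpd = np.maximum(_saturation_vp(tmean) - vap, 0.0)
    par = par_clear_sky * (0.25 + 0.50 * sun)
    gs = growing_season_stats(tmean, vpd=vpd, par=par,
                              base_temperature=constants.gs_base_temperature)
    tdj = float(daytime_temperature(clim.tmax[6], clim.tmin[6], latitude,
                                    _DECLINATION[6]))
    r_lai = float(canopy_light(gs.r0, lai, constants.extinction_k,
                               constants.daylight_hours))
    return {"tg": gs.tg, "tdj": tdj, "d0": max(gs.d0, 1e-3), "r0": gs.r0,
            "r_lai": r_lai, "f": gs.f}


def sites_from_frame(df: pd.DataFrame) -> list[SiteEnvironment]:
    """Materialise :class:`SiteEnvironment` objects from a validated frame."""
    sites = []
    for _, row in df.iterrows():
        sites.append(SiteEnvironment(
            site_id=str(row["site_id"]), elevation=float(row["elevation_m"]),
            latitude=float(row["latitude_deg"]), tg=float(row["tg"]),
            tdj=float(row["tdj"]), d0=float(row["d0"]), r0=float(row["r0"]),
            lai=float(row["lai"]), r_lai=float(row["r_lai"]),
            f=float(row["f"]), alpha_p=float(row["alpha_p"]),
            patm=float(row["patm"]) if "patm" in row else None,
            ca=float(row["ca"]) if "ca" in row else None,
        ))
    return sites


def write_sites(sites, path: str | Path) -> None:
    from .synthetic import sites_frame
    sites_frame(sites).to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Load and validate traits.csv."""
    df = pd.read_csv(path)
    _require(df, TRAIT_KEY_COLUMNS, path)
    if not any(c in df.columns for c in TRAIT_VALUE_COLUMNS):
        raise SchemaError(str(path), "ma",
                          f"{path}: no trait value column present "
                          f"(expected one of {TRAIT_VALUE_COLUMNS})")
    if "n_fixer" in df.columns:
        df["n_fixer"] = df["n_fixer"].astype(bool)
    return df
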
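"""One-at-a-time attribution of trait differences to environmental drivers.

Three-step procedure: (1) build a baseline "average site" by averaging each
driver across the transect; (2) move one driver at a time from its baseline
value to the target site's value and re-run the trait model; (3) report the
difference from the baseline prediction as that driver's contribution.

Driver sets per trait:

* chi — air pressure (with elevation), daytime temperature, vapour
  pressure deficit;
* Vcmax25 — air pressure, daytime temperature, radiation, and chi itself
  (chi enters the coordination model as an input);
* Ma — growth temperature, canopy-averaged radiation, growing-season
  length (a proxy for leaf longevity), and moisture.

The trait models are not additive in their drivers, so one-at-a-time
contributions need not sum to the full site-minus-baseline difference; the
residual is reported explicitly as an ``interaction`` row rather than folded
into any driver. For the deciduous-LMA model in log space the decomposition
is exact and the interaction vanishes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bioclim import SiteEnvironment
from .constants import PhysioConstants
from .exceptions import ConfigurationError
from .models import chi_optimal, lma_deciduous, vcmax25_predicted

__all__ = ["TRAIT_DRIVERS", "average_site", "decompose", "contribution_table"]

_DEFAULT = PhysioConstants()

#: Drivers perturbed for each trait, in reporting order.
TRAIT_DRIVERS: dict[str, tuple[str, ...]] = {
    "chi": ("pressure", "temperature", "d0"),
    "vcmax25": ("pressure", "temperature", "r0", "chi"),
    "ma": ("temperature", "r_lai", "f", "alpha_p"),
}

_MEAN_FIELDS = ("elevation", "latitude", "tg", "tdj", "d0", "r0", "lai",
                "r_lai", "f", "alpha_p")


def average_site(sites: Sequence[SiteEnvironment] | Iterable[SiteEnvironment],
                 site_id: str = "average") -> SiteEnvironment:
    """Arithmetic mean of every driver field across sites.

    Pressure and ambient CO2 are *recomputed* from the mean elevation, not
    averaged: the barometric formula is convex, so the mean of pressures
    differs from the pressure at mean elevation, and derived fields must
    stay consistent with the drivers they derive from.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to average")
    means = {f: float(np.mean([getattr(s, f) for s in sites])) for f in _MEAN_FIELDS}
    return SiteEnvironment(site_id=site_id, **means)


def _set_driver(baseline: SiteEnvironment, site: SiteEnvironment,
                driver: str, temperature_field: str,
                recompute_ca: bool = True) -> SiteEnvironment:
    """Baseline environment with one driver moved to the site's value."""
    if driver == "pressure":
        if recompute_ca:
            return baseline.replace(elevation=site.elevation, patm=site.patm,
                                    ca=site.ca)
        return baseline.replace(elevation=site.elevation, patm=site.patm)
    if driver == "temperature":
        return baseline.replace(**{temperature_field:
                                   getattr(site, temperature_field)})
    if driver in ("d0", "r0", "r_lai", "f", "alpha_p"):
        return baseline.replace(**{driver: getattr(site, driver)})
    raise ConfigurationError(f"unknown driver {driver!r}")


def _chi_model(env: SiteEnvironment, constants, basis_field: str) -> float:
    t = getattr(env, basis_field)
    return float(chi_optimal(t, env.d0, env.patm, env.ca, constants))


def decompose(site: SiteEnvironment, baseline: SiteEnvironment, trait: str,
              constants: PhysioConstants | None = None,
              temperature_basis: str | None = None,
              log_scale: bool = False,
              recompute_ca: bool = True) -> pd.DataFrame:
    """Per-driver contributions to a trait difference from the baseline.

    Returns a long-format frame with one row per driver plus an
    ``interaction`` row, and columns ``site_id, trait, driver, delta,
    baseline, total_delta``. ``log_scale`` differences ln(trait) instead of
    the trait itself (natural for the multiplicative LMA model, where it
    makes the decomposition exact).

    ``recompute_ca`` controls whether perturbing pressure also carries the
    pressure-dependent ambient CO2 partial pressure (default: yes — ca is
    not an independent driver).
    """
    constants = constants or _DEFAULT
    if trait not in TRAIT_DRIVERS:
        raise ConfigurationError(
            f"unknown trait {trait!r}; expected one of {sorted(TRAIT_DRIVERS)}")
    if temperature_basis is None:
        temperature_basis = "tg" if trait == "ma" else "tdj"
    basis_field = {"tdj": "tdj", "tg": "tg"}.get(temperature_basis)
    if basis_field is None:
        raise ConfigurationError(f"bad temperature_basis {temperature_basis!r}")

    def evaluate(env: SiteEnvironment, chi_value: float | None = None) -> float:
        if trait == "chi":
            value = _chi_model(env, constants, basis_field)
        elif trait == "vcmax25":
            chi_in = (chi_value if chi_value is not None
                      else _chi_model(env, constants, basis_field))
            value = float(vcmax25_predicted(env, chi_in, constants,
                                            temperature_basis=temperature_basis))
        else:  # ma
            value = float(lma_deciduous(env.r_lai, env.f,
                                        getattr(env, basis_field),
                                        env.alpha_p, constants.lma_coeffs))
        return float(np.log(value)) if log_scale else value

    chi_baseline = (_chi_model(baseline, constants, basis_field)
                    if trait == "vcmax25" else None)
    chi_site = (_chi_model(site, constants, basis_field)
                if trait == "vcmax25" else None)

    base_value = evaluate(baseline, chi_baseline)
    total = evaluate(site, chi_site) - base_value

    rows = []
    for driver in TRAIT_DRIVERS[trait]:
        if driver == "chi":
            # chi is an input to the Vcmax model, not an environment field:
            # substitute the site's predicted chi into the baseline model
            delta = evaluate(baseline, chi_site) - base_value
        else:
            perturbed = _set_driver(baseline, site, driver, basis_field,
                                    recompute_ca)
            delta = evaluate(perturbed, chi_baseline) - base_value
        rows.append({"site_id": site.site_id, "trait": trait, "driver": driver,
                     "delta": delta, "baseline": base_value,
                     "total_delta": total})
    interaction = total - sum(r["delta"] for r in rows)
    rows.append({"site_id": site.site_id, "trait": trait,
                 "driver": "interaction", "delta": interaction,
                 "baseline": base_value, "total_delta": total})
    return pd.DataFrame(rows)


def contribution_table(sites: Sequence[SiteEnvironment],
                       traits: Sequence[str] = ("chi", "vcmax25", "ma"),
                       constants: PhysioConstants | None = None,
                       log_scale_ma: bool = True) -> pd.DataFrame:
    """Full transect x trait contribution table against the average-site
    baseline (deltas for Ma in log space by default, where the model is
    additive)."""
    baseline = average_site(sites)
    frames = [
        decompose(site, baseline, trait, constants,
                  log_scale=(trait == "ma" and log_scale_ma))
        for site in sites for trait in traits
    ]
    return pd.concat(frames, ignore_index=True)
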
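"""Synthetic elevation transects and species-level trait tables.

The generator emulates the statistical structure of a high-relief montane
transect: 18 sites from ~1100 to ~4400 m, temperatures declining
monotonically with elevation, a hump-shaped moisture profile (the lowest
and uppermost sites drier than mid-elevations, as in deep valley systems
where both valley floors and alpine ridges miss the orographic rainfall
belt), radiation increasing and leaf area index and growing-season length
decreasing with elevation.

Species-level traits are the optimality-model predictions for the site
plus independent lognormal noise — positive-valued traits with CV-style
dispersion. Leaf d13C is back-computed from each species' generated chi by
inverting the isotope-discrimination model, so the isotope pathway of the
pipeline is exercised end to end. Everything is deterministic under the
scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bioclim import SiteEnvironment, canopy_light
from .constants import PhysioConstants
from .models import (chi_optimal, delta13c_leaf, fv_instantaneous,
                     lma_deciduous, narea_simple, vcmax25_predicted)

__all__ = ["TransectScenario", "generate_sites", "generate_traits",
           "sites_frame", "lma_calibration_table", "narea_calibration_table"]

_DEFAULT = PhysioConstants()


def _saturation_vp(temperature):
    """Saturation vapour pressure (kPa), Magnus form."""
    t = np.asarray(temperature, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


@dataclass(frozen=True)
class TransectScenario:
    """A stated synthetic world: one montane transect and its noise levels."""

    n_sites: int = 18
    elevation_min: float = 1143.0   # m
    elevation_max: float = 4361.0   # m
    latitude: float = 29.6          # degrees N

    # temperature profiles (deg C at the lowest site; K km-1 lapse)
    tdj_low: float = 22.0
    tdj_lapse: float = 5.5
    tg_low: float = 16.0
    #: effective lapse of the growing-season mean — flatter than the free-air
    #: lapse because the season itself shortens and truncates cold days
    tg_lapse: float = 3.3

    # hump-shaped moisture profile alpha_p(z) = base + amp exp(-((z-peak)/width)^2)
    alpha_base: float = 0.55
    alpha_amp: float = 0.30
    alpha_peak_elevation: float = 2800.0
    alpha_width: float = 1100.0

    # humidity ties VPD to the moisture profile: rh = rh_base + rh_slope * alpha_p
    rh_base: float = 0.40
    rh_slope: float = 0.50

    # radiation and canopy profiles
    r0_low: float = 380.0           # umol m-2 s-1 at the lowest site
    r0_gradient: float = 25.0       # umol m-2 s-1 per km (clearer sky aloft)
    lai_low: float = 4.5
    lai_gradient: float = -0.9      # per km
    f_low: float = 0.95
    f_gradient: float = -0.11       # per km

    # species sampling per site
    n_tree: int = 5
    n_shrub: int = 5
    n_forb: int = 5
    evergreen_fraction: float = 0.2
    n_fixer_fraction: float = 0.1
    evergreen_ma_factor: float = 1.8

    # residual standard deviations on the log scale
    sd_ln_ma: float = 0.2
    sd_ln_vcmax25: float = 0.15
    sd_ln_chi: float = 0.05
    sd_ln_narea: float = 0.10
    n_fixer_offset: float = 0.3     # g m-2, additive on Narea

    seed: int = 0

    #: site-to-site scatter (relative) applied to moisture/radiation profiles
    site_scatter: float = 0.03

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        for name in ("sd_ln_ma", "sd_ln_vcmax25", "sd_ln_chi", "sd_ln_narea"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "TransectScenario":
        import dataclasses
        return dataclasses.replace(self, **kw)


def generate_sites(scenario: TransectScenario,
                   constants: PhysioConstants | None = None
                   ) -> list[SiteEnvironment]:
    """Build the transect's site environments.

    Temperatures follow the lapse rates exactly (monotone by construction);
    moisture, humidity-derived VPD, radiation and LAI carry small seeded
    site-to-site scatter. Pressure and ambient CO2 come from the barometric
    formula and a fixed CO2 mole fraction.
    """
    constants = constants or _DEFAULT
    rng = np.random.default_rng(scenario.seed)
    z = np.linspace(scenario.elevation_min, scenario.elevation_max,
                    scenario.n_sites)
    dz_km = (z - scenario.elevation_min) / 1000.0

    tdj = scenario.tdj_low - scenario.tdj_lapse * dz_km
    tg = scenario.tg_low - scenario.tg_lapse * dz_km

    alpha = (scenario.alpha_base + scenario.alpha_amp
             * np.exp(-((z - scenario.alpha_peak_elevation)
                        / scenario.alpha_width) ** 2))
    scatter = 1.0 + scenario.site_scatter * rng.standard_normal((4, scenario.n_sites))
    alpha = alpha * scatter[0]
    rh = np.clip(scenario.rh_base + scenario.rh_slope * alpha, 0.05, 0.98)
    d0 = np.maximum(_saturation_vp(tdj) * (1.0 - rh) * scatter[1], 0.05)
    r0 = (scenario.r0_low + scenario.r0_gradient * dz_km) * scatter[2]
    lai = np.maximum((scenario.lai_low + scenario.lai_gradient * dz_km)
                     * scatter[3], 0.2)
    f = np.clip(scenario.f_low + scenario.f_gradient * dz_km, 0.05, 1.0)
    r_lai = canopy_light(r0, lai, constants.extinction_k,
                         constants.daylight_hours)

    return [
        SiteEnvironment(
            site_id=f"S{i + 1:02d}", elevation=float(z[i]),
            latitude=scenario.latitude, tg=float(tg[i]), tdj=float(tdj[i]),
            d0=float(d0[i]), r0=float(r0[i]), lai=float(lai[i]),
            r_lai=float(r_lai[i]), f=float(f[i]), alpha_p=float(alpha[i]),
        )
        for i in range(scenario.n_sites)
    ]


def sites_frame(sites: Sequence[SiteEnvironment]) -> pd.DataFrame:
    """Site table in the documented sites.csv schema."""
    return pd.DataFrame([{
        "site_id": s.site_id, "elevation_m": s.elevation,
        "latitude_deg": s.latitude, "tg": s.tg, "tdj": s.tdj, "d0": s.d0,
        "r0": s.r0, "lai": s.lai, "r_lai": s.r_lai, "f": s.f,
        "alpha_p": s.alpha_p, "patm": s.patm, "ca": s.ca,
    } for s in sites])


def generate_traits(sites: Sequence[SiteEnvironment],
                    scenario: TransectScenario,
                    constants: PhysioConstants | None = None) -> pd.DataFrame:
    """Species-level trait table around the optimality predictions.

    For each site, ``n_tree + n_shrub + n_forb`` species are drawn. Woody
    species are evergreen with probability ``evergreen_fraction`` (forbs are
    always deciduous); evergreen leaf mass is inflated by
    ``evergreen_ma_factor`` over the deciduous prediction. Nitrogen fixers
    receive an additive Narea offset. With all noise levels at zero, site
    means reproduce the model predictions exactly.
    """
    constants = constants or _DEFAULT
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    records = []
    forms = (["tree"] * scenario.n_tree + ["shrub"] * scenario.n_shrub
             + ["forb"] * scenario.n_forb)
    for site in sites:
        chi_site = float(chi_optimal(site.tdj, site.d0, site.patm, site.ca,
                                     constants))
        vcmax25_site = float(vcmax25_predicted(site, chi_site, constants))
        ma_site = float(lma_deciduous(site.r_lai, site.f, site.tg,
                                      site.alpha_p, constants.lma_coeffs))
        fv = float(fv_instantaneous(site.tdj, constants))
        for j, form in enumerate(forms):
            evergreen = (form != "forb"
                         and rng.random() < scenario.evergreen_fraction)
            n_fixer = rng.random() < scenario.n_fixer_fraction
            chi = chi_site * np.exp(rng.normal(0.0, scenario.sd_ln_chi))
            vcmax25 = vcmax25_site * np.exp(
                rng.normal(0.0, scenario.sd_ln_vcmax25))
            ma = ma_site * np.exp(rng.normal(0.0, scenario.sd_ln_ma))
            if evergreen:
                ma *= scenario.evergreen_ma_factor
            narea = (float(narea_simple(ma, vcmax25,
                                        coeffs=constants.narea_coeffs))
                     * np.exp(rng.normal(0.0, scenario.sd_ln_narea)))
            if n_fixer:
                narea += scenario.n_fixer_offset
            records.append({
                "site_id": site.site_id,
                "species": f"{site.site_id}_sp{j + 1:02d}",
                "growth_form": form,
                "leaf_habit": "evergreen" if evergreen else "deciduous",
                "n_fixer": n_fixer,
                "ma": ma,
                "narea": narea,
                "vcmax25": vcmax25,
                "vcmax": vcmax25 * fv,
                "d13c": float(delta13c_leaf(chi, site.tdj, site.patm, site.ca,
                                            constants=constants)),
                "chi": chi,
            })
    return pd.DataFrame(records)


def lma_calibration_table(n: int, noise_sd: float, seed: int,
                          coeffs: tuple[float, ...] | None = None
                          ) -> pd.DataFrame:
    """Independent design for LMA-coefficient recovery experiments.

    Predictors are drawn uniformly over realistic ranges (R_LAI 5-40
    mol m-2 d-1, f 0.3-1, Tg 2-25 deg C, alpha_p 0.3-1.2) so the design is
    well conditioned regardless of transect collinearity; ln(Ma) is the
    deciduous model plus normal noise of sd ``noise_sd``.
    """
    coeffs = coeffs if coeffs is not None else _DEFAULT.lma_coeffs
    rng = np.random.default_rng(seed)
    r_lai = rng.uniform(5.0, 40.0, n)
    f = rng.uniform(0.3, 1.0, n)
    tg = rng.uniform(2.0, 25.0, n)
    alpha_p = rng.uniform(0.3, 1.2, n)
    ma = lma_deciduous(r_lai, f, tg, alpha_p, coeffs) * np.exp(
        rng.normal(0.0, noise_sd, n))
    return pd.DataFrame({"r_lai": r_lai, "f": f, "tg": tg,
                         "alpha_p": alpha_p, "ma": ma})


def narea_calibration_table(n: int, noise_sd: float, seed: int,
                            coeffs: tuple[float, float] | None = None,
                            n_fixer_offset: float = 0.0,
                            n_fixer_fraction: float = 0.0) -> pd.DataFrame:
    """Independent design for Narea-coefficient recovery experiments."""
    coeffs = coeffs if coeffs is not None else _DEFAULT.narea_coeffs
    rng = np.random.default_rng(seed)
    ma = rng.uniform(20.0, 200.0, n)
    vcmax25 = rng.uniform(10.0, 120.0, n)
    n_fixer = rng.random(n) < n_fixer_fraction
    narea = (coeffs[0] * ma + coeffs[1] * vcmax25
             + np.where(n_fixer, n_fixer_offset, 0.0)
             + rng.normal(0.0, noise_sd, n))
    return pd.DataFrame({"ma": ma, "vcmax25": vcmax25,
                         "n_fixer": n_fixer, "narea": narea})
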
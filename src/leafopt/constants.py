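"""Physiological constants of the trait models, with their uncertainties.

All model coefficients live in one frozen dataclass so that a run is fully
described by (inputs, constants, seed). Defaults are the published values;
every one can be overridden from a YAML config file. Standard uncertainties,
where we carry them, feed the error-propagation module.

Units follow the conventions used throughout the package: pressures in Pa
unless a name says kPa, temperatures in degrees Celsius at the API surface,
photosynthetic rates in umol C m-2 s-1, leaf mass in g m-2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ConfigurationError

#: Universal gas constant, J mol-1 K-1.
GAS_CONSTANT = 8.314

#: Reference (standard) temperature, K.
T_REF_K = 298.15

#: Sea-level standard pressure, kPa.
P0_KPA = 101.325


@dataclass(frozen=True)
class PhysioConstants:
    # -- least-cost chi model --------------------------------------------
    #: ratio at 25 C of the unit costs of carboxylation vs transpiration
    beta: float = 146.0
    #: unit carbon cost of maintaining electron-transport capacity
    c_cost: float = 0.41
    #: intrinsic quantum efficiency of photosynthesis, umol C umol-1 photon
    phi0: float = 0.085

    # -- Rubisco kinetics (Bernacchi-style, 25 C references) -------------
    kc25: float = 39.97          # Pa, Michaelis constant for CO2
    ko25_kpa: float = 27.48      # kPa, Michaelis constant for O2
    gammastar25: float = 4.332   # Pa, photorespiratory compensation point
    dha_kc: float = 79_430.0     # J mol-1, activation energy of Kc
    dha_ko: float = 36_380.0     # J mol-1, activation energy of Ko
    dha_gammastar: float = 37_830.0  # J mol-1, activation energy of Gamma*
    o2_mole_fraction: float = 0.2095

    # -- instantaneous Vcmax temperature response ------------------------
    ha_v: float = 71_513.0       # J mol-1, activation energy
    hd_v: float = 200_000.0      # J mol-1, deactivation energy
    ds_slope: float = 1.07       # J mol-1 K-2, entropy slope vs Tg (deg C)
    ds_intercept: float = 668.39  # J mol-1 K-1

    # -- leaf economics (LMA) --------------------------------------------
    u: float = 8889.0            # dimensionless longevity scaling
    k_scale: float = 30.0        # g biomass mol C-1
    cc: float = 1.5              # gC gC-1 leaf construction cost (see docs)
    #: fitted deciduous-LMA coefficients:
    #: (ln R_LAI, ln f, Tg, ln alpha_p, intercept)
    lma_coeffs: tuple[float, float, float, float, float] = (
        1.22, 0.78, -0.06, -0.60, 1.70)

    # -- isotope discrimination ------------------------------------------
    a_s: float = 4.4             # permil, diffusion in air
    b_prime: float = 30.0        # permil, Rubisco carboxylation
    f_prime: float = 16.0        # permil, photorespiration
    d13c_air: float = -8.0       # permil, atmospheric CO2

    # -- leaf nitrogen ----------------------------------------------------
    #: simple model: Narea = a_ma * Ma + a_v * Vcmax25
    narea_coeffs: tuple[float, float] = (0.02, 0.003)
    #: structural N: Nstructure = c0 * Ma ** c1
    nstruct_coeffs: tuple[float, float] = (10 ** -2.67, 0.99)
    #: Rubisco N per unit Vcmax25
    nrub_slope: float = 0.003135
    #: metabolic-N allocation multiplier of Nrubisco
    rubisco_alloc: float = 7.2           # locally refit value
    rubisco_alloc_original: float = 9.5  # published global value

    # -- environment plumbing --------------------------------------------
    co2_mole_fraction: float = 410e-6  # mol mol-1, ambient CO2
    extinction_k: float = 0.5          # canopy light extinction coefficient
    daylight_hours: float = 12.0       # h, convention for daily PAR totals
    gs_base_temperature: float = 0.0   # deg C, growing-season threshold

    # -- standard uncertainties u(n_i) for propagation --------------------
    uncertainties: Mapping[str, float] = field(
        default_factory=lambda: {"beta": 30.0, "c_cost": 0.08, "phi0": 0.008}
    )

    @property
    def ko25(self) -> float:
        """Ko reference value in Pa."""
        return self.ko25_kpa * 1000.0

    def replace(self, **overrides: Any) -> "PhysioConstants":
        """Return a copy with the given fields replaced."""
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigurationError(f"unknown constant(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_constants(path: str | Path | None = None,
                   overrides: Mapping[str, Any] | None = None) -> PhysioConstants:
    """Build constants from defaults, an optional YAML file, and overrides.

    The YAML file holds a flat mapping of field name to value (lists are
    converted to tuples). Unknown keys are rejected, not ignored.
    """
    consts = PhysioConstants()
    merged: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        merged.update(data)
    if overrides:
        merged.update(overrides)
    merged = {k: tuple(v) if isinstance(v, list) else v for k, v in merged.items()}
    return consts.replace(**merged) if merged else consts
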
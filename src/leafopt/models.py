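"""Optimality-based trait models: chi, Vcmax25, LMA and Narea.

The computational core of the package. Four first-principles models predict
leaf traits from growing-season bioclimate alone, with no site-level
calibration:

* **chi** — the least-cost hypothesis: leaves minimise the combined unit
  costs of maintaining transpiration and carboxylation capacity, which
  fixes the ratio of internal to ambient CO2 partial pressure as a function
  of temperature, vapour pressure deficit and pressure.
* **Vcmax25** — the coordination hypothesis: Rubisco-limited and
  light-limited photosynthesis are equal under average daytime conditions,
  so carboxylation capacity tracks absorbed light, CO2 and temperature.
* **Ma (LMA)** — maximising lifetime net carbon gain of a leaf ties leaf
  mass per area to absorbed light, leaf longevity, growth temperature and
  (empirically) moisture. For deciduous species leaf longevity is indexed
  by growing-season length.
* **Narea** — leaf nitrogen is the sum of a metabolic component
  proportional to Vcmax25 and a structural component proportional to Ma.

Scalar or array inputs broadcast; all outputs are deterministic functions
of (inputs, constants).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .bioclim import SiteEnvironment, rubisco_kinetics
from .constants import GAS_CONSTANT, T_REF_K, PhysioConstants
from .exceptions import PhysicalDomainError

__all__ = [
    "chi_optimal",
    "chi_from_isotope",
    "IsotopeChi",
    "vcmax_coordination",
    "fv_instantaneous",
    "vcmax25_predicted",
    "lma_theoretical",
    "lma_deciduous",
    "narea_simple",
    "narea_two_step",
    "predict_site",
    "PredictionSet",
]

_DEFAULT = PhysioConstants()


def chi_optimal(temperature, d0_kpa, patm, ca,
                constants: PhysioConstants | None = None):
    """Optimal ratio of internal to ambient CO2 partial pressure.

    Least-cost solution::

        chi = G/ca + xi (1 - G/ca) / (xi + sqrt(D0)),
        xi  = sqrt(beta (K + G) / (1.6 eta))

    with G the photorespiratory compensation point, K the effective
    Michaelis coefficient, eta the water-viscosity ratio and D0 the vapour
    pressure deficit **in Pa** inside the square root (the argument is in
    kPa and converted here). chi lies strictly between G/ca and 1 and
    decreases with D0.

    Parameters
    ----------
    temperature : deg C (growth temperature; July daytime mean recommended)
    d0_kpa : kPa, growing-season mean vapour pressure deficit (> 0)
    patm : kPa
    ca : Pa, ambient CO2 partial pressure
    """
    constants = constants or _DEFAULT
    d0_kpa = np.asarray(d0_kpa, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(d0_kpa <= 0):
        raise ValueError("D0 must be positive")
    kin = rubisco_kinetics(temperature, patm, constants)
    if np.any(ca <= kin.gammastar):
        raise PhysicalDomainError(
            "ca <= Gamma*: no positive assimilation is possible at this site")
    xi = np.sqrt(constants.beta * (kin.k + kin.gammastar) / (1.6 * kin.eta_rel))
    gamma_ratio = kin.gammastar / ca
    return gamma_ratio + xi * (1.0 - gamma_ratio) / (xi + np.sqrt(d0_kpa * 1000.0))


class IsotopeChi(NamedTuple):
    chi: float
    #: True where chi falls outside (0, 1.2); values are never clipped
    flagged: bool


def chi_from_isotope(d13c_leaf, d13c_air=None, temperature=25.0,
                     patm=101.325, ca=40.0,
                     constants: PhysioConstants | None = None) -> IsotopeChi:
    """chi estimated from leaf carbon-isotope composition.

    Discrimination relative to source air,
    Delta = (d_air - d_leaf) / (1 + d_leaf / 1000), is mapped to chi via the
    simplified fractionation model with diffusion (a_s), carboxylation (b')
    and photorespiration (f') terms::

        chi = (Delta + f' G / ca - a_s) / (b' - a_s)

    Out-of-range values (outside (0, 1.2)) are returned as-is with a quality
    flag so that filtering is an explicit pipeline step, never silent.
    """
    constants = constants or _DEFAULT
    if d13c_air is None:
        d13c_air = constants.d13c_air
    d13c_leaf = np.asarray(d13c_leaf, dtype=float)
    delta = (d13c_air - d13c_leaf) / (1.0 + d13c_leaf / 1000.0)
    kin = rubisco_kinetics(temperature, patm, constants)
    chi = ((delta + constants.f_prime * kin.gammastar / np.asarray(ca, dtype=float)
            - constants.a_s)
           / (constants.b_prime - constants.a_s))
    flagged = (chi <= 0.0) | (chi >= 1.2)
    return IsotopeChi(chi=chi, flagged=flagged)


def delta13c_leaf(chi, temperature, patm, ca, d13c_air=None,
                  constants: PhysioConstants | None = None):
    """Invert the isotope model: leaf d13C that would yield the given chi.

    Round-trips with :func:`chi_from_isotope` to machine precision; used by
    the synthetic-data generator so the isotope pathway is testable.
    """
    constants = constants or _DEFAULT
    if d13c_air is None:
        d13c_air = constants.d13c_air
    kin = rubisco_kinetics(temperature, patm, constants)
    delta = (np.asarray(chi, dtype=float) * (constants.b_prime - constants.a_s)
             + constants.a_s - constants.f_prime * kin.gammastar / ca)
    return (d13c_air - delta) / (1.0 + delta / 1000.0)


def vcmax_coordination(temperature, r0, chi, ca, patm,
                       constants: PhysioConstants | None = None):
    """Carboxylation capacity at growth temperature (umol C m-2 s-1).

    The coordination hypothesis equates Rubisco- and light-limited rates
    under average daytime conditions::

        Vcmax = phi0 R0 (ci + K) / (ci + 2 G) sqrt(1 - (c / m)^(2/3)),
        m = (ci - G) / (ci + 2 G)

    Linear in absorbed light R0 (umol photon m-2 s-1). Raises
    :class:`PhysicalDomainError` when ci <= G or when m <= c (light too dim
    or ci too low for the electron-transport cost to be paid).
    """
    constants = constants or _DEFAULT
    r0 = np.asarray(r0, dtype=float)
    ci = np.asarray(chi, dtype=float) * np.asarray(ca, dtype=float)
    kin = rubisco_kinetics(temperature, patm, constants)
    if np.any(ci <= kin.gammastar):
        raise PhysicalDomainError("ci <= Gamma*: chi * ca must exceed the "
                                  "photorespiratory compensation point")
    m = (ci - kin.gammastar) / (ci + 2.0 * kin.gammastar)
    if np.any(m <= constants.c_cost):
        raise PhysicalDomainError(
            f"m = (ci - G)/(ci + 2G) = {np.min(m):.4f} <= c = "
            f"{constants.c_cost}: inequality m > c fails (ci too low)")
    root = np.sqrt(1.0 - (constants.c_cost / m) ** (2.0 / 3.0))
    return constants.phi0 * r0 * (ci + kin.k) / (ci + 2.0 * kin.gammastar) * root


def fv_instantaneous(tg, constants: PhysioConstants | None = None):
    """Instantaneous temperature factor fv with Vcmax = Vcmax25 * fv.

    Peaked (modified) Arrhenius response: an activation term times a
    deactivation ratio, with the entropy parameter declining linearly in
    growth temperature, dS = 668.39 - 1.07 Tg (Tg in deg C inside the linear
    relation; Kelvin in the exponentials). Equals 1 exactly at 25 deg C.
    """
    constants = constants or _DEFAULT
    tg = np.asarray(tg, dtype=float)
    tk = tg + 273.15
    ds = constants.ds_intercept - constants.ds_slope * tg
    arr = np.exp(constants.ha_v * (tk - T_REF_K) / (T_REF_K * GAS_CONSTANT * tk))
    num = 1.0 + np.exp((T_REF_K * ds - constants.hd_v) / (T_REF_K * GAS_CONSTANT))
    den = 1.0 + np.exp((tk * ds - constants.hd_v) / (tk * GAS_CONSTANT))
    return arr * num / den


def vcmax25_predicted(site: SiteEnvironment, chi=None,
                      constants: PhysioConstants | None = None,
                      temperature_basis: str = "tdj"):
    """Site-level Vcmax25 (umol C m-2 s-1) from the coordination model.

    Computes Vcmax at growth temperature then standardises to 25 deg C by
    dividing by fv. The acclimation temperature defaults to the July daytime
    mean (``tdj``), which tracks the few-week timescale on which
    photosynthetic capacity adjusts; ``tg`` selects the growing-season mean
    instead. ``chi`` defaults to the least-cost prediction at the same
    temperature.
    """
    constants = constants or _DEFAULT
    t = _basis_temperature(site, temperature_basis)
    if chi is None:
        chi = chi_optimal(t, site.d0, site.patm, site.ca, constants)
    vcmax = vcmax_coordination(t, site.r0, chi, site.ca, site.patm, constants)
    return vcmax / fv_instantaneous(t, constants)


def _basis_temperature(site: SiteEnvironment, basis: str) -> float:
    if basis == "tdj":
        return site.tdj
    if basis == "tg":
        return site.tg
    raise ValueError(f"temperature_basis must be 'tdj' or 'tg', got {basis!r}")


def lma_theoretical(i_abs, ll, temperature, ca, chi, patm,
                    constants: PhysioConstants | None = None):
    """Theoretical leaf mass per area (g m-2) from lifetime-gain optimality.

    Combining the optimal LMA-longevity trade-off, the proportionality of
    photosynthetic lifespan to Ma / Vcmax25, and coordination-predicted
    Vcmax gives::

        Ma = phi0 I_abs LL k sqrt[ (ci - G)(ci + K)
                                   / (2 u CC fv (ci + 2G)^2) ]

    Proportional to absorbed light ``i_abs`` (mol photon m-2 day-1) and
    leaf longevity ``ll`` (days). The construction-cost constant CC cancels
    from the calibrated deciduous model; this uncalibrated form exists for
    derivative and elasticity analysis, not site prediction.
    """
    constants = constants or _DEFAULT
    ci = np.asarray(chi, dtype=float) * np.asarray(ca, dtype=float)
    kin = rubisco_kinetics(temperature, patm, constants)
    if np.any(ci <= kin.gammastar):
        raise PhysicalDomainError("ci <= Gamma*")
    fv = fv_instantaneous(temperature, constants)
    inner = ((ci - kin.gammastar) * (ci + kin.k)
             / (2.0 * constants.u * constants.cc * fv
                * (ci + 2.0 * kin.gammastar) ** 2))
    return (constants.phi0 * np.asarray(i_abs, dtype=float)
            * np.asarray(ll, dtype=float) * constants.k_scale * np.sqrt(inner))


def lma_deciduous(r_lai, f, tg, alpha_p,
                  coeffs: tuple[float, ...] | None = None):
    """Deciduous leaf mass per area (g m-2) from the calibrated model.

    ln(Ma) = b_R ln(R_LAI) + b_f ln(f) + b_T Tg + b_a ln(alpha_p) + b_0,
    with default coefficients (1.22, 0.78, -0.06, -0.60, 1.70) fitted on an
    independent continental trait data set. Raises on non-positive
    log-domain arguments.
    """
    coeffs = coeffs if coeffs is not None else _DEFAULT.lma_coeffs
    r_lai = np.asarray(r_lai, dtype=float)
    f = np.asarray(f, dtype=float)
    alpha_p = np.asarray(alpha_p, dtype=float)
    for name, value in (("r_lai", r_lai), ("f", f), ("alpha_p", alpha_p)):
        if np.any(value <= 0):
            raise PhysicalDomainError(f"{name} must be positive (log-domain)")
    b_r, b_f, b_t, b_a, b_0 = coeffs
    ln_ma = (b_r * np.log(r_lai) + b_f * np.log(f)
             + b_t * np.asarray(tg, dtype=float) + b_a * np.log(alpha_p) + b_0)
    return np.exp(ln_ma)


def narea_simple(ma, vcmax25, n_fixer=False,
                 coeffs: tuple[float, float] | None = None,
                 n_fixer_offset: float = 0.0):
    """Leaf nitrogen per area (g m-2), direct linear model.

    Narea = a_ma Ma + a_v Vcmax25, defaults (0.02, 0.003), no intercept;
    nitrogen-fixing species receive ``n_fixer_offset`` (g m-2) on top when
    flagged (a calibrated offset, default 0).
    """
    coeffs = coeffs if coeffs is not None else _DEFAULT.narea_coeffs
    a_ma, a_v = coeffs
    base = a_ma * np.asarray(ma, dtype=float) + a_v * np.asarray(vcmax25, dtype=float)
    return base + np.where(np.asarray(n_fixer, dtype=bool), n_fixer_offset, 0.0)


def narea_two_step(ma, vcmax25, alloc: float | None = None,
                   constants: PhysioConstants | None = None):
    """Leaf nitrogen per area (g m-2), structural + metabolic decomposition.

    Nstructure = c0 Ma^c1 (defaults 10^-2.67, 0.99);
    Nrubisco = 0.003135 Vcmax25; Narea = alloc * Nrubisco + Nstructure with
    ``alloc`` the metabolic-N allocation multiplier (7.2 locally refit, 9.5
    published).
    """
    constants = constants or _DEFAULT
    if alloc is None:
        alloc = constants.rubisco_alloc
    c0, c1 = constants.nstruct_coeffs
    nstructure = c0 * np.asarray(ma, dtype=float) ** c1
    nrubisco = constants.nrub_slope * np.asarray(vcmax25, dtype=float)
    return alloc * nrubisco + nstructure


class PredictionSet(NamedTuple):
    """Per-site predicted traits (uncertainties attach via the uncertainty
    module, which wraps these same model functions)."""

    site_id: str
    chi: float
    vcmax25: float
    ma: float
    narea: float


def predict_site(site: SiteEnvironment,
                 constants: PhysioConstants | None = None,
                 temperature_basis_chi: str = "tdj",
                 temperature_basis_ma: str = "tg",
                 n_fixer_offset: float = 0.0) -> PredictionSet:
    """All four trait predictions for one site.

    chi and Vcmax25 use the July daytime temperature by default (fast
    acclimation), Ma the growing-season mean (leaves are built once per
    season); both bases are selectable. Narea chains the predicted Ma and
    Vcmax25 through the simple linear model.
    """
    constants = constants or _DEFAULT
    t_chi = _basis_temperature(site, temperature_basis_chi)
    chi = float(chi_optimal(t_chi, site.d0, site.patm, site.ca, constants))
    vcmax25 = float(vcmax25_predicted(site, chi, constants,
                                      temperature_basis=temperature_basis_chi))
    t_ma = _basis_temperature(site, temperature_basis_ma)
    ma = float(lma_deciduous(site.r_lai, site.f, t_ma, site.alpha_p,
                             constants.lma_coeffs))
    narea = float(narea_simple(ma, vcmax25, coeffs=constants.narea_coeffs))
    return PredictionSet(site.site_id, chi, vcmax25, ma, narea)
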
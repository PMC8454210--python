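"""Re-estimation of the free trait-model coefficients from trait tables.

Three fits mirror how the published coefficients were obtained:

* deciduous LMA: OLS of ln(Ma) on ln(R_LAI), Tg, ln(f) and ln(alpha_p);
* Narea: zero-intercept OLS on Ma and Vcmax25, optionally with an
  N-fixer indicator;
* Rubisco allocation: zero-intercept slope of metabolic nitrogen
  (Narea - Nstructure) on Nrubisco.

All fits are ordinary least squares (statsmodels), reproducible
bit-for-bit, and invariant to row order. Records with missing fields are
dropped listwise with a logged count; nothing is imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import PhysioConstants
from .exceptions import CollinearityError, InsufficientDataError

__all__ = [
    "FitResult",
    "fit_lma_coefficients",
    "fit_narea_coefficients",
    "fit_rubisco_allocation",
]

log = logging.getLogger(__name__)

_DEFAULT = PhysioConstants()


@dataclass(frozen=True)
class FitResult:
    """Coefficients with standard errors and fit quality."""

    params: dict[str, float]
    bse: dict[str, float]
    r_squared: float
    n_obs: int

    def conf_int(self, name: str, z: float = 1.96) -> tuple[float, float]:
        p, se = self.params[name], self.bse[name]
        return (p - z * se, p + z * se)


def _drop_incomplete(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    complete = df.dropna(subset=columns)
    n_dropped = len(df) - len(complete)
    if n_dropped:
        log.info("%s: dropped %d incomplete record(s) listwise", what, n_dropped)
    return complete


def _check_rank(design: pd.DataFrame) -> None:
    """Name the offending column when the design is rank deficient."""
    for col in design.columns:
        if col == "const":
            continue
        if np.ptp(design[col].to_numpy()) == 0.0:
            raise CollinearityError(col, f"column {col!r} is constant")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        # identify a column whose removal restores full column rank
        for col in design.columns:
            reduced = design.drop(columns=col).to_numpy()
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise CollinearityError(col)
        raise CollinearityError("<unknown>")


def fit_lma_coefficients(traits: pd.DataFrame) -> FitResult:
    """Refit the deciduous-LMA model on a trait table joined to bioclimate.

    Requires columns ``ma, r_lai, f, tg, alpha_p``; regresses ln(Ma) on
    ln(R_LAI), ln(f), Tg and ln(alpha_p) with intercept. Returns
    coefficients keyed ``ln_r_lai, ln_f, tg, ln_alpha_p, intercept`` in the
    same order as :attr:`PhysioConstants.lma_coeffs`.
    """
    cols = ["ma", "r_lai", "f", "tg", "alpha_p"]
    data = _drop_incomplete(traits, cols, "lma fit")
    if len(data) < 6:
        raise InsufficientDataError(
            f"need at least 6 complete records, got {len(data)}")
    design = pd.DataFrame({
        "ln_r_lai": np.log(data["r_lai"].to_numpy(dtype=float)),
        "ln_f": np.log(data["f"].to_numpy(dtype=float)),
        "tg": data["tg"].to_numpy(dtype=float),
        "ln_alpha_p": np.log(data["alpha_p"].to_numpy(dtype=float)),
    })
    _check_rank(sm.add_constant(design, has_constant="add"))
    model = sm.OLS(np.log(data["ma"].to_numpy(dtype=float)),
                   sm.add_constant(design, has_constant="add"))
    res = model.fit()
    params = dict(res.params)
    bse = dict(res.bse)
    params["intercept"] = params.pop("const")
    bse["intercept"] = bse.pop("const")
    return FitResult(params=params, bse=bse,
                     r_squared=float(res.rsquared), n_obs=int(res.nobs))


def fit_narea_coefficients(traits: pd.DataFrame,
                           include_n_fixer: bool = False) -> FitResult:
    """Zero-intercept fit of Narea on Ma and Vcmax25.

    With ``include_n_fixer`` a 0/1 indicator column ``n_fixer`` enters as an
    additive factor, capturing the extra nitrogen of nitrogen-fixing
    species at given Ma and Vcmax25.
    """
    cols = ["narea", "ma", "vcmax25"] + (["n_fixer"] if include_n_fixer else [])
    data = _drop_incomplete(traits, cols, "narea fit")
    if len(data) < 3:
        raise InsufficientDataError(
            f"need at least 3 complete records, got {len(data)}")
    design = pd.DataFrame({
        "ma": data["ma"].to_numpy(dtype=float),
        "vcmax25": data["vcmax25"].to_numpy(dtype=float),
    })
    if include_n_fixer:
        design["n_fixer"] = data["n_fixer"].to_numpy(dtype=float)
    _check_rank(design)
    res = sm.OLS(data["narea"].to_numpy(dtype=float), design).fit()
    return FitResult(params=dict(res.params), bse=dict(res.bse),
                     r_squared=float(res.rsquared), n_obs=int(res.nobs))


def fit_rubisco_allocation(traits: pd.DataFrame,
                           constants: PhysioConstants | None = None) -> float:
    """Refit the metabolic-nitrogen allocation multiplier.

    Computes Nstructure and Nrubisco from observed Ma and Vcmax25, then the
    zero-intercept slope of (Narea - Nstructure) on Nrubisco. Warns when
    more than half the implied metabolic-nitrogen values are negative (a
    data-quality signal, not an error).
    """
    constants = constants or _DEFAULT
    data = _drop_incomplete(traits, ["narea", "ma", "vcmax25"], "allocation fit")
    if len(data) < 1:
        raise InsufficientDataError("no complete records")
    c0, c1 = constants.nstruct_coeffs
    nstructure = c0 * data["ma"].to_numpy(dtype=float) ** c1
    nrubisco = constants.nrub_slope * data["vcmax25"].to_numpy(dtype=float)
    metabolic = data["narea"].to_numpy(dtype=float) - nstructure
    if np.mean(metabolic < 0) > 0.5:
        log.warning("allocation fit: %.0f%% of records imply negative "
                    "metabolic nitrogen", 100 * np.mean(metabolic < 0))
    denom = float(np.sum(nrubisco ** 2))
    if denom == 0.0:
        raise CollinearityError("vcmax25", "Nrubisco is identically zero")
    return float(np.sum(metabolic * nrubisco) / denom)
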
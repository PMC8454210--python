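"""Model evaluation: observed-vs-predicted agreement, trait dispersion, and
a multiple-regression statistical benchmark.

Site-mean aggregation defaults to deciduous species only (the evergreen
leaf-longevity needed by the LMA model is unobservable from one visit); an
``include_evergreen`` flag widens the pool for chi and Vcmax25, whose
models apply to both habits.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientDataError

__all__ = [
    "AgreementStats",
    "agreement_stats",
    "site_means",
    "cv_within_across",
    "benchmark_regression",
    "BENCHMARK_DRIVERS",
]

log = logging.getLogger(__name__)


class AgreementStats(NamedTuple):
    r: float
    rmse: float
    r_squared: float          # squared Pearson correlation (default notion)
    relative_rmse: float      # RMSE / mean(observed)
    r_squared_identity: float  # 1 - SS_res/SS_tot about the 1:1 line


def agreement_stats(observed, predicted) -> AgreementStats:
    """Agreement between paired site-mean observations and predictions.

    Pearson r, RMSE, R^2 (two notions: squared correlation, and variance
    explained about the 1:1 line, which penalises bias) and RMSE relative
    to the observed mean. Requires >= 3 complete pairs; a zero-variance
    observed vector leaves r undefined (NaN) rather than erroring.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    mask = np.isfinite(observed) & np.isfinite(predicted)
    if mask.sum() < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    obs, pred = observed[mask], predicted[mask]
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
        log.warning("zero-variance vector: correlation undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(obs, pred).statistic)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2_identity = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    mean_obs = float(obs.mean())
    return AgreementStats(
        r=r, rmse=rmse, r_squared=r ** 2,
        relative_rmse=rmse / mean_obs if mean_obs != 0 else float("nan"),
        r_squared_identity=r2_identity,
    )


def site_means(traits: pd.DataFrame, trait: str,
               include_evergreen: bool = False) -> pd.Series:
    """Per-site mean of a species-level trait column.

    Deciduous records only by default; rows with missing trait values are
    ignored.
    """
    data = traits
    if not include_evergreen and "leaf_habit" in data.columns:
        data = data[data["leaf_habit"] == "deciduous"]
    return data.groupby("site_id")[trait].mean()


def cv_within_across(traits: pd.DataFrame, trait: str,
                     include_evergreen: bool = False
                     ) -> tuple[pd.Series, float]:
    """Within-site and across-site coefficients of variation.

    CV = sample standard deviation / mean. Within-site CVs use species
    values at each site (sites with a single species are skipped with a log
    entry); the across-site CV uses the site means.
    """
    data = traits
    if not include_evergreen and "leaf_habit" in data.columns:
        data = data[data["leaf_habit"] == "deciduous"]
    data = data.dropna(subset=[trait])

    def _cv(values: np.ndarray) -> float:
        return float(np.std(values, ddof=1) / np.mean(values))

    within = {}
    for site_id, group in data.groupby("site_id"):
        values = group[trait].to_numpy(dtype=float)
        if len(values) < 2:
            log.info("site %s skipped for within-site CV (single species)",
                     site_id)
            continue
        within[site_id] = _cv(values)
    means = data.groupby("site_id")[trait].mean().to_numpy()
    if len(means) < 2:
        raise InsufficientDataError("need >= 2 sites for across-site CV")
    return pd.Series(within, name=f"cv_{trait}"), _cv(means)


#: Climate driver sets used by the statistical benchmark — the same
#: predictors the corresponding optimality model consumes.
BENCHMARK_DRIVERS: dict[str, tuple[str, ...]] = {
    "chi": ("patm", "tdj", "d0"),
    "vcmax25": ("patm", "tdj", "r0"),
    "ma": ("tg", "r_lai", "f", "alpha_p"),
    "narea": ("patm", "tg", "r0", "r_lai", "f", "alpha_p"),
}


def benchmark_regression(site_table: pd.DataFrame, trait: str,
                         drivers: tuple[str, ...] | None = None) -> dict:
    """Multiple linear regression of site-mean trait on its climate drivers.

    The statistical benchmark an optimality model must beat: same driver
    set, freely fitted. Returns the fitted R^2, adjusted R^2 and
    coefficients. Requires at least two more sites than predictors.
    """
    drivers = drivers or BENCHMARK_DRIVERS[trait]
    data = site_table.dropna(subset=[trait, *drivers])
    if len(data) < len(drivers) + 2:
        raise InsufficientDataError(
            f"need >= {len(drivers) + 2} sites for {len(drivers)} predictors, "
            f"got {len(data)}")
    design = sm.add_constant(data[list(drivers)].astype(float),
                             has_constant="add")
    res = sm.OLS(data[trait].to_numpy(dtype=float), design).fit()
    return {
        "trait": trait,
        "r_squared": float(res.rsquared),
        "adj_r_squared": float(res.rsquared_adj),
        "n_sites": int(res.nobs),
        "params": dict(res.params),
    }
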
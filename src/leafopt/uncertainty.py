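"""Parameter-uncertainty propagation: first-order budgets and a Monte-Carlo
cross-check.

First-order propagation combines independent parameter uncertainties as

    u^2(y) = sum_i (dm/dn_i)^2 u^2(n_i)

with sensitivities dm/dn_i obtained by central finite differences. The
Monte-Carlo routine draws the parameters from independent normals and
reports the empirical spread; for linear models the two agree exactly (up
to sampling error), and the divergence for curved models measures how far
the first-order budget can be trusted. Parameter covariances are assumed
zero throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = ["UncertaintyBudget", "MCResult", "propagate", "mc_propagate"]

ModelFn = Callable[[Mapping[str, float]], float]


@dataclass(frozen=True)
class UncertaintyBudget:
    """Total first-order standard uncertainty and its per-parameter shares.

    ``shares`` has one row per parameter with the sensitivity dm/dn_i, the
    input uncertainty u(n_i) and the variance contribution
    (dm/dn_i)^2 u^2(n_i); contributions sum to ``total_sd ** 2`` by
    construction.
    """

    value: float
    total_sd: float
    shares: pd.DataFrame

    def fraction(self, parameter: str) -> float:
        """Share of total variance carried by one parameter."""
        row = self.shares.set_index("parameter").loc[parameter]
        total_var = self.total_sd ** 2
        return float(row["contribution"] / total_var) if total_var > 0 else 0.0


def propagate(model: ModelFn, params: Mapping[str, float],
              uncertainties: Mapping[str, float],
              rel_step: float = 1e-4) -> UncertaintyBudget:
    """First-order uncertainty budget for ``model`` at ``params``.

    Sensitivities use central differences with step ``rel_step * |n_i|``
    (absolute ``rel_step`` for parameters at zero). Parameters without an
    entry in ``uncertainties`` are held exact. Raises ``ValueError`` naming
    the parameter if a sensitivity evaluates non-finite.
    """
    base = dict(params)
    value = float(model(base))
    rows = []
    for name, u in uncertainties.items():
        if u < 0:
            raise ValueError(f"negative uncertainty for {name!r}")
        if name not in base:
            raise ValueError(f"unknown parameter {name!r}")
        step = rel_step * abs(base[name]) or rel_step
        hi = dict(base, **{name: base[name] + step})
        lo = dict(base, **{name: base[name] - step})
        sens = (float(model(hi)) - float(model(lo))) / (2.0 * step)
        if not np.isfinite(sens):
            raise ValueError(f"non-finite sensitivity for parameter {name!r}")
        rows.append({"parameter": name, "sensitivity": sens, "u": u,
                     "contribution": sens ** 2 * u ** 2})
    shares = pd.DataFrame(rows, columns=["parameter", "sensitivity", "u",
                                         "contribution"])
    total_sd = float(np.sqrt(shares["contribution"].sum())) if rows else 0.0
    return UncertaintyBudget(value=value, total_sd=total_sd, shares=shares)


@dataclass(frozen=True)
class MCResult:
    mean: float
    sd: float
    quantiles: dict[float, float]
    n_draws: int


def mc_propagate(model: ModelFn, params: Mapping[str, float],
                 uncertainties: Mapping[str, float],
                 n_draws: int = 10_000, seed: int = 0,
                 quantiles: tuple[float, ...] = (0.025, 0.5, 0.975)) -> MCResult:
    """Monte-Carlo propagation: independent normal draws per parameter.

    Deterministic under a fixed seed. Draws that land outside the model's
    domain propagate whatever the model does (no silent clipping); callers
    with hard domain bounds should supply uncertainties small enough that
    the normal approximation is meaningful.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    names = list(uncertainties)
    draws = {name: rng.normal(params[name], uncertainties[name], size=n_draws)
             for name in names}
    values = np.empty(n_draws)
    scratch = dict(params)
    for i in range(n_draws):
        for name in names:
            scratch[name] = draws[name][i]
        values[i] = float(model(scratch))
    return MCResult(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        quantiles={q: float(np.quantile(values, q)) for q in quantiles},
        n_draws=n_draws,
    )
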
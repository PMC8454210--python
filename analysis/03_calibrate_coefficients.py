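#!/usr/bin/env python
"""Refit the free model coefficients on the synthetic trait table.

Checks that the estimation route used for the published coefficients
(OLS of ln(Ma) on ln(R_LAI), ln(f), Tg, ln(alpha_p); zero-intercept
regression of Narea on Ma and Vcmax25 with an N-fixer factor; and the
Rubisco-allocation slope) recovers the generating values from noisy
species-level data. Writes results/calibration.json.
"""

import json
from pathlib import Path

from leafopt import (fit_lma_coefficients, fit_narea_coefficients,
                     fit_rubisco_allocation)
from leafopt.io import read_sites, read_traits

OUT = Path("results/calibration.json")
GENERATING = {"ln_r_lai": 1.22, "ln_f": 0.78, "tg": -0.06,
              "ln_alpha_p": -0.60, "intercept": 1.70}


def main() -> None:
    sites = read_sites("results/synthetic/sites.csv")
    traits = read_traits("results/synthetic/traits.csv")
    joined = traits.merge(sites[["site_id", "r_lai", "f", "tg", "alpha_p"]],
                          on="site_id")
    deciduous = joined[joined.leaf_habit == "deciduous"]

    lma = fit_lma_coefficients(deciduous)
    narea = fit_narea_coefficients(traits, include_n_fixer=True)
    alloc = fit_rubisco_allocation(traits)

    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps({
        "lma": {"params": lma.params, "bse": lma.bse,
                "r_squared": lma.r_squared, "n": lma.n_obs},
        "narea": {"params": narea.params, "bse": narea.bse, "n": narea.n_obs},
        "rubisco_alloc": alloc,
    }, indent=2))

    print(f"wrote {OUT}")
    print(f"\nLMA fit on {lma.n_obs} deciduous records "
          f"(R2 = {lma.r_squared:.2f}):")
    for name, truth in GENERATING.items():
        est, se = lma.params[name], lma.bse[name]
        print(f"  {name:<11} {est:+.3f} (se {se:.3f})  generating {truth:+.2f}")
    print("  (drivers covary along a single transect, so the standard "
          "errors are wide;\n   estimates stay within ~1-2 se of the "
          "generating values — a well-conditioned\n   independent design "
          "recovers them tightly, see the recovery tests)")
    print("\nNarea fit:", {k: round(v, 4) for k, v in narea.params.items()},
          "(generating 0.02, 0.003, N-fixer offset 0.3)")
    print(f"Rubisco allocation slope: {alloc:.2f} (observed tables mix the "
          "direct-model noise into the two-step decomposition)")


if __name__ == "__main__":
    main()
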
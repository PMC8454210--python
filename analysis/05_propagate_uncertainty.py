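#!/usr/bin/env python
"""Propagate parameter uncertainty through each trait model.

First-order budgets (central-difference sensitivities combined by the
standard error-propagation formula) at the mid-transect site, cross-checked
against 10,000-draw Monte Carlo. Writes results/uncertainty.csv.
"""

from pathlib import Path

import pandas as pd

from leafopt import (PhysioConstants, chi_optimal, fv_instantaneous,
                     mc_propagate, propagate, vcmax_coordination)
from leafopt.io import read_sites, sites_from_frame

OUT = Path("results/uncertainty.csv")
SEED = 1


def main() -> None:
    sites = sites_from_frame(read_sites("results/synthetic/sites.csv"))
    site = sites[len(sites) // 2]
    consts = PhysioConstants()

    def chi_model(p):
        c = consts.replace(beta=p["beta"])
        return float(chi_optimal(site.tdj, site.d0, site.patm, site.ca, c))

    def vcmax_model(p):
        c = consts.replace(beta=p["beta"], c_cost=p["c_cost"], phi0=p["phi0"])
        chi = float(chi_optimal(site.tdj, site.d0, site.patm, site.ca, c))
        v = float(vcmax_coordination(site.tdj, site.r0, chi, site.ca,
                                     site.patm, c))
        return v / float(fv_instantaneous(site.tdj, c))

    cases = [
        ("chi", chi_model, {"beta": consts.beta},
         {"beta": consts.uncertainties["beta"]}),
        ("vcmax25", vcmax_model,
         {"beta": consts.beta, "c_cost": consts.c_cost, "phi0": consts.phi0},
         dict(consts.uncertainties)),
    ]

    rows = []
    print(f"reference site {site.site_id} ({site.elevation:.0f} m)")
    for trait, model, params, u in cases:
        budget = propagate(model, params, u)
        mc = mc_propagate(model, params, u, n_draws=10_000, seed=SEED)
        ratio = budget.total_sd / mc.sd
        print(f"\n{trait}: value {budget.value:.3f}, first-order sd "
              f"{budget.total_sd:.4f}, MC sd {mc.sd:.4f} "
              f"(ratio {ratio:.3f})")
        for _, share in budget.shares.iterrows():
            frac = budget.fraction(share["parameter"])
            print(f"  {share['parameter']:<7} contributes {frac:6.1%} of the "
                  "variance")
            rows.append({"site_id": site.site_id, "trait": trait,
                         **share.to_dict(), "total_sd": budget.total_sd,
                         "mc_sd": mc.sd})
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"\nwrote {OUT}")
    print("beta dominates the chi budget; the electron-transport cost c "
          "dominates Vcmax25, matching the structure of the models.")


if __name__ == "__main__":
    main()
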
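#!/usr/bin/env python
"""Exposure-corrected Hill fitting across the 28-drug panel.

For each drug: simulate bioanalysis loss triplicates from the drug's LogP
(losses rise with hydrophobicity), correct the nominal test concentrations,
simulate a noisy 3-cell concentration-inhibition panel at the corrected
exposures, and fit the variable-slope Hill equation.  Writes the per-drug
fit table and prints the recovery summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hergvar.exposure import correct_concentrations
from hergvar.hill import fit_hill
from hergvar.synthetic import (default_drugs, simulate_concentration_response,
                               simulate_loss_samples)

OUT = Path("results/potency")
SEED = 7
X50, DX = 3.5, 0.9  # loss-vs-LogP curve of the simulated perfusion system


def main() -> None:
    rows = []
    for i, drug in enumerate(default_drugs()):
        ic50 = 10.0 ** (-drug.true_pic50)
        nominals = ic50 * np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        losses = [simulate_loss_samples(drug.logP, X50, DX, 0.05, 3,
                                        SEED * 1000 + 10 * i + j,
                                        nominal_molar=c, drug=drug.name
                                        ).fractional_loss
                  for j, c in enumerate(nominals)]
        corrected = correct_concentrations(nominals, losses, mode="averaged")
        pts = simulate_concentration_response(
            ic50, drug.true_nH, corrected, n_cells=3, noise_sd=0.05,
            seed=SEED + i, drug=drug.name)
        fit = fit_hill(pts)
        rows.append({
            "drug": drug.name, "logP": drug.logP,
            "mean_loss_pct": 100 * float(np.mean(losses)),
            "true_pic50": drug.true_pic50,
            "pic50": fit.pic50, "sd_pic50": fit.pic50_sd,
            "nH": fit.nH, "determined": fit.determined,
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "hill_fits.csv", index=False, float_format="%.6g")
    det = table[table.determined]
    err = det["pic50"] - det["true_pic50"]
    print(f"fitted {len(det)}/{len(table)} drugs; "
          f"median pIC50 error {err.median():+.3f}, "
          f"max |error| {err.abs().max():.3f}")
    print(f"high-LogP drugs lose more drug: loss ranges "
          f"{table.mean_loss_pct.min():.0f}% (LogP {table.logP.min():.1f}) "
          f"to {table.mean_loss_pct.max():.0f}% (LogP {table.logP.max():.1f})")
    print(f"fit table -> {OUT / 'hill_fits.csv'}")


if __name__ == "__main__":
    main()
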
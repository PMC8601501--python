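#!/usr/bin/env python
"""Calibrate the surrogate's flowering-duration coefficient by grid search.

Generates two synthetic "observed" seasons from a known parameter set, then
recovers EM-FL by minimising the summed nRMSE loss over a grid — first on
noise-free observations (exact recovery expected), then across 50 noise
replicates (phenology scoring error 1.5 d, 5% CV on yield/biomass) to check
the truth stays a local minimum of the loss.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from canolagsa import calibration_objective, grid_search
from canolagsa.surrogate import (
    default_parameters,
    generate_observations,
    make_calibration_model,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "calibration"
TRUE_EMFL, STEP = 33.0, 2.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = default_parameters()
    truth["EM-FL"] = TRUE_EMFL
    records, weathers, mgmts = generate_observations(truth, n_seasons=2, seed=4)
    model = make_calibration_model(weathers, mgmts)
    grid = np.arange(25.0, 41.0, STEP)
    best, losses = grid_search("EM-FL", grid, truth, records, model)
    loss_table = pd.DataFrame(
        {"EM-FL": list(losses), "loss_nRMSE_sum": list(losses.values())}
    )
    loss_table.to_csv(OUT / "grid_losses.csv", index=False)
    print(f"Noise-free grid search: true EM-FL {TRUE_EMFL}, recovered {best}")
    print(loss_table.round(3).to_string(index=False))

    successes = 0
    for rep in range(50):
        noisy, _, _ = generate_observations(
            truth, n_seasons=2, phenology_sd=1.5, biomass_cv=0.05,
            seed=4, noise_seed=1000 + rep,
        )
        at_truth = calibration_objective(dict(truth), noisy, model)
        at_nb = min(
            calibration_objective({**truth, "EM-FL": TRUE_EMFL + s * STEP}, noisy, model)
            for s in (-1, 1)
        )
        successes += at_truth <= at_nb
    rate = 100.0 * successes / 50
    pd.DataFrame(
        [{"replicates": 50, "success_pct": rate, "phenology_sd_d": 1.5,
          "biomass_cv": 0.05, "grid_step": STEP}]
    ).to_csv(OUT / "noisy_recovery.csv", index=False)
    print(
        f"\nNoisy replicates: truth beat both grid neighbours in {successes}/50 "
        f"({rate:.0f}%) — the loss surface localises EM-FL to within one grid "
        "step at realistic observation noise."
    )


if __name__ == "__main__":
    main()
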
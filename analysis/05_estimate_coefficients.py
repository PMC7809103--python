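#!/usr/bin/env python
"""Competition-coefficient estimation on synthetic density experiments.

Generates density-dependent survival tables from the published pairwise
coefficient block (noise-free and with count-scale noise) and re-estimates
the coefficients by the intercept-free multiple regression, demonstrating
exact recovery and unbiasedness.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pestdyn import build_competition_matrix, estimate_coefficients
from pestdyn.io import write_experiment
from pestdyn.synth import ExperimentDesign, generate_density_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main():
    OUT.mkdir(exist_ok=True)
    truth = build_competition_matrix({"Bf", "Cp"})

    exact = estimate_coefficients(generate_density_experiment(
        truth, ExperimentDesign(("Bf", "Cp"), noise_sd=0.0, replicates=1)))
    print("noise-free recovery, max abs error: "
          f"{np.max(np.abs(exact.matrix.a - truth.a)):.2e}")

    design = ExperimentDesign(("Bf", "Cp"),
                              density_levels=(50.0, 100.0, 200.0),
                              noise_sd=5.0, replicates=12, seed=SEED)
    exp = generate_density_experiment(truth, design)
    write_experiment(exp, OUT / "density_experiment_synthetic.csv")
    noisy = estimate_coefficients(exp)

    rows = []
    for affected, acting in (("Bf", "Cp"), ("Cp", "Bf")):
        rows.append({
            "coefficient": f"a({affected}<-{acting})",
            "true": truth.coefficient(affected, acting),
            "estimate": noisy.matrix.coefficient(affected, acting),
            "std_error": noisy.standard_errors[(affected, acting)],
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "estimation_summary.csv", index=False)
    print(df.to_string(index=False))
    print(f"design condition numbers: {noisy.condition_numbers}")
    print("\nWith count-scale noise the per-individual effects (1e-4 range) "
          "carry wide relative uncertainty in a single experiment, but the "
          "estimator is exact on noise-free data and unbiased on average "
          "(see the test suite's Monte-Carlo check).")


if __name__ == "__main__":
    main()
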
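"""Seeded simulation studies: beta recovery and classification accuracy.

Small-scale versions of the validation studies the test suite runs in
full: how well does log-linear fitting recover a known Detriment Index
under Poisson count noise, and how often is each generating family
correctly labelled?
"""

from adrtrend.simulate import (
    SimulationSpec,
    run_classification_study,
    run_recovery_study,
)

recovery_grid = [
    SimulationSpec("exponential", {"alpha": 20.0, "beta": b}, n_years=30,
                   noise="poisson_increments")
    for b in (0.1, 0.3)
]
print("beta recovery under Poisson count noise (50 replicates/cell):")
table = run_recovery_study(recovery_grid, replicates=50, seed=42)
print(table[["beta_true", "beta_mean", "bias", "rmse", "ci_coverage"]]
      .round(4).to_string(index=False))
print("Bias is negligible; note the Wald CI under-covers because cumulative-")
print("count residuals are autocorrelated (a random walk), which the iid")
print("error model behind the CI ignores.\n")

classify_grid = [
    SimulationSpec("saturation_mm", {"y0": 100.0, "theta1": 4000.0, "theta2": 3.0},
                   n_years=25, noise="poisson_increments"),
    SimulationSpec("logistic", {"L": 5000.0, "k": 0.6, "t0": 10.0},
                   n_years=25, noise="poisson_increments"),
]
print("classification confusion (25 replicates/cell):")
table = run_classification_study(classify_grid, replicates=25, seed=42)
print(table.to_string(index=False))
print("Rows are the generating family; columns count the assigned labels.")
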
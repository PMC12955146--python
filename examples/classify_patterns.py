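"""Classify the temporal pattern of simulated ADR reporting curves.

Simulates one curve per growth family — clean and with Poisson count
noise — and prints the assigned pattern label with the per-family AIC
scores behind the decision.
"""

from adrtrend import classify_pattern
from adrtrend.simulate import SimulationSpec, simulate_series

CELLS = [
    ("linear", {"a": 50.0, "b": 120.0}),
    ("exponential", {"alpha": 40.0, "beta": 0.15}),
    ("saturation_mm", {"y0": 100.0, "theta1": 4000.0, "theta2": 3.0}),
    ("logistic", {"L": 5000.0, "k": 0.6, "t0": 10.0}),
]

for noise in ("none", "poisson_increments"):
    print(f"\n--- noise model: {noise} ---")
    for family, params in CELLS:
        series = simulate_series(
            SimulationSpec(family, params, n_years=25, noise=noise, seed=11, drug_id=family)
        )
        cls = classify_pattern(series)
        aics = ", ".join(
            f"{fam}={s['aic']:.1f}" if s["valid"] else f"{fam}=invalid"
            for fam, s in cls.scores.items()
        )
        print(f"{family:>14} -> {cls.label:<12} (AIC: {aics})")

print()
print("The label is the minimum-AIC family; within a 2-unit AIC tie the family")
print("with fewer parameters wins. Noise-free curves always recover their own")
print("family; under count noise a linear/exponential curve is occasionally")
print("absorbed by the richer saturation/logistic family that nests it.")
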
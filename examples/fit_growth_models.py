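"""Fit the four growth families to reference cumulative ADR curves.

Regenerates noise-free curves from published fitted parameters for two
withdrawn drugs — Benoxaprofen (saturation) and Rofecoxib (sigmoidal) —
refits them, and prints the recovered parameters with fit statistics.
"""

from adrtrend import fit_logistic, fit_saturation_mm
from adrtrend.datasets import LOGISTIC_EXAMPLE, SATURATION_EXAMPLE
from adrtrend.simulate import SimulationSpec, simulate_series


def show(name, fit):
    print(f"\n{name} ({fit.family}):")
    for pname, est in fit.params.items():
        lo, hi = fit.ci95[pname]
        print(f"  {pname:>7} = {est:12.4f}   95% CI [{lo:.4f}, {hi:.4f}]")
    print(f"  RMSE {fit.rmse:.4f}   R^2 {fit.r2:.4f}   AIC {fit.aic:.4f}   BIC {fit.bic:.4f}")


mm = SATURATION_EXAMPLE
series = simulate_series(
    SimulationSpec("saturation_mm", mm["params"], n_years=mm["n_years"], drug_id=mm["drug"])
)
show(mm["drug"], fit_saturation_mm(series))
print("  -> theta2 is the time (years) to reach half of the post-baseline rise;")
print("     a small value means reporting momentum was exhausted quickly after withdrawal.")

lg = LOGISTIC_EXAMPLE
params = dict(lg["params"], L=100_000.0)  # upper asymptote is a free parameter
series = simulate_series(
    SimulationSpec("logistic", params, n_years=lg["n_years"], drug_id=lg["drug"])
)
show(lg["drug"], fit_logistic(series))
print("  -> t0 is the inflection year (reports still surging ~6 years in),")
print("     k the steepness of the post-withdrawal reporting surge.")
print("\nA perfect refit reports AIC/BIC = -inf: the regenerated curves are noise-free.")
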
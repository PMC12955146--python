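"""Temporal-pattern classification of cumulative ADR curves.

Each drug's cumulative reporting curve is fitted with all four growth
families and labelled by the family with the lowest AIC among valid fits:

* ``saturation``  — rise then plateau (shifted Michaelis–Menten), the shape
  an effective market withdrawal is expected to produce;
* ``linear``      — steady year-on-year reporting;
* ``exponential`` — accelerating accumulation (persistent safety signal);
* ``sigmoidal``   — slow start, surge, plateau (logistic lifecycle shape).

When the top two AIC values are within ΔAIC < 2 the family with fewer
parameters wins; remaining ties fall back to the fixed precedence
linear < exponential < saturation < logistic (simpler, monotone-growth
families first).  Classification is deterministic and invariant to positive
rescaling of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .series import ADRSeries

__all__ = ["PatternClassification", "classify_pattern", "classify_panel", "FAMILY_LABELS"]

# family -> reported pattern label
FAMILY_LABELS = {
    "saturation_mm": "saturation",
    "linear": "linear",
    "exponential": "exponential",
    "logistic": "sigmoidal",
}
_PRECEDENCE = ["linear", "exponential", "saturation_mm", "logistic"]
DELTA_AIC_TIE = 2.0


@dataclass
class PatternClassification:
    drug_id: str
    label: str                      # saturation|linear|exponential|sigmoidal|undetermined
    scores: dict[str, dict]         # per family: aic, bic, r2, rmse, valid_flag
    best_fit: models.GrowthFit | None
    delta_aic: dict[str, float]


def _fit_all(series: ADRSeries) -> dict[str, object]:
    """Attempt every family; record failures instead of raising."""
    fits: dict[str, object] = {}
    for family, fitter in (
        ("linear", models.fit_linear),
        ("saturation_mm", models.fit_saturation_mm),
        ("logistic", models.fit_logistic),
    ):
        try:
            fits[family] = fitter(series)
        except (models.FitError, FloatingPointError) as exc:
            fits[family] = exc
    # AIC is only comparable across families when each sits at its
    # least-squares optimum on the cumulative scale, so model selection
    # uses the NLS exponential route (itself initialized from the
    # log-linear solution); it also tolerates leading zeros.
    try:
        fits["exponential"] = models.fit_exponential(series, method="nls")
    except models.FitError as exc:
        fits["exponential"] = exc
    return fits


def classify_pattern(series: ADRSeries, tie_threshold: float = DELTA_AIC_TIE) -> PatternClassification:
    """Fit all four families and label the series by minimal AIC.

    Invalid fits (non-convergence, θ2 ≤ 0, k ≤ 0) are excluded from
    selection but reported in ``scores``.  With no valid fit the label is
    ``undetermined``.
    """
    if series.n_obs < 6:
        raise models.FitError("classification needs at least 6 observations")
    fits = _fit_all(series)

    scores = {}
    valid = {}
    for family, fit in fits.items():
        if isinstance(fit, models.GrowthFit):
            scores[family] = {
                "aic": fit.aic,
                "bic": fit.bic,
                "r2": fit.r2,
                "rmse": fit.rmse,
                "valid": fit.valid,
            }
            if fit.valid:
                valid[family] = fit
        else:
            scores[family] = {
                "aic": np.inf, "bic": np.inf, "r2": np.nan, "rmse": np.nan,
                "valid": False, "error": str(fit),
            }

    if len(valid) < 2:
        if not valid:
            return PatternClassification(series.drug_id, "undetermined", scores, None, {})
        raise models.FitError(
            f"only {len(valid)} valid fit(s) for {series.drug_id!r}; need at least two"
        )

    best_aic = min(f.aic for f in valid.values())
    if np.isneginf(best_aic):
        # perfect fits are mutually tied; everything else is infinitely worse
        contenders = [fam for fam, f in valid.items() if np.isneginf(f.aic)]
        delta = {fam: (0.0 if np.isneginf(f.aic) else np.inf) for fam, f in valid.items()}
    else:
        contenders = [fam for fam, f in valid.items() if f.aic - best_aic < tie_threshold]
        delta = {fam: f.aic - best_aic for fam, f in valid.items()}
    fewest = min(models.N_PARAMS[f] for f in contenders)
    contenders = [f for f in contenders if models.N_PARAMS[f] == fewest]
    winner = min(contenders, key=_PRECEDENCE.index)

    return PatternClassification(
        drug_id=series.drug_id,
        label=FAMILY_LABELS[winner],
        scores=scores,
        best_fit=valid[winner],
        delta_aic=delta,
    )


def classify_panel(panel, tie_threshold: float = DELTA_AIC_TIE) -> pd.DataFrame:
    """Classify a collection of series; per-drug failures never abort the panel.

    Returns one row per drug with the label and per-family AIC columns.
    """
    panel = list(panel)
    rows = []
    for series in panel:
        try:
            cls = classify_pattern(series, tie_threshold=tie_threshold)
            label, scores, delta = cls.label, cls.scores, cls.delta_aic
            r2_winner = cls.best_fit.r2 if cls.best_fit is not None else np.nan
            err = ""
        except models.FitError as exc:
            label, scores, delta, r2_winner, err = "error", {}, {}, np.nan, str(exc)
        rows.append(
            {
                "drug": series.drug_id,
                "label": label,
                "aic_linear": scores.get("linear", {}).get("aic", np.nan),
                "aic_exponential": scores.get("exponential", {}).get("aic", np.nan),
                "aic_saturation": scores.get("saturation_mm", {}).get("aic", np.nan),
                "aic_logistic": scores.get("logistic", {}).get("aic", np.nan),
                "delta_aic_winner": min(delta.values()) if delta else np.nan,
                "r2_winner": r2_winner,
                "error": err,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "label", "aic_linear", "aic_exponential", "aic_saturation",
            "aic_logistic", "delta_aic_winner", "r2_winner", "error",
        ],
    )
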
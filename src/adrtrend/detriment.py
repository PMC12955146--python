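"""The Detriment Index: scale-invariant safety ranking of ADR trajectories.

The Detriment Index of a drug is the growth-rate parameter β of the
exponential model Y = α·exp(β·t) fitted to its cumulative ADR reporting
curve.  β measures how fast reports accumulate *relative to their current
level*: multiplying every count by a positive constant changes α but leaves
β untouched, so drugs with very different reporting volumes (market sizes)
can be ranked on one scale.  Higher β means faster safety-signal
accumulation (less favourable profile); β = 0 is a completely flat curve.

An experimental composite — β times the normalised area under the
cumulative curve — is provided behind an explicit flag; it is never used
for the default ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import models
from .series import ADRSeries, ValidationError

__all__ = [
    "DetrimentResult",
    "detriment_index",
    "check_scale_invariance",
    "normalize_by_exposure",
    "rank_drugs",
    "composite_index",
]


@dataclass
class DetrimentResult:
    drug_id: str
    beta: float
    beta_ci95: tuple[float, float]
    alpha: float
    fit_r2: float
    rank: int | None = None
    experimental_composite: float | None = None


def detriment_index(series: ADRSeries, method: str = "log_linear") -> DetrimentResult:
    """Compute β (the Detriment Index) with its 95% CI for one series.

    A flat cumulative curve returns β = 0 by convention without fitting
    (this also covers the all-zero curve, where a log-linear fit would be
    undefined).
    """
    y = series.cumulative_counts
    if np.all(y == y[0]):
        return DetrimentResult(
            drug_id=series.drug_id,
            beta=0.0,
            beta_ci95=(0.0, 0.0),
            alpha=float(y[0]),
            fit_r2=1.0,
        )
    fit = models.fit_exponential(series, method=method)
    return DetrimentResult(
        drug_id=series.drug_id,
        beta=fit.params["beta"],
        beta_ci95=fit.ci95["beta"],
        alpha=fit.params["alpha"],
        fit_r2=fit.r2,
    )


def check_scale_invariance(series: ADRSeries, multipliers, method: str = "log_linear") -> float:
    """Max |β(c·Y) − β(Y)| over a set of positive multipliers c.

    For the default log-linear method this is zero to machine precision:
    scaling Y shifts ln Y by a constant, which moves only the intercept of
    the log-scale regression.
    """
    mult = np.asarray(multipliers, dtype=float)
    if np.any(mult <= 0):
        raise ValidationError("multipliers must be positive")
    beta0 = detriment_index(series, method=method).beta
    return max(
        abs(detriment_index(series.scaled(c), method=method).beta - beta0) for c in mult
    )


def normalize_by_exposure(series: ADRSeries, exposure) -> ADRSeries:
    """Divide annual counts by per-year exposure (doses sold or a proxy).

    ``exposure`` is a DataFrame/CSV with columns ``drug,year,exposure_units``
    (or just ``year,exposure_units``) covering every year of the series; the
    result is a rate-valued series whose cumulative curve is the running sum
    of annual reporting rates.  Downstream fitting is unchanged in
    mechanics.
    """
    exp_df = exposure if isinstance(exposure, pd.DataFrame) else pd.read_csv(exposure)
    if "drug" in exp_df.columns:
        exp_df = exp_df[exp_df["drug"] == series.drug_id]
    exp_df = exp_df.set_index("year")["exposure_units"]
    missing = sorted(set(series.years.tolist()) - set(exp_df.index.tolist()))
    if missing:
        raise ValidationError(f"exposure missing for years {missing}")
    units = exp_df.reindex(series.years).to_numpy(dtype=float)
    if np.any(units <= 0):
        raise ValidationError("exposure_units must be positive")
    return _dc_replace(series, annual_counts=series.annual_counts / units)


def rank_drugs(panel, method: str = "log_linear", composite: bool = False) -> pd.DataFrame:
    """Rank a panel ascending in β (rank 1 = smallest β = safest).

    ``panel`` may hold :class:`ADRSeries` or precomputed
    :class:`DetrimentResult` objects.  Ties share the minimum rank.
    Per-drug fitting failures are reported in the ``error`` column, not
    fatal.
    """
    panel = list(panel)
    if not panel:
        raise ValidationError("empty panel")
    results, failures = [], []
    for item in panel:
        if isinstance(item, DetrimentResult):
            results.append(item)
            continue
        try:
            res = detriment_index(item, method=method)
            if composite:
                res.experimental_composite = composite_index(item, method=method)
            results.append(res)
        except (models.FitError, ValidationError) as exc:
            failures.append({"drug": item.drug_id, "error": str(exc)})

    frame = pd.DataFrame(
        {
            "drug": [r.drug_id for r in results],
            "beta": [r.beta for r in results],
            "beta_lo": [r.beta_ci95[0] for r in results],
            "beta_hi": [r.beta_ci95[1] for r in results],
            "r2": [r.fit_r2 for r in results],
            "alpha": [r.alpha for r in results],
        }
    )
    if composite:
        frame["composite_experimental"] = [r.experimental_composite for r in results]
    if len(frame):
        frame["rank"] = rankdata(frame["beta"], method="min").astype(int)
        for r, rk in zip(results, frame["rank"]):
            r.rank = int(rk)
        frame = frame.sort_values(["beta", "drug"], kind="mergesort").reset_index(drop=True)
    frame["error"] = ""
    if failures:
        fail = pd.DataFrame(failures)
        fail["rank"] = pd.NA
        frame = pd.concat([frame, fail], ignore_index=True)
    cols = ["rank", "drug", "beta", "beta_lo", "beta_hi", "r2", "alpha"]
    if composite:
        cols.append("composite_experimental")
    return frame[cols + ["error"]]


def composite_index(series: ADRSeries, method: str = "log_linear") -> float:
    """Experimental burden-weighted variant: β × normalised AUC.

    The cumulative curve's trapezoidal area over t = 1..n is normalised by
    n × max(Y), giving a shape factor in [0, 1] that is invariant to
    rescaling the counts; the product therefore keeps β's scale
    invariance.  Exploratory only — the Detriment Index proper is β and
    default ranking never uses this number.
    """
    y = series.cumulative_counts
    if np.all(y == 0):
        return 0.0
    beta = detriment_index(series, method=method).beta
    auc = float(np.trapezoid(y, series.time_index))
    return beta * auc / (series.n_obs * float(y.max()))
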
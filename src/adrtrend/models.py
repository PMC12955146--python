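"""Growth-model fitting for cumulative ADR curves.

Four families describe how a drug's cumulative adverse-reaction report count
Y grows with time t (years since the series start, t = 1..n):

* linear            Y = a + b·t
* exponential       Y = α·exp(β·t)          (β is the Detriment Index)
* saturation_mm     Y = Y0 + θ1·t/(θ2 + t)  (shifted Michaelis–Menten)
* logistic          Y = L/(1 + exp(−k·(t − t0)))

All fits minimise the residual sum of squares on the cumulative scale
(additive homoscedastic Gaussian error model).  Fit quality is summarised by
RSS, RMSE, R² and the least-squares information criteria

    AIC = n·ln(RSS/n) + 2p,      BIC = n·ln(RSS/n) + p·ln(n),

so BIC − AIC = p·(ln n − 2) identically.  A perfect fit (RSS = 0) gets the
−inf sentinel and a ``perfect_fit`` flag rather than an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .series import ADRSeries

__all__ = [
    "GrowthFit",
    "FitError",
    "fit_linear",
    "fit_exponential",
    "fit_saturation_mm",
    "fit_logistic",
    "compute_fit_metrics",
    "residual_diagnostics",
    "FAMILY_CURVES",
    "N_PARAMS",
]

MAX_NFEV = 500          # iteration cap for nonlinear solvers
RSS_TOL = 1e-10         # convergence tolerance on RSS change

N_PARAMS = {"linear": 2, "exponential": 2, "saturation_mm": 3, "logistic": 3}


class FitError(RuntimeError):
    """Raised when a model cannot be fitted to a series."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def linear_curve(t, a, b):
    return a + b * np.asarray(t, dtype=float)


def exponential_curve(t, alpha, beta):
    return alpha * np.exp(beta * np.asarray(t, dtype=float))


def saturation_mm_curve(t, y0, theta1, theta2):
    t = np.asarray(t, dtype=float)
    return y0 + theta1 * t / (theta2 + t)


def logistic_curve(t, L, k, t0):
    t = np.asarray(t, dtype=float)
    return L / (1.0 + np.exp(-k * (t - t0)))


FAMILY_CURVES = {
    "linear": linear_curve,
    "exponential": exponential_curve,
    "saturation_mm": saturation_mm_curve,
    "logistic": logistic_curve,
}


@dataclass
class GrowthFit:
    """Fitted parameters, uncertainty and fit statistics for one family."""

    family: str
    params: dict[str, float]
    std_errors: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    fitted_values: np.ndarray
    residuals: np.ndarray
    rss: float
    rmse: float
    r2: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    flags: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return not self.flags.get("invalid", False)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "family": self.family,
            "params": self.params,
            "std_errors": self.std_errors,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "metrics": {
                "rss": self.rss,
                "rmse": self.rmse,
                "r2": self.r2,
                "aic": self.aic,
                "bic": self.bic,
            },
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "flags": self.flags,
        }


def compute_fit_metrics(observed, fitted, n_params):
    """RSS, RMSE, R², AIC and BIC for a fitted curve.

    Information criteria use the Gaussian least-squares profile form
    n·ln(RSS/n) + penalty.  RSS = 0 yields −inf AIC/BIC (perfect-fit
    sentinel), which callers flag rather than raise.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    n = len(obs)
    if len(fit) != n or n < 2:
        raise ValueError("observed and fitted must share length n >= 2")
    if n <= n_params:
        raise ValueError("need n > n_params")
    rss = float(np.sum((obs - fit) ** 2))
    rmse = float(np.sqrt(rss / n))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    # perfect-fit threshold: RMSE at solver/float noise level relative to
    # the data scale counts as an exact fit (finite-precision OLS/NLS never
    # returns a literal 0 residual vector)
    scale = max(1.0, float(np.max(np.abs(obs))))
    perfect = rmse <= 1e-8 * scale
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if perfect else -np.inf)
    if perfect:
        aic = bic = -np.inf
    else:
        aic = n * np.log(rss / n) + 2 * n_params
        bic = n * np.log(rss / n) + n_params * np.log(n)
    return rss, rmse, r2, float(aic), float(bic)


def _build_fit(family, series, params, std_errors, ci95, flags=None):
    curve = FAMILY_CURVES[family]
    fitted = curve(series.time_index, *params.values())
    resid = series.cumulative_counts - fitted
    rss, rmse, r2, aic, bic = compute_fit_metrics(
        series.cumulative_counts, fitted, N_PARAMS[family]
    )
    flags = dict(flags or {})
    if np.isneginf(aic):
        flags["perfect_fit"] = True
    return GrowthFit(
        family=family,
        params=params,
        std_errors=std_errors,
        ci95=ci95,
        fitted_values=fitted,
        residuals=resid,
        rss=rss,
        rmse=rmse,
        r2=r2,
        aic=aic,
        bic=bic,
        n_obs=series.n_obs,
        n_params=N_PARAMS[family],
        flags=flags,
    )


def _ols(y, t):
    res = sm.OLS(y, sm.add_constant(t.astype(float))).fit()
    ci = res.conf_int(alpha=0.05)
    return res, np.asarray(ci)


def fit_linear(series: ADRSeries) -> GrowthFit:
    """Ordinary least squares of cumulative count on time, Y = a + b·t.

    Standard errors and 95% confidence intervals come from the usual
    t-distribution with n − 2 degrees of freedom.
    """
    if series.n_obs < 4:
        raise FitError("linear fit needs at least 4 observations")
    t = series.time_index
    if np.ptp(t) == 0:
        raise FitError("degenerate time axis")
    res, ci = _ols(series.cumulative_counts, t)
    params = {"a": float(res.params[0]), "b": float(res.params[1])}
    ses = {"a": float(res.bse[0]), "b": float(res.bse[1])}
    cis = {"a": (float(ci[0, 0]), float(ci[0, 1])), "b": (float(ci[1, 0]), float(ci[1, 1]))}
    return _build_fit("linear", series, params, ses, cis)


def fit_exponential(series: ADRSeries, method: str = "log_linear") -> GrowthFit:
    """Fit Y = α·exp(β·t); β is the Detriment Index.

    ``log_linear`` (default) regresses ln Y on t by OLS — deterministic and
    exactly scale-invariant in β — then reports RSS/RMSE/R²/AIC/BIC on the
    original count scale from Y − α̂·exp(β̂·t).  ``nls`` refines the
    log-linear solution by least squares on the original scale.  Leading
    zero cumulative values are dropped (with a warning) before the
    log-linear regression; interior non-positive values are an error.
    """
    if method not in ("log_linear", "nls"):
        raise ValueError(f"unknown method {method!r}")
    y_full = series.cumulative_counts
    t_full = series.time_index.astype(float)

    lead = int(np.argmax(y_full > 0)) if np.any(y_full > 0) else len(y_full)
    if lead == len(y_full):
        raise FitError("all-zero series: exponential fit infeasible (flat convention is β=0)")
    y, t = y_full[lead:], t_full[lead:]
    if lead and method == "log_linear":
        warnings.warn(
            f"dropping {lead} leading zero cumulative value(s) before log-linear fit",
            stacklevel=2,
        )
    if np.any(y <= 0):
        raise FitError(
            "non-positive cumulative values inside the series: drop leading zeros "
            "or use method='nls'"
        )
    if len(y) < 4:
        raise FitError("exponential fit needs at least 4 positive observations")

    res, ci = _ols(np.log(y), t)
    ln_alpha, beta = float(res.params[0]), float(res.params[1])
    alpha = float(np.exp(ln_alpha))

    if method == "log_linear":
        # delta-method SE for α from the SE of ln α
        params = {"alpha": alpha, "beta": beta}
        ses = {"alpha": alpha * float(res.bse[0]), "beta": float(res.bse[1])}
        cis = {
            "alpha": (float(np.exp(ci[0, 0])), float(np.exp(ci[0, 1]))),
            "beta": (float(ci[1, 0]), float(ci[1, 1])),
        }
        flags = {"method": "log_linear"}
        if lead:
            flags["leading_zeros_dropped"] = lead
        return _build_fit("exponential", series, params, ses, cis, flags)

    def resid(p):
        return exponential_curve(t_full, *p) - y_full

    sol = optimize.least_squares(
        resid, x0=[alpha, beta], max_nfev=MAX_NFEV, ftol=RSS_TOL, xtol=1e-12, gtol=1e-12
    )
    if not sol.success:
        raise FitError("exponential NLS did not converge", last_iterate=sol.x)
    names = ["alpha", "beta"]
    params = dict(zip(names, map(float, sol.x)))
    ses, cis = _wald_intervals(sol, series.n_obs, len(names), names)
    return _build_fit("exponential", series, params, ses, cis, {"method": "nls"})


def _wald_intervals(sol, n, p, names):
    """Asymptotic SEs and 95% t-Wald CIs from the Jacobian at the solution."""
    dof = n - p
    s2 = 2 * sol.cost / dof if dof > 0 else np.nan
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    ses = dict(zip(names, map(float, se)))
    cis = {
        nm: (float(x - tq * s), float(x + tq * s))
        for nm, x, s in zip(names, sol.x, se)
    }
    return ses, cis


def _nls(series, family, x0, names, bounds=(-np.inf, np.inf)):
    y = series.cumulative_counts
    t = series.time_index
    curve = FAMILY_CURVES[family]

    def resid(p):
        return curve(t, *p) - y

    sol = optimize.least_squares(
        resid, x0=x0, bounds=bounds, max_nfev=MAX_NFEV, ftol=RSS_TOL, xtol=1e-12, gtol=1e-12
    )
    if not sol.success:
        raise FitError(f"{family} fit did not converge", last_iterate=sol.x)
    params = dict(zip(names, map(float, sol.x)))
    ses, cis = _wald_intervals(sol, series.n_obs, len(names), names)
    return params, ses, cis


def fit_saturation_mm(series: ADRSeries) -> GrowthFit:
    """Shifted Michaelis–Menten saturation fit Y = Y0 + θ1·t/(θ2 + t).

    The baseline Y0 accommodates series that start above zero.  Starting
    values: Y0 ← first observation, θ1 ← rise (last − first), θ2 ← time at
    half-rise.  A converged fit with θ2 ≤ 0 is flagged invalid (excluded
    from model selection) rather than raised.
    """
    if series.n_obs < 5:
        raise FitError("saturation fit needs at least 5 observations")
    y = series.cumulative_counts
    t = series.time_index
    y0_init = float(y[0])
    theta1_init = float(y[-1] - y[0])
    half = y0_init + theta1_init / 2.0
    above = np.nonzero(y >= half)[0]
    theta2_init = float(t[above[0]]) if len(above) else float(t[-1] / 2)
    if theta1_init == 0:
        theta1_init, theta2_init = 0.0, 1.0
    params, ses, cis = _nls(
        series, "saturation_mm", [y0_init, max(theta1_init, 0.0), max(theta2_init, 1e-3)],
        ["y0", "theta1", "theta2"],
    )
    flags = {}
    if params["theta2"] <= 0 or params["theta1"] < 0:
        flags["invalid"] = True
        flags["reason"] = "saturation parameters out of range (need theta1 >= 0, theta2 > 0)"
    return _build_fit("saturation_mm", series, params, ses, cis, flags)


def fit_logistic(series: ADRSeries) -> GrowthFit:
    """Logistic (sigmoidal) fit Y = L/(1 + exp(−k·(t − t0))).

    Starting values: L ← 1.05·max(Y); t0 ← first time Y exceeds L/2; k from
    the slope of the logit-linearised regression ln(Y/(L−Y)) on t.  A fit
    with k̂ ≤ 0 is flagged invalid.
    """
    if series.n_obs < 5:
        raise FitError("logistic fit needs at least 5 observations")
    y = series.cumulative_counts
    t = series.time_index.astype(float)
    L0 = 1.05 * float(y.max())
    if L0 <= 0:
        raise FitError("logistic fit infeasible on an all-zero series")
    above = np.nonzero(y > L0 / 2)[0]
    t0_init = float(t[above[0]]) if len(above) else float(t[-1])
    pos = (y > 0) & (y < L0)
    if pos.sum() >= 2:
        z = np.log(y[pos] / (L0 - y[pos]))
        k_init = float(np.polyfit(t[pos], z, 1)[0])
    else:
        k_init = 0.5
    if not np.isfinite(k_init) or k_init <= 0:
        k_init = 0.5
    params, ses, cis = _nls(
        series, "logistic", [L0, k_init, t0_init], ["L", "k", "t0"],
        bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
    )
    flags = {}
    if params["k"] <= 0:
        flags["invalid"] = True
        flags["reason"] = "logistic growth rate k <= 0"
    return _build_fit("logistic", series, params, ses, cis, flags)


def residual_diagnostics(fit: GrowthFit, plot_prefix=None) -> dict:
    """Numeric residual summaries (and optional diagnostic plots).

    Returns mean, standard deviation, skewness, lag-1 autocorrelation, a
    Shapiro–Wilk normality p-value and the extreme standardized residuals.
    Zero-variance residuals give all-zero summaries with a
    ``degenerate`` flag (the normality test is skipped).  When
    ``plot_prefix`` is given, residual-vs-fitted and Q–Q plots are written
    to ``<prefix>_resid.png`` and ``<prefix>_qq.png``.
    """
    if fit.n_obs < 5:
        raise ValueError("diagnostics need at least 5 observations")
    r = np.asarray(fit.residuals, dtype=float)
    out = {
        "mean": float(r.mean()),
        "std": float(r.std(ddof=0)),
        "skewness": 0.0,
        "lag1_autocorr": 0.0,
        "normality_p": np.nan,
        "std_resid_min": 0.0,
        "std_resid_max": 0.0,
        "degenerate": False,
    }
    scale = max(1.0, float(np.max(np.abs(fit.fitted_values))))
    if out["std"] <= 1e-10 * scale:
        out["degenerate"] = True
        if abs(out["mean"]) <= 1e-10 * scale:
            out["mean"] = 0.0
        out["std"] = 0.0
    else:
        out["skewness"] = float(stats.skew(r, bias=True))
        c = r - r.mean()
        out["lag1_autocorr"] = float(np.sum(c[:-1] * c[1:]) / np.sum(c**2))
        out["normality_p"] = float(stats.shapiro(r).pvalue)
        z = c / out["std"]
        out["std_resid_min"] = float(z.min())
        out["std_resid_max"] = float(z.max())
    if plot_prefix is not None:
        _write_diagnostic_plots(fit, plot_prefix)
    return out


def _write_diagnostic_plots(fit, prefix):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.scatter(fit.fitted_values, fit.residuals)
    ax.axhline(0.0, color="grey", lw=1)
    ax.set_xlabel("fitted cumulative count")
    ax.set_ylabel("residual")
    fig.savefig(f"{prefix}_resid.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    stats.probplot(fit.residuals, dist="norm", plot=ax)
    fig.savefig(f"{prefix}_qq.png", dpi=100)
    plt.close(fig)
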
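"""Sigmoid growth-curve fitting and growth-phase segmentation.

Monoculture/co-culture abundance trajectories are fitted with the three
classic sigmoid growth equations

* logistic   ``f(t) = K / (1 + exp(-r (t - t_m)))``
* Gompertz   ``f(t) = K exp(-exp(-r (t - t_m)))``
* Richards   ``f(t) = K (1 + nu exp(-r (t - t_m)))^(-1/nu)``  (nu > 0)

where ``K`` is the carrying capacity (asymptote), ``r`` the rate parameter
and ``t_m`` the inflection-region location; the Richards shape ``nu``
interpolates between Gompertz (nu -> 0) and beyond-logistic forms (nu = 1
is exactly logistic).  The best model is chosen by the small-sample
corrected information criterion (AICc) by default.

Phases are segmented from the fitted curve: the lag phase ends where the
growth *acceleration* f'' is maximal, the log (exponential) phase ends
where the deceleration is maximal (f'' minimal).  For the logistic these
are the closed-form points ``t_m ± ln(2 + sqrt(3)) / r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "MODELS",
    "fit_growth",
    "segment_phases",
    "f_test",
    "fit_table",
]


def logistic(t, K, r, t_m):
    return K / (1.0 + np.exp(-r * (t - t_m)))


def gompertz(t, K, r, t_m):
    return K * np.exp(-np.exp(-r * (t - t_m)))


def richards(t, K, r, t_m, nu):
    return K * (1.0 + nu * np.exp(-r * (t - t_m))) ** (-1.0 / nu)


MODELS = {
    "logistic": (logistic, ("K", "r", "t_m")),
    "gompertz": (gompertz, ("K", "r", "t_m")),
    "richards": (richards, ("K", "r", "t_m", "nu")),
}


@dataclass(frozen=True)
class GrowthSeries:
    """An abundance time series for one strain in one culture."""

    times: np.ndarray
    abundances: np.ndarray
    strain_id: str = ""
    culture_kind: str = "mono"  # {mono, co}

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "abundances", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and abundances must be 1-D and equal length")
        if len(t) < 5:
            raise ValueError(f"need >= 5 time points to fit, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("abundances must be nonnegative")


@dataclass
class GrowthFit:
    """One fitted growth model plus selection and segmentation results."""

    model_name: str
    parameters: dict
    rss: float
    sigma2: float
    criterion: str
    score: float
    n: int
    all_scores: dict = field(default_factory=dict)
    phase_boundaries: tuple = None  # (lag_end_h, log_end_h)
    window: tuple = None

    def predict(self, t):
        fun, names = MODELS[self.model_name]
        return fun(np.asarray(t, dtype=float), *[self.parameters[k] for k in names])


def _aicc(rss, n, k):
    # k counts the variance as a parameter
    k = k + 1
    score = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        score += 2 * k * (k + 1) / (n - k - 1)
    return score


def _bic(rss, n, k):
    return n * np.log(rss / n) + (k + 1) * np.log(n)


_CRITERIA = {"aicc": _aicc, "bic": _bic}


def _initial_guess(t, y, model):
    K0 = max(y.max(), 1e-12)
    # rate from the log-slope of the middle third of the rise
    lo, hi = np.quantile(t, [1 / 3, 2 / 3])
    mid = (t >= lo) & (t <= hi) & (y > 0)
    if mid.sum() >= 2:
        slope = np.polyfit(t[mid], np.log(y[mid]), 1)[0]
        r0 = float(np.clip(abs(slope), 1e-3, 50.0))
    else:
        r0 = 1.0
    # inflection near the half-max crossing
    above = np.nonzero(y >= K0 / 2)[0]
    t_m0 = t[above[0]] if len(above) else t[len(t) // 2]
    if model == "richards":
        return [K0, r0, t_m0, 1.0]
    return [K0, r0, t_m0]


def _fit_one(t, y, model, seed):
    fun, names = MODELS[model]
    p0 = _initial_guess(t, y, model)
    span = t[-1] - t[0]
    lower = [1e-12, 1e-6, t[0] - 5 * span] + ([1e-6] if model == "richards" else [])
    upper = [np.inf, np.inf, t[-1] + 5 * span] + ([50.0] if model == "richards" else [])
    rng = np.random.default_rng(seed)
    starts = [p0] + [
        [p * float(j) for p, j in zip(p0, rng.lognormal(0.0, 0.3, len(p0)))]
        for _ in range(5)
    ]
    best = None
    for start in starts:
        start = np.clip(start, lower, upper)
        try:
            popt, _ = optimize.curve_fit(
                fun, t, y, p0=start, bounds=(lower, upper), maxfev=20000,
                xtol=1e-14, ftol=1e-14,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - fun(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss < 1e-20:
            break
    if best is None:
        return None
    popt, rss = best
    return dict(zip(names, popt)), rss


def fit_growth(
    series: GrowthSeries,
    *,
    criterion: str = "aicc",
    models=("gompertz", "logistic", "richards"),
    seed: int = 0,
    segment: bool = True,
) -> GrowthFit:
    """Fit the candidate growth equations and select the best one.

    All requested models are fitted by nonlinear least squares with
    data-driven starting values and a fixed-seed multi-start; the model
    minimizing the configured information criterion wins.  If no model
    converges an error naming the series is raised; if some fail, the best
    among the converged is returned.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {list(_CRITERIA)}")
    t, y = series.times, series.abundances
    if np.ptp(y) == 0:
        raise ValueError(
            f"constant series {series.strain_id!r}: growth fit degenerate (K = const, r -> 0)"
        )
    n = len(t)
    # an exact fit leaves only rounding noise in the RSS; floor it at a
    # sqrt(eps) relative scale so effectively-exact fits tie and the
    # parsimony penalty decides between them
    rss_floor = n * (np.sqrt(np.finfo(float).eps) * np.max(np.abs(y))) ** 2
    fits, scores = {}, {}
    for model in models:
        res = _fit_one(t, y, model, seed)
        if res is None:
            continue
        params, rss = res
        fits[model] = (params, rss)
        scores[model] = _CRITERIA[criterion](max(rss, rss_floor), n, len(params))
    if not fits:
        raise RuntimeError(
            f"no growth model converged for series {series.strain_id!r} ({series.culture_kind})"
        )
    best = min(scores, key=scores.get)
    params, rss = fits[best]
    fit = GrowthFit(
        model_name=best,
        parameters=params,
        rss=rss,
        sigma2=rss / n,
        criterion=criterion,
        score=scores[best],
        n=n,
        all_scores=scores,
        window=(float(t[0]), float(t[-1])),
    )
    if segment:
        fit.phase_boundaries = segment_phases(fit)
    return fit


def f_test(fit_small: GrowthFit, fit_big: GrowthFit) -> float:
    """RSS F-comparison of two nested fits; returns the p-value."""
    k1 = len(fit_small.parameters)
    k2 = len(fit_big.parameters)
    if k2 <= k1:
        raise ValueError("fit_big must have more parameters than fit_small")
    n = fit_small.n
    num = (fit_small.rss - fit_big.rss) / (k2 - k1)
    den = fit_big.rss / (n - k2)
    if den <= 0:
        return 0.0
    F = num / den
    return float(stats.f.sf(F, k2 - k1, n - k2))


def segment_phases(fit: GrowthFit) -> tuple:
    """Locate lag/log phase boundaries from the fitted curve.

    Returns ``(lag_end, log_end)``: the times of maximum acceleration and
    maximum deceleration of the fitted sigmoid.  For all three models the
    extrema of f'' occur where, in the substitution
    ``u = exp(-r (t - t_m))``, the quadratic ``u^2 - (3 + nu) u + 1``
    vanishes (nu = 1 logistic, nu -> 0 Gompertz, nu free for Richards), so
    boundaries are closed-form: the logistic case reduces to
    ``t_m ± ln(2 + sqrt(3)) / r``.  Boundaries outside the observed window
    are clamped with a warning.
    """
    p = fit.parameters
    nu = {"logistic": 1.0, "gompertz": 0.0}.get(fit.model_name, p.get("nu", 1.0))
    s = 3.0 + nu
    disc = np.sqrt(s * s - 4.0)
    u_hi = (s + disc) / 2.0  # maximum acceleration (t < t_m side)
    u_lo = (s - disc) / 2.0  # maximum deceleration
    lag_end = p["t_m"] - np.log(u_hi) / p["r"]
    log_end = p["t_m"] - np.log(u_lo) / p["r"]
    lo, hi = fit.window
    clamped = (min(max(lag_end, lo), hi), min(max(log_end, lo), hi))
    if clamped != (lag_end, log_end):
        warnings.warn(
            f"phase boundary outside observed window [{lo}, {hi}]; clamped", stacklevel=2
        )
    return clamped


def fit_table(long_df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every (strain, culture) series in a long-format table.

    Expects columns ``strain_id, culture_kind, time_h, abundance``.
    Returns one row per series with the selected model, parameters,
    criterion score, and phase boundaries.
    """
    rows = []
    for (strain, kind), grp in long_df.groupby(["strain_id", "culture_kind"]):
        grp = grp.sort_values("time_h")
        series = GrowthSeries(
            grp["time_h"].to_numpy(), grp["abundance"].to_numpy(), strain, kind
        )
        fit = fit_growth(series, **kwargs)
        rows.append(
            {
                "strain_id": strain,
                "culture_kind": kind,
                "model": fit.model_name,
                **{f"param_{k}": v for k, v in fit.parameters.items()},
                "rss": fit.rss,
                "score": fit.score,
                "lag_end_h": fit.phase_boundaries[0],
                "log_end_h": fit.phase_boundaries[1],
            }
        )
    return pd.DataFrame(rows)


def assign_phases(times, fit: GrowthFit) -> np.ndarray:
    """Label each time point lag/log/stationary from fitted boundaries."""
    lag_end, log_end = fit.phase_boundaries
    times = np.asarray(times, dtype=float)
    out = np.full(times.shape, "log", dtype=object)
    out[times < lag_end] = "lag"
    out[times > log_end] = "stationary"
    return out
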
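"""Performance summaries and psychometric fitting.

``summarize`` turns a session log into proportion-correct tables with binomial
standard errors (and across-observer mean ± SEM when several observers
contributed).  ``fit_psychometric`` performs maximum-likelihood binomial fits
of Weibull or logistic performance functions with the guess rate fixed by the
task design (1/3 for the 3AFC oddity task, 1/2 for the two-choice
displacement-limit task) and a bounded lapse rate, and reads off the stimulus
level at a stated criterion (e.g. the displacement supporting 75% correct —
the displacement limit D_max).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "summarize",
    "PsychometricFit",
    "fit_psychometric",
    "threshold_highest_passing",
    "bootstrap_ci",
]


def summarize(log: pd.DataFrame, by: str = "condition_param") -> pd.DataFrame:
    """Proportion correct per condition from a session log.

    Invalid trials are excluded (and counted in ``n_invalid``).  When the log
    holds several observers, per-observer proportions are averaged and the
    error bar is ±1 SEM across observers; with a single observer the error
    column is the binomial standard error ``sqrt(p(1−p)/n)``.  Conditions with
    zero valid trials are omitted with a warning.
    """
    if log.empty:
        raise ValueError("cannot summarize an empty session log")
    rows = []
    for param, grp in log.groupby(by, sort=True):
        valid = grp[grp["valid"].astype(bool)]
        n_invalid = len(grp) - len(valid)
        if valid.empty:
            warnings.warn(f"condition {param!r} has no valid trials; omitted")
            continue
        n = len(valid)
        k = int(valid["correct"].astype(bool).sum())
        p = k / n
        observers = valid["observer"].unique()
        if len(observers) > 1:
            per_obs = valid.groupby("observer")["correct"].mean().to_numpy(float)
            p = float(per_obs.mean())
            err = float(per_obs.std(ddof=1) / np.sqrt(per_obs.size))
            err_kind = "sem_across_observers"
        else:
            err = float(np.sqrt(p * (1.0 - p) / n))
            err_kind = "binomial_se"
        rows.append(
            {
                by: param,
                "n_trials": n,
                "n_correct": k,
                "n_invalid": n_invalid,
                "proportion_correct": p,
                "error": err,
                "error_kind": err_kind,
                "n_observers": len(observers),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted performance curve and its threshold at a stated criterion."""

    family: str  # "weibull" | "logistic"
    guess: float  # fixed lower asymptote γ
    lapse: float  # fitted lapse rate λ
    params: tuple[float, float]  # (scale α, shape β) or (midpoint m, spread s)
    increasing: bool
    criterion: float
    threshold: float  # stimulus level where the curve crosses the criterion
    threshold_method: str  # "fit" | "highest_passing"
    slope_at_threshold: float
    nll: float
    converged: bool
    extrapolated: bool  # criterion crossing lies outside the tested levels

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _predict(
            x, self.family, self.guess, self.lapse, self.params, self.increasing
        )


def _core(x, family, params, increasing):
    if family == "weibull":
        alpha, beta = params
        f = 1.0 - np.exp(-np.power(np.maximum(x, 1e-12) / alpha, beta))
    elif family == "logistic":
        m, s = params
        f = expit((x - m) / s)
    else:
        raise ValueError(f"unknown family {family!r}")
    return f if increasing else 1.0 - f


def _predict(x, family, guess, lapse, params, increasing):
    return guess + (1.0 - guess - lapse) * _core(x, family, params, increasing)


def _invert(criterion, family, guess, lapse, params, increasing):
    """Stimulus level where the fitted curve equals ``criterion`` (or NaN)."""
    q = (criterion - guess) / (1.0 - guess - lapse)
    if not increasing:
        q = 1.0 - q
    if not 0.0 < q < 1.0:
        return float("nan")
    if family == "weibull":
        alpha, beta = params
        return float(alpha * (-np.log1p(-q)) ** (1.0 / beta))
    m, s = params
    return float(m + s * logit(q))


def fit_psychometric(
    levels,
    n_trials,
    n_correct,
    family: str = "weibull",
    guess: float = 1.0 / 3.0,
    criterion: float = 0.75,
    lapse_max: float = 0.06,
    increasing: bool | None = None,
) -> PsychometricFit:
    """Maximum-likelihood binomial fit of a psychometric function.

    Parameters
    ----------
    levels, n_trials, n_correct : aligned arrays per stimulus level.
    family : "weibull" (scale/shape, positive levels) or "logistic".
    guess : fixed lower asymptote γ (1/3 oddity, 1/2 displacement limit).
    criterion : performance criterion for the reported threshold; must exceed γ.
    lapse_max : upper bound on the free lapse rate λ.
    increasing : direction of the curve; inferred from the data when ``None``
        (a displacement-limit curve is decreasing in displacement).

    The fit is deterministic: a small fixed grid of starting points, refined
    with L-BFGS-B.  If the fitted curve never reaches the criterion inside the
    tested levels the ``extrapolated`` flag is set (flat-at-chance data yield
    a NaN threshold).
    """
    x = np.asarray(levels, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    if not (x.shape == n.shape == k.shape) or x.size < 3:
        raise ValueError("need >= 3 aligned stimulus levels")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("n_correct must lie in [0, n_trials]")
    if criterion <= guess:
        raise ValueError(f"criterion {criterion} must exceed the guess rate {guess}")
    if increasing is None:
        p_obs = k / np.maximum(n, 1)
        increasing = bool(np.polyfit(x, p_obs, 1)[0] >= 0)

    span = float(x.max() - x.min()) or 1.0

    def nll(theta):
        lapse = theta[2]
        if family == "weibull":
            params = (np.exp(theta[0]), np.exp(theta[1]))
        else:
            params = (theta[0], np.exp(theta[1]))
        p = _predict(x, family, guess, lapse, params, increasing)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    if family == "weibull":
        loc_starts = [np.log(max(v, 1e-6)) for v in (x.min() + span / 4, np.median(x), x.max())]
        scale_starts = [np.log(1.0), np.log(3.0)]
        bounds = [(None, None), (np.log(1e-2), np.log(50.0)), (0.0, lapse_max)]
    elif family == "logistic":
        loc_starts = [x.min() + span / 4, float(np.median(x)), x.max() - span / 4]
        scale_starts = [np.log(span / 10), np.log(span / 4)]
        bounds = [(None, None), (np.log(span * 1e-3), np.log(span * 10)), (0.0, lapse_max)]
    else:
        raise ValueError(f"unknown family {family!r}")

    best = None
    for loc0 in loc_starts:
        for sc0 in scale_starts:
            res = minimize(
                nll,
                np.array([loc0, sc0, 0.01]),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    theta = best.x
    lapse = float(theta[2])
    if family == "weibull":
        params = (float(np.exp(theta[0])), float(np.exp(theta[1])))
    else:
        params = (float(theta[0]), float(np.exp(theta[1])))

    threshold = _invert(criterion, family, guess, lapse, params, increasing)
    p_at_levels = _predict(x, family, guess, lapse, params, increasing)
    lo, hi = float(p_at_levels.min()), float(p_at_levels.max())
    extrapolated = bool(
        np.isnan(threshold)
        or not (x.min() - 1e-9 <= threshold <= x.max() + 1e-9)
        or not (lo - 1e-9 <= criterion <= hi + 1e-9)
    )
    if np.isnan(threshold):
        slope = float("nan")
    else:
        h = 1e-4 * span
        slope = float(
            (
                _predict(threshold + h, family, guess, lapse, params, increasing)
                - _predict(threshold - h, family, guess, lapse, params, increasing)
            )
            / (2 * h)
        )
    return PsychometricFit(
        family=family,
        guess=guess,
        lapse=lapse,
        params=params,
        increasing=increasing,
        criterion=criterion,
        threshold=threshold,
        threshold_method="fit",
        slope_at_threshold=slope,
        nll=float(best.fun),
        converged=bool(best.success),
        extrapolated=extrapolated,
    )


def threshold_highest_passing(levels, n_trials, n_correct, criterion: float = 0.75):
    """Model-free threshold: the largest level whose raw proportion correct
    still meets the criterion (assumes performance declines with the level, as
    in the displacement-limit task).  Returns NaN when no level passes."""
    x = np.asarray(levels, dtype=float)
    p = np.asarray(n_correct, dtype=float) / np.asarray(n_trials, dtype=float)
    passing = x[p >= criterion]
    return float(passing.max()) if passing.size else float("nan")


def bootstrap_ci(
    levels,
    n_trials,
    n_correct,
    fit: PsychometricFit,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for the threshold and lapse.

    Trials are resampled within each level (parametric binomial resampling of
    the observed proportions), the curve refitted per replicate, and central
    ``ci`` percentile intervals returned.  Reproducible from the RNG.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(levels, dtype=float)
    n = np.asarray(n_trials, dtype=int)
    k = np.asarray(n_correct, dtype=int)
    p_hat = k / n
    thresholds, lapses = [], []
    for _ in range(n_boot):
        k_b = rng.binomial(n, p_hat)
        f = fit_psychometric(
            x,
            n,
            k_b,
            family=fit.family,
            guess=fit.guess,
            criterion=fit.criterion,
            increasing=fit.increasing,
        )
        thresholds.append(f.threshold)
        lapses.append(f.lapse)
    q = [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100]
    thr = np.asarray(thresholds, dtype=float)
    thr = thr[np.isfinite(thr)]
    out = {}
    out["threshold"] = tuple(np.percentile(thr, q)) if thr.size else (float("nan"),) * 2
    out["lapse"] = tuple(np.percentile(np.asarray(lapses), q))
    return out
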
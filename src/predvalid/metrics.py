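"""Performance measures for binary-outcome risk models.

Three measures carry the whole validation framework:

* **c statistic** — the concordance probability: among all event/non-event
  pairs, the fraction in which the event individual received the higher
  estimated risk, ties counting 1/2. 0.5 is coin-toss discrimination, 1 is
  perfect. Standard error by DeLong's method (default) or bootstrap.
* **calibration slope** — the coefficient from a logistic regression of the
  outcome on the model's linear predictor (free intercept). Ideal value 1;
  below 1 the estimated risks are too extreme (the signature of
  overfitting), above 1 too narrow.
* **calibration-in-the-large (CITL)** — the intercept from a logistic fit
  with the linear predictor as a fixed offset. Ideal value 0; negative
  means risks are systematically too high, positive too low.

A flexible calibration curve (smoothed observed proportion vs estimated
risk) complements the two calibration scalars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import Dataset
from .errors import (DataError, DegenerateOutcomeError, FittingError,
                     InsufficientDataError)
from .model import _MAXITER, FittedModel

_Z95 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class MetricEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    def round(self, k: int) -> tuple[float, float, float]:
        return (round(self.estimate, k), round(self.ci_low, k), round(self.ci_high, k))


def _check_two_class(outcome: np.ndarray) -> np.ndarray:
    outcome = np.asarray(outcome)
    if outcome.sum() == 0 or outcome.sum() == len(outcome):
        raise DegenerateOutcomeError(
            "outcome contains a single class; measure undefined")
    return outcome


def _delong(risks: np.ndarray, outcome: np.ndarray) -> tuple[float, float]:
    """Concordance probability and its DeLong variance via midrank placements."""
    pos = risks[outcome == 1]
    neg = risks[outcome == 0]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n          # placement of each event among non-events
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # placement of each non-event among events
    c = float(v10.mean())
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    else:
        var = np.nan
    return c, float(var)


def c_statistic(risks, outcome, ci_method: str = "delong",
                n_boot: int = 1000, seed: int = 0) -> MetricEstimate:
    """Concordance statistic with SE and 95% CI (clipped to [0, 1]).

    ``ci_method``: ``"delong"`` (default) or ``"bootstrap"``
    (percentile CI over ``n_boot`` resamples of individuals).
    """
    risks = np.asarray(risks, dtype=float)
    outcome = _check_two_class(outcome)
    if len(risks) != len(outcome):
        raise DataError("risks and outcome lengths differ")
    c, var = _delong(risks, outcome)
    if ci_method == "delong":
        se = float(np.sqrt(var)) if np.isfinite(var) else np.nan
        lo, hi = c - _Z95 * se, c + _Z95 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(outcome)
        cs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            y = outcome[idx]
            if 0 < y.sum() < n:
                cs.append(_delong(risks[idx], y)[0])
        cs = np.asarray(cs)
        se = float(cs.std(ddof=1))
        lo, hi = np.quantile(cs, [0.025, 0.975])
    else:
        raise ValueError(f"unknown ci_method '{ci_method}'")
    return MetricEstimate(c, se, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def _glm_logistic(y, X, offset=None, context=None):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # separation re-checked below
            res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset
                         ).fit(maxiter=_MAXITER, tol=1e-10)
    except Exception as exc:
        raise FittingError(f"calibration refit failed: {exc}", context=context) from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise FittingError("calibration refit gave non-finite estimates "
                           "(separation?)", context=context)
    return res


def calibration_slope(linear_predictor, outcome,
                      context: str | None = None) -> MetricEstimate:
    """Slope of logistic(outcome ~ intercept + linear_predictor); ideal 1."""
    lp = np.asarray(linear_predictor, dtype=float)
    outcome = _check_two_class(outcome)
    if np.ptp(lp) == 0:
        raise DataError("linear predictor is constant; calibration slope "
                        "unidentifiable")
    X = np.column_stack([np.ones_like(lp), lp])
    res = _glm_logistic(outcome.astype(float), X, context=context)
    b, se = float(res.params[1]), float(res.bse[1])
    return MetricEstimate(b, se, b - _Z95 * se, b + _Z95 * se)


def calibration_in_the_large(linear_predictor, outcome,
                             context: str | None = None) -> MetricEstimate:
    """Intercept of logistic(outcome ~ intercept, offset=linear_predictor); ideal 0."""
    lp = np.asarray(linear_predictor, dtype=float)
    outcome = _check_two_class(outcome)
    res = _glm_logistic(outcome.astype(float), np.ones((len(lp), 1)),
                        offset=lp, context=context)
    a, se = float(res.params[0]), float(res.bse[0])
    return MetricEstimate(a, se, a - _Z95 * se, a + _Z95 * se)


@dataclass
class CalibrationCurve:
    grid: np.ndarray          # estimated risks, strictly increasing
    observed: np.ndarray      # smoothed observed proportions, in [0, 1]
    smoother_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimated_risk": self.grid,
                             "observed_proportion": self.observed})


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond boundary knots."""
    k = knots
    K = len(k)
    def d(j):
        num = np.maximum(x - k[j], 0) ** 3 - np.maximum(x - k[K - 1], 0) ** 3
        return num / (k[K - 1] - k[j])
    cols = [x]
    for j in range(K - 2):
        cols.append(d(j) - d(K - 2) * (k[K - 1] - k[j]) / (k[K - 1] - k[K - 2]))
    return np.column_stack(cols)


def calibration_curve(risks, outcome, smoother: str = "lowess",
                      grid_size: int = 100, min_n: int = 50) -> CalibrationCurve:
    """Smoothed flexible calibration curve: observed proportion vs estimated risk.

    ``smoother="lowess"`` (default) runs a local-polynomial smoother of the
    0/1 outcome on the risk scale; ``smoother="spline"`` fits a logistic
    regression on a restricted cubic spline (4 knots) of logit(risk).
    Requires at least ``min_n`` individuals; below that, grouped
    (decile-style) calibration is the sensible fallback.
    """
    risks = np.asarray(risks, dtype=float)
    outcome = _check_two_class(outcome)
    if len(risks) < min_n:
        raise InsufficientDataError(
            f"{len(risks)} individuals < smoother floor {min_n}; "
            "use grouped observed/expected proportions instead")
    lo, hi = np.quantile(risks, [0.01, 0.99])
    if hi <= lo:
        raise DataError("risks are (nearly) constant; no curve to draw")
    grid = np.linspace(lo, hi, grid_size)
    if smoother == "lowess":
        obs = lowess(outcome.astype(float), risks, frac=0.6, it=0,
                     xvals=grid, return_sorted=False)
    elif smoother == "spline":
        z = logit(np.clip(risks, 1e-12, 1 - 1e-12))
        knots = np.quantile(z, [0.05, 0.35, 0.65, 0.95])
        X = sm.add_constant(_rcs_basis(z, knots))
        res = _glm_logistic(outcome.astype(float), X)
        zg = logit(np.clip(grid, 1e-12, 1 - 1e-12))
        obs = res.predict(sm.add_constant(_rcs_basis(zg, knots), has_constant="add"))
    else:
        raise ValueError(f"unknown smoother '{smoother}'")
    return CalibrationCurve(grid=grid, observed=np.clip(obs, 0, 1),
                            smoother_name=smoother)


@dataclass
class PerformanceResult:
    """The three performance measures plus provenance."""

    c_statistic: MetricEstimate
    calibration_slope: MetricEstimate
    calibration_in_the_large: MetricEstimate
    strategy_tag: str
    n_eval: int
    n_events_eval: int

    MEASURES = ("c_statistic", "calibration_slope", "calibration_in_the_large")

    def estimates(self) -> dict[str, float]:
        return {m: getattr(self, m).estimate for m in self.MEASURES}

    def to_dict(self) -> dict:
        out = {"strategy": self.strategy_tag, "n": self.n_eval,
               "n_events": self.n_events_eval}
        for m in self.MEASURES:
            e = getattr(self, m)
            out[m] = {"estimate": e.estimate, "se": e.se,
                      "ci_low": e.ci_low, "ci_high": e.ci_high}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.MEASURES:
            e = getattr(self, m)
            rows.append({"strategy": self.strategy_tag, "measure": m,
                         "estimate": e.estimate, "se": e.se,
                         "ci_low": e.ci_low, "ci_high": e.ci_high,
                         "n": self.n_eval, "n_events": self.n_events_eval})
        return pd.DataFrame(rows)


def performance_report(model: FittedModel, data: Dataset, tag: str,
                       context: str | None = None) -> PerformanceResult:
    """Evaluate a fitted model on a dataset: c, slope, CITL in one pass."""
    if data.n == 0:
        raise DataError("cannot evaluate on an empty dataset")
    lp = model.linear_predictor(data)
    risks = expit(lp)
    return PerformanceResult(
        c_statistic=c_statistic(risks, data.outcome),
        calibration_slope=calibration_slope(lp, data.outcome, context=context),
        calibration_in_the_large=calibration_in_the_large(lp, data.outcome,
                                                          context=context),
        strategy_tag=tag, n_eval=data.n, n_events_eval=data.n_events,
    )
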
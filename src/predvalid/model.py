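"""Logistic model building, prediction, and coefficient shrinkage.

The central object is :class:`ModelBuilder`: a *reproducible recipe* for
turning a dataset into a fitted logistic model. Resampling-based validation
must repeat the entire recipe — including any predictor selection — inside
every bootstrap sample or cross-validation fold, not merely refit the final
coefficients; everything the recipe does is therefore encapsulated here and
is a pure function of (data, seed).

Shrinkage multiplies the regression coefficients by a uniform factor
(typically the optimism-corrected calibration slope, a value below 1 for an
overfit model) and then re-estimates the intercept so that the mean
predicted risk again matches the observed event fraction on the
development data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .data import Dataset
from .errors import DataError, FittingError

_MAXITER = 100


def _fit_logistic(X: np.ndarray, y: np.ndarray, context: str | None = None):
    """Maximum-likelihood logistic fit; raises FittingError on separation
    or non-convergence. X must already include the constant column.

    statsmodels' separation/convergence warnings are silenced here because
    the same conditions are re-checked below and surfaced as typed errors
    that resampling callers handle explicitly."""
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=_MAXITER)
    except Exception as exc:  # PerfectSeparationError and numerical failures
        raise FittingError(f"logistic fit failed: {exc}", context=context) from exc
    if not res.mle_retvals.get("converged", False):
        raise FittingError("logistic fit did not converge", context=context)
    if not np.all(np.isfinite(res.params)):
        raise FittingError("non-finite coefficients (separation?)", context=context)
    return res


@dataclass(frozen=True)
class FittedModel:
    """A logistic prediction model: intercept + named coefficients.

    risk_i = expit(intercept + sum_j coef_j * x_ij)
    """

    intercept: float
    coefficients: pd.Series  # index = predictor names

    def linear_predictor(self, data: Dataset | pd.DataFrame) -> np.ndarray:
        X = data.predictors if isinstance(data, Dataset) else data
        missing = [c for c in self.coefficients.index if c not in X.columns]
        if missing:
            raise DataError(f"predictor column(s) {missing} required by the model "
                            "are absent from the data")
        Xm = X[list(self.coefficients.index)].to_numpy(dtype=float)
        return self.intercept + Xm @ self.coefficients.to_numpy(dtype=float)

    def predict_risk(self, data: Dataset | pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))

    def to_json(self, **meta) -> str:
        return json.dumps({
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            **meta,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        obj = json.loads(text)
        return cls(intercept=float(obj["intercept"]),
                   coefficients=pd.Series(obj["coefficients"], dtype=float))


@dataclass
class ModelBuilder:
    """Reproducible model-building procedure.

    Parameters
    ----------
    predictor_set
        Candidate predictor names; ``None`` means every predictor column.
    selection_rule
        ``"none"`` fits all candidates (the default: the illustrative
        trauma-mortality model enters all 14 predictors, noise included);
        ``"backward"`` performs backward elimination at ``alpha``.
    alpha
        Wald p-value threshold for backward elimination. The default 0.157
        is the AIC-equivalent threshold for a 1-df predictor.
    """

    predictor_set: list[str] | None = None
    selection_rule: str = "none"
    alpha: float = 0.157

    def __post_init__(self):
        if self.selection_rule not in ("none", "backward"):
            raise ValueError(f"unknown selection_rule '{self.selection_rule}'")

    def candidates(self, data: Dataset) -> list[str]:
        if self.predictor_set is None:
            return data.predictor_names
        missing = [c for c in self.predictor_set if c not in data.predictor_names]
        if missing:
            raise DataError(f"candidate predictor(s) {missing} not in data")
        return list(self.predictor_set)

    def build(self, data: Dataset, seed: int = 0,
              context: str | None = None) -> FittedModel:
        """Apply the full recipe to ``data``. Deterministic given (data, seed);
        the seed is part of the contract so stochastic recipes stay
        reproducible, though the built-in rules are deterministic."""
        data.require_both_classes()
        cols = self.candidates(data)
        y = data.outcome.astype(float)
        if self.selection_rule == "backward":
            cols = self._backward_eliminate(data, cols, y, context)
        X = np.column_stack([np.ones(data.n)] +
                            [data.predictors[c].to_numpy(dtype=float) for c in cols])
        res = _fit_logistic(X, y, context=context)
        return FittedModel(intercept=float(res.params[0]),
                           coefficients=pd.Series(res.params[1:], index=cols, dtype=float))

    def _backward_eliminate(self, data: Dataset, cols: list[str],
                            y: np.ndarray, context: str | None) -> list[str]:
        cols = list(cols)
        while len(cols) > 1:
            X = np.column_stack([np.ones(data.n)] +
                                [data.predictors[c].to_numpy(dtype=float) for c in cols])
            res = _fit_logistic(X, y, context=context)
            pvals = pd.Series(res.pvalues[1:], index=cols)
            worst = pvals.idxmax()
            if pvals[worst] <= self.alpha:
                break
            cols.remove(worst)
        return cols

    def describe(self) -> dict:
        return {"predictor_set": self.predictor_set,
                "selection_rule": self.selection_rule, "alpha": self.alpha}


@dataclass
class ShrinkageRecord:
    shrinkage_factor: float
    source: str
    original_coefficients: pd.Series
    shrunk_coefficients: pd.Series
    original_intercept: float
    reestimated_intercept: float


def apply_shrinkage(model: FittedModel, factor: float, data: Dataset,
                    source: str = "optimism-corrected calibration slope",
                    ) -> tuple[FittedModel, ShrinkageRecord]:
    """Uniform shrinkage: coefficients scaled by ``factor``, intercept
    re-estimated on the development data.

    The new intercept is the MLE of an intercept-only logistic model with
    the shrunk linear predictor as a fixed offset; the score equation of
    that fit forces mean predicted risk == observed event fraction.
    """
    if factor <= 0:
        raise ValueError(f"shrinkage factor must be positive, got {factor}")
    data.require_both_classes()
    shrunk = model.coefficients * factor
    offset = data.predictors[list(shrunk.index)].to_numpy(dtype=float) @ shrunk.to_numpy()
    glm = sm.GLM(data.outcome.astype(float), np.ones((data.n, 1)),
                 family=sm.families.Binomial(), offset=offset)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=_MAXITER, tol=1e-12)
    except Exception as exc:
        raise FittingError(f"intercept re-estimation failed: {exc}") from exc
    new_intercept = float(res.params[0])
    record = ShrinkageRecord(
        shrinkage_factor=factor, source=source,
        original_coefficients=model.coefficients.copy(),
        shrunk_coefficients=shrunk,
        original_intercept=model.intercept,
        reestimated_intercept=new_intercept,
    )
    return FittedModel(intercept=new_intercept, coefficients=shrunk), record
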
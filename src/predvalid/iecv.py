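"""Internal-external cross-validation (IECV) and subgroup audits.

When data are clustered — centres, geographical regions, constituent
studies — IECV develops the deliverable model on *all* the data, then
probes its generalisability by holding out each cluster once: the same
building recipe is re-run on the remaining clusters and evaluated in the
held-out one. Cluster-level performance estimates are pooled with a
random-effects meta-analysis (DerSimonian–Laird), whose between-cluster
variance tau^2 quantifies heterogeneity; results are laid out as a forest
table.

A related audit evaluates one fitted model within key subgroups (sex,
ethnic group, ...), flagging groups too small to support a stable estimate
instead of silently dropping them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .data import Dataset
from .errors import (DataError, FittingError, InsufficientDataError,
                     ValidationDesignError)
from .metrics import PerformanceResult, performance_report
from .model import FittedModel, ModelBuilder

_Z95 = float(norm.ppf(0.975))


@dataclass
class ClusterResult:
    label: str
    n: int
    n_events: int
    performance: PerformanceResult


@dataclass
class IECVResult:
    final_model: FittedModel
    cluster_results: list[ClusterResult]
    excluded_clusters: list[str]

    def pooled(self, measure: str = "c_statistic",
               scale: str = "natural") -> "MetaAnalysisResult":
        est = np.array([getattr(r.performance, measure).estimate
                        for r in self.cluster_results])
        se = np.array([getattr(r.performance, measure).se
                       for r in self.cluster_results])
        return pool_random_effects(est, se, scale=scale)


def iecv_run(builder: ModelBuilder, data: Dataset, seed: int = 0) -> IECVResult:
    """Leave-one-cluster-out evaluation plus the final all-data model.

    Clusters with no events (or no non-events) cannot be evaluated — the c
    statistic is undefined there — so they are excluded from the held-out
    rotation with a warning, but their individuals still contribute to
    every development set. At least three evaluable clusters are required.
    """
    if data.cluster_id is None:
        raise DataError("iecv_run requires a dataset with cluster labels")
    labels = pd.unique(data.cluster_id)
    usable, excluded = [], []
    for lab in labels:
        y = data.outcome[(data.cluster_id == lab).to_numpy()]
        if 0 < y.sum() < len(y):
            usable.append(lab)
        else:
            excluded.append(str(lab))
            warnings.warn(f"cluster '{lab}' has a single outcome class; "
                          "excluded from held-out evaluation (kept in "
                          "development sets)")
    if len(usable) < 3:
        raise ValidationDesignError(
            f"only {len(usable)} evaluable clusters (need >= 3)")
    final_model = builder.build(data, seed=seed, context="iecv:final")
    results = []
    for lab in usable:
        held = (data.cluster_id == lab).to_numpy()
        dev = data.subset(~held)
        test = data.subset(held)
        try:
            m = builder.build(dev, seed=seed, context=f"iecv:holdout={lab}")
        except FittingError as exc:
            raise FittingError(f"development fit failed with cluster '{lab}' "
                               f"held out: {exc}") from exc
        perf = performance_report(m, test, tag="iecv_cluster",
                                  context=f"iecv:holdout={lab}")
        results.append(ClusterResult(label=str(lab), n=test.n,
                                     n_events=test.n_events, performance=perf))
    return IECVResult(final_model=final_model, cluster_results=results,
                      excluded_clusters=excluded)


@dataclass
class MetaAnalysisResult:
    estimates: np.ndarray
    standard_errors: np.ndarray
    pooled: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    scale: str
    pooled_se: float


def pool_random_effects(estimates, standard_errors,
                        scale: str = "natural") -> MetaAnalysisResult:
    """DerSimonian–Laird random-effects pooling.

    Q is computed with fixed-effect (inverse-variance) weights;
    tau^2 = max(0, (Q − df) / C) with C = Σw − Σw²/Σw; random-effects
    weights are 1/(se² + tau²); the pooled CI is Wald. ``scale="logit"``
    pools logit-transformed estimates (delta-method SEs) and back-transforms
    the pooled value and CI — appropriate for c statistics near 1.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if len(est) < 2:
        raise ValidationDesignError("random-effects pooling needs >= 2 estimates")
    if len(est) != len(se):
        raise DataError("estimates and standard_errors lengths differ")
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise DataError("all standard errors must be finite and positive")
    if scale == "logit":
        theta = logit(est)
        se_t = se / (est * (1.0 - est))
    elif scale == "natural":
        theta, se_t = est, se
    else:
        raise ValueError(f"unknown scale '{scale}'")
    w = 1.0 / se_t ** 2
    theta_fe = np.sum(w * theta) / np.sum(w)
    Q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = len(est) - 1
    C = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    w_re = 1.0 / (se_t ** 2 + tau2)
    pooled_t = float(np.sum(w_re * theta) / np.sum(w_re))
    pooled_se_t = float(np.sqrt(1.0 / np.sum(w_re)))
    lo_t, hi_t = pooled_t - _Z95 * pooled_se_t, pooled_t + _Z95 * pooled_se_t
    if scale == "logit":
        pooled, lo, hi = float(expit(pooled_t)), float(expit(lo_t)), float(expit(hi_t))
    else:
        pooled, lo, hi = pooled_t, lo_t, hi_t
    return MetaAnalysisResult(estimates=est, standard_errors=se, pooled=pooled,
                              ci_low=lo, ci_high=hi, tau2=float(tau2), Q=Q,
                              scale=scale, pooled_se=pooled_se_t)


def forest_table(results: list[ClusterResult], pooled: MetaAnalysisResult,
                 measure: str = "c_statistic",
                 precision: int | None = None) -> pd.DataFrame:
    """Forest-plot data: one row per held-out cluster plus a pooled row."""
    if not results:
        raise DataError("forest_table needs at least one cluster result")
    rows = []
    for r in results:
        e = getattr(r.performance, measure)
        rows.append({"label": r.label, "n": r.n, "n_events": r.n_events,
                     "estimate": e.estimate, "ci_low": e.ci_low,
                     "ci_high": e.ci_high})
    rows.append({"label": "pooled (random effects)",
                 "n": sum(r.n for r in results),
                 "n_events": sum(r.n_events for r in results),
                 "estimate": pooled.pooled, "ci_low": pooled.ci_low,
                 "ci_high": pooled.ci_high})
    df = pd.DataFrame(rows)
    if precision is not None:
        for c in ("estimate", "ci_low", "ci_high"):
            df[c] = df[c].round(precision)
    return df


@dataclass
class SubgroupResult:
    label: str
    n: int
    n_events: int
    status: str                      # "ok" | "insufficient data"
    performance: PerformanceResult | None


def subgroup_performance(model: FittedModel, data: Dataset,
                         subgroup_column: str, min_n: int = 20,
                         min_events: int = 5) -> list[SubgroupResult]:
    """Per-subgroup performance of one fitted model.

    Groups below the size/event floor (default 20 individuals and 5 of each
    outcome class) are reported with status ``"insufficient data"`` rather
    than silently dropped: an audit that hides sparse groups invites the
    very blind spots it exists to reveal.
    """
    if data.subgroup_labels is not None and subgroup_column in data.subgroup_labels:
        col = data.subgroup_labels[subgroup_column]
    elif subgroup_column in data.predictors.columns:
        col = data.predictors[subgroup_column]
    elif data.cluster_id is not None and subgroup_column == "cluster":
        col = data.cluster_id
    else:
        raise DataError(f"subgroup column '{subgroup_column}' not found")
    out = []
    for lab in pd.unique(col):
        mask = (col == lab).to_numpy()
        sub = data.subset(mask)
        enough = (sub.n >= min_n and sub.n_events >= min_events
                  and sub.n - sub.n_events >= min_events)
        if not enough:
            out.append(SubgroupResult(str(lab), sub.n, sub.n_events,
                                      "insufficient data", None))
            continue
        try:
            perf = performance_report(model, sub, tag="subgroup",
                                      context=f"subgroup={lab}")
        except FittingError:
            out.append(SubgroupResult(str(lab), sub.n, sub.n_events,
                                      "insufficient data", None))
            continue
        out.append(SubgroupResult(str(lab), sub.n, sub.n_events, "ok", perf))
    return out
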
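"""Internal-validation strategies: apparent, split-sample, k-fold, bootstrap.

All strategies answer the same question — how will this model-building
procedure perform in new individuals from the same population? — with very
different bias/variance trade-offs at small n:

* *apparent*: evaluate on the development data itself (optimistic).
* *split-sample*: one random split, develop on one side, test on the other
  (unbiased but wasteful and unstable; never re-split).
* *k-fold*: partition into k groups, develop on k−1 and test on the held-out
  group, average over the k rotations.
* *enhanced bootstrap*: estimate the optimism of the apparent estimate by
  repeating the *entire* model-building recipe in bootstrap samples, and
  subtract it. The optimism-corrected calibration slope doubles as a
  uniform shrinkage factor.

Every strategy draws all randomness from one caller-supplied seed via
numpy ``SeedSequence`` spawning, so whole experiments replay bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import Dataset
from .errors import DegenerateOutcomeError, FittingError, ValidationDesignError
from .metrics import MetricEstimate, PerformanceResult, performance_report
from .model import ModelBuilder

_Z95 = float(norm.ppf(0.975))
MEASURES = list(PerformanceResult.MEASURES)

#: abort a resampling run if more than this fraction of replicates fail
FAILURE_CAP = 0.05


def _spawn_ints(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def apparent_validation(builder: ModelBuilder, data: Dataset,
                        seed: int = 0) -> PerformanceResult:
    """Build on all data, evaluate on the same data (tag ``apparent``)."""
    model = builder.build(data, seed=seed, context="apparent")
    return performance_report(model, data, tag="apparent")


def split_sample(builder: ModelBuilder, data: Dataset, dev_fraction: float = 0.7,
                 seed: int = 0, stratify: bool = False,
                 ) -> tuple[PerformanceResult, PerformanceResult]:
    """One random development/test split; returns (dev apparent, test) results.

    The split is made exactly once. If either side ends up with zero events
    (or zero non-events) the call fails rather than silently re-splitting:
    repeated looks until a satisfactory split appears is a form of result
    shopping.
    """
    if not 0 < dev_fraction < 1:
        raise ValidationDesignError(f"dev_fraction must be in (0,1), got {dev_fraction}")
    rng = np.random.default_rng(seed)
    n = data.n
    n_dev = int(round(dev_fraction * n))
    if stratify:
        dev_idx = []
        for cls in (1, 0):
            members = rng.permutation(np.flatnonzero(data.outcome == cls))
            take = int(round(dev_fraction * len(members)))
            dev_idx.append(members[:take])
        dev_idx = np.sort(np.concatenate(dev_idx))
    else:
        perm = rng.permutation(n)
        dev_idx = np.sort(perm[:n_dev])
    mask = np.zeros(n, dtype=bool)
    mask[dev_idx] = True
    dev, test = data.subset(mask), data.subset(~mask)
    for side, name in ((dev, "development"), (test, "test")):
        if side.n_events == 0 or side.n_events == side.n:
            raise ValidationDesignError(
                f"the {name} side of the split has a single outcome class; "
                "increase n or use a resampling strategy (the split is never "
                "silently redrawn)")
    model = builder.build(dev, seed=seed, context="split:dev")
    return (performance_report(model, dev, tag="split_dev"),
            performance_report(model, test, tag="split_test"))


@dataclass
class FoldAssignment:
    fold_index: np.ndarray  # 1..k per individual
    k: int
    repeat_index: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def make_folds(n: int, k: int, repeats: int = 1, seed: int = 0,
               stratify_on: np.ndarray | None = None) -> list[FoldAssignment]:
    """Random fold assignments: every individual in exactly one fold per
    repeat, fold sizes within 1 of each other.

    With ``stratify_on`` (a 0/1 outcome vector) each class is also spread
    across folds within ±1, so fold event fractions match the overall one
    up to rounding. Cyclic assignment over the class-ordered shuffle gives
    both guarantees at once.
    """
    if not 2 <= k <= n:
        raise ValidationDesignError(f"need 2 <= k <= n, got k={k}, n={n}")
    out = []
    for r, s in enumerate(_spawn_ints(seed, repeats), start=1):
        rng = np.random.default_rng(s)
        if stratify_on is None:
            order = rng.permutation(n)
        else:
            y = np.asarray(stratify_on)
            order = np.concatenate([rng.permutation(np.flatnonzero(y == 1)),
                                    rng.permutation(np.flatnonzero(y == 0))])
        fold = np.empty(n, dtype=int)
        fold[order] = np.arange(n) % k + 1
        out.append(FoldAssignment(fold_index=fold, k=k, repeat_index=r, seed=s))
    return out


def _average_results(results: list[PerformanceResult], tag: str,
                     average: str = "mean") -> PerformanceResult:
    agg = np.mean if average == "mean" else np.median
    ests = {}
    for m in MEASURES:
        vals = np.array([getattr(r, m).estimate for r in results])
        point = float(agg(vals))
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        ests[m] = MetricEstimate(point, se, point - _Z95 * se, point + _Z95 * se)
    return PerformanceResult(
        c_statistic=ests["c_statistic"],
        calibration_slope=ests["calibration_slope"],
        calibration_in_the_large=ests["calibration_in_the_large"],
        strategy_tag=tag,
        n_eval=int(sum(r.n_eval for r in results)),
        n_events_eval=int(sum(r.n_events_eval for r in results)),
    )


@dataclass
class KFoldResult:
    averaged: PerformanceResult
    per_fold: list[PerformanceResult]
    pooled: PerformanceResult | None
    k: int
    repeats: int
    skipped: int


def kfold_validation(builder: ModelBuilder, data: Dataset, k: int = 10,
                     repeats: int = 1, seed: int = 0, average: str = "mean",
                     stratify: bool = True, pooled: bool = False) -> KFoldResult:
    """(Repeated) k-fold cross-validation of the full building recipe.

    Per fold, the builder is re-run on the other k−1 groups and the model
    evaluated on the held-out group; per-fold results are averaged
    (``average`` = ``"mean"`` default, or ``"median"``). ``pooled=True``
    additionally computes one set of metrics on the held-out predictions
    pooled across folds — the two aggregations differ when folds are small.
    """
    data.require_both_classes()
    if k > min(data.n_events, data.n - data.n_events):
        raise ValidationDesignError(
            f"k={k} exceeds the minority class count "
            f"({min(data.n_events, data.n - data.n_events)}); held-out folds "
            "would lack both outcome classes and the c statistic would be "
            "undefined — reduce k or pool predictions across larger folds")
    assignments = make_folds(data.n, k, repeats, seed,
                             stratify_on=data.outcome if stratify else None)
    per_fold: list[PerformanceResult] = []
    skipped = 0
    pooled_lp = np.full(data.n, np.nan) if pooled else None
    for fa in assignments:
        for f in range(1, k + 1):
            train = data.subset(fa.train_indices(f))
            test = data.subset(fa.test_indices(f))
            ctx = f"kfold:repeat{fa.repeat_index}:fold{f}"
            try:
                model = builder.build(train, seed=fa.seed, context=ctx)
                per_fold.append(performance_report(model, test, tag="kfold_fold",
                                                   context=ctx))
            except FittingError as exc:
                skipped += 1
                warnings.warn(f"skipping fold: {exc}")
                continue
            if pooled and fa.repeat_index == 1:
                pooled_lp[fa.test_indices(f)] = model.linear_predictor(test)
    total = k * repeats
    if skipped > FAILURE_CAP * total:
        raise FittingError(f"{skipped}/{total} folds failed (> {FAILURE_CAP:.0%} cap)")
    averaged = _average_results(per_fold, tag="kfold", average=average)
    pooled_res = None
    if pooled:
        # held-out predictions come from different fold models, so evaluate
        # the pooled linear predictor directly rather than via one model
        from scipy.special import expit

        from .metrics import (c_statistic, calibration_in_the_large,
                              calibration_slope)
        ok = ~np.isnan(pooled_lp)
        lp = pooled_lp[ok]
        y = data.outcome[ok]
        pooled_res = PerformanceResult(
            c_statistic=c_statistic(expit(lp), y),
            calibration_slope=calibration_slope(lp, y),
            calibration_in_the_large=calibration_in_the_large(lp, y),
            strategy_tag="kfold_pooled", n_eval=int(ok.sum()),
            n_events_eval=int(y.sum()))
    return KFoldResult(averaged=averaged, per_fold=per_fold, pooled=pooled_res,
                       k=k, repeats=repeats, skipped=skipped)


@dataclass
class OptimismResult:
    """Output of the enhanced (optimism-correcting) bootstrap.

    ``corrected[m] = apparent[m] − mean_optimism[m]`` for each measure; the
    corrected calibration slope is exposed as ``shrinkage_factor``.
    """

    apparent: PerformanceResult
    mean_optimism: dict[str, float]
    corrected: dict[str, float]
    replicate_optimism: pd.DataFrame  # one row per completed replicate
    B_requested: int
    B_completed: int
    skipped_replicates: int

    @property
    def shrinkage_factor(self) -> float:
        return self.corrected["calibration_slope"]

    def corrected_result(self) -> PerformanceResult:
        """Corrected point estimates with bootstrap-spread SEs (the spread of
        the per-replicate corrected values demonstrates stability)."""
        ests = {}
        for m in MEASURES:
            point = self.corrected[m]
            spread = self.apparent.estimates()[m] - self.replicate_optimism[m]
            se = float(spread.std(ddof=1)) if len(spread) > 1 else np.nan
            ests[m] = MetricEstimate(point, se, point - _Z95 * se, point + _Z95 * se)
        return PerformanceResult(
            c_statistic=ests["c_statistic"],
            calibration_slope=ests["calibration_slope"],
            calibration_in_the_large=ests["calibration_in_the_large"],
            strategy_tag="bootstrap_corrected",
            n_eval=self.apparent.n_eval,
            n_events_eval=self.apparent.n_events_eval)


def bootstrap_optimism(builder: ModelBuilder, data: Dataset, B: int = 500,
                       seed: int = 0) -> OptimismResult:
    """Enhanced bootstrap internal validation.

    1. Build on the full data; compute apparent performance.
    2. Draw a bootstrap sample of size n with replacement.
    3. Re-run the *entire* building recipe on the bootstrap sample; evaluate
       it on the bootstrap sample (bootstrap performance) and on the
       original data (test performance).
    4. optimism = bootstrap performance − test performance, per measure.
    5-6. Repeat B times; average the optimism.
    7. corrected = apparent − mean optimism.

    Replicates whose fit fails (separation at small n) are skipped and
    counted; more than ``FAILURE_CAP`` of them aborts the run. The default
    B=500 follows the usual recommendation; optimism is already estimated
    precisely with a few hundred replicates.
    """
    if B < 1:
        raise ValidationDesignError("B must be >= 1")
    data.require_both_classes()
    seeds = _spawn_ints(seed, B + 1)
    model = builder.build(data, seed=seeds[0], context="bootstrap:apparent")
    apparent = performance_report(model, data, tag="apparent")
    app = apparent.estimates()
    rng = np.random.default_rng(seeds[0])
    rows = []
    skipped = 0
    for b in range(B):
        idx = rng.integers(0, data.n, data.n)
        boot = data.subset(idx)
        ctx = f"bootstrap:replicate{b + 1}"
        try:
            boot.require_both_classes()
            bmodel = builder.build(boot, seed=seeds[b + 1], context=ctx)
            perf_boot = performance_report(bmodel, boot, tag="bootstrap", context=ctx)
            perf_test = performance_report(bmodel, data, tag="test", context=ctx)
        except (FittingError, DegenerateOutcomeError):
            skipped += 1
            continue
        rows.append({m: perf_boot.estimates()[m] - perf_test.estimates()[m]
                     for m in MEASURES})
    if skipped > FAILURE_CAP * B:
        raise FittingError(
            f"{skipped}/{B} bootstrap replicates failed (> {FAILURE_CAP:.0%} cap)")
    rep = pd.DataFrame(rows, columns=MEASURES)
    mean_opt = {m: float(rep[m].mean()) for m in MEASURES}
    corrected = {m: app[m] - mean_opt[m] for m in MEASURES}
    return OptimismResult(apparent=apparent, mean_optimism=mean_opt,
                          corrected=corrected, replicate_optimism=rep,
                          B_requested=B, B_completed=len(rep),
                          skipped_replicates=skipped)
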
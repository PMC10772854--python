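"""Bias/variability experiments for validation strategies across sample sizes.

Re-creates, at configurable scale, the resampling experiment in which a
logistic mortality model with informative plus noise predictors is
developed on subsets of increasing size n and each internal-validation
strategy's estimate ĉ is compared with the model's large-sample
performance c_large. One tidy record is emitted per
(strategy, n, replicate, measure); the headline summaries are the mean and
2.5%/97.5% spread of ĉ − c_large per cell.

Two sources are supported, with different reference semantics, recorded in
every row:

* *generator mode* — fresh cohorts from the synthetic generator; the
  reference is the generator's exact truth (Monte-Carlo large-sample c;
  ideal slope 1 and CITL 0).
* *superpopulation mode* — subsets resampled with replacement from one
  large fixed dataset; the reference is the apparent performance of the
  model built on the whole superpopulation (itself an apparent value, as
  in the original construction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import FittingError, ValidationDesignError
from .model import ModelBuilder
from .simulate import GeneratorConfig, GroundTruth, generate, resolve_truth
from .validation import (MEASURES, _spawn_ints, apparent_validation,
                         bootstrap_optimism, kfold_validation, split_sample)

STRATEGIES = ("apparent", "split70", "split90", "kfold", "bootstrap")


@dataclass(frozen=True)
class ExperimentGrid:
    sample_sizes: tuple[int, ...] = (200, 500, 1000, 2000, 5000, 10_000)
    replicates: int = 500
    strategies: tuple[str, ...] = STRATEGIES
    seed: int = 0
    B: int = 100          # bootstrap replicates inside each experiment cell
    k: int = 10

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationDesignError("replicates must be >= 1")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValidationDesignError(f"unknown strategies {sorted(unknown)}")


@dataclass
class ExperimentResult:
    records: pd.DataFrame          # strategy, n, replicate, measure, value, reference, difference
    skipped: pd.DataFrame          # strategy, n, count of failed replicates
    grid: ExperimentGrid


def _strategy_estimates(strategy: str, builder: ModelBuilder, ds: Dataset,
                        seed: int, grid: ExperimentGrid) -> dict[str, float]:
    if strategy == "apparent":
        return apparent_validation(builder, ds, seed=seed).estimates()
    if strategy in ("split70", "split90"):
        frac = 0.7 if strategy == "split70" else 0.9
        _, test = split_sample(builder, ds, dev_fraction=frac, seed=seed)
        return test.estimates()
    if strategy == "kfold":
        return kfold_validation(builder, ds, k=grid.k, seed=seed).averaged.estimates()
    if strategy == "bootstrap":
        return bootstrap_optimism(builder, ds, B=grid.B, seed=seed).corrected
    raise ValidationDesignError(f"unknown strategy '{strategy}'")


def run_experiment(grid: ExperimentGrid,
                   generator_config: GeneratorConfig | None = None,
                   superpopulation: Dataset | None = None,
                   builder: ModelBuilder | None = None) -> ExperimentResult:
    """Run every strategy on every (n, replicate) cell; fully seeded.

    Exactly one of ``generator_config`` / ``superpopulation`` must be given.
    Strategy failures (separation at small n, degenerate splits) skip that
    (strategy, replicate) and are itemised in the ``skipped`` table.
    """
    if (generator_config is None) == (superpopulation is None):
        raise ValidationDesignError(
            "supply exactly one of generator_config or superpopulation")
    builder = builder or ModelBuilder()
    if superpopulation is not None:
        if superpopulation.n <= max(grid.sample_sizes):
            raise ValidationDesignError(
                "superpopulation must exceed the largest grid sample size")
        ref_model = builder.build(superpopulation, seed=grid.seed,
                                  context="experiment:superpopulation")
        from .metrics import performance_report
        ref_perf = performance_report(ref_model, superpopulation,
                                      tag="superpopulation_apparent")
        reference = ref_perf.estimates()
        truth = None
        ref_mode = "superpopulation_apparent"
    else:
        truth = resolve_truth(generator_config)
        reference = {"c_statistic": truth.true_c,
                     "calibration_slope": 1.0,
                     "calibration_in_the_large": 0.0}
        ref_mode = "generator_truth"

    cells = [(n, r) for n in grid.sample_sizes for r in range(1, grid.replicates + 1)]
    seeds = _spawn_ints(grid.seed, len(cells))
    records = []
    skip_counts: dict[tuple[str, int], int] = {}
    for (n, rep), cell_seed in zip(cells, seeds):
        draw_seed, *strat_seeds = _spawn_ints(cell_seed, 1 + len(grid.strategies))
        if superpopulation is not None:
            rng = np.random.default_rng(draw_seed)
            ds = superpopulation.subset(rng.integers(0, superpopulation.n, n))
        else:
            ds, _ = generate(replace(generator_config, n=n, seed=draw_seed),
                             truth=truth)
        for strategy, s_seed in zip(grid.strategies, strat_seeds):
            try:
                est = _strategy_estimates(strategy, builder, ds, s_seed, grid)
            except (FittingError, ValidationDesignError):
                skip_counts[(strategy, n)] = skip_counts.get((strategy, n), 0) + 1
                continue
            for m in MEASURES:
                records.append({
                    "strategy": strategy, "n": n, "replicate": rep,
                    "measure": m, "value": est[m], "reference": reference[m],
                    "difference": est[m] - reference[m],
                    "reference_mode": ref_mode,
                })
    rec = pd.DataFrame(records, columns=["strategy", "n", "replicate", "measure",
                                         "value", "reference", "difference",
                                         "reference_mode"])
    skipped = pd.DataFrame(
        [{"strategy": s, "n": n, "skipped": c}
         for (s, n), c in sorted(skip_counts.items())],
        columns=["strategy", "n", "skipped"])
    return ExperimentResult(records=rec, skipped=skipped, grid=grid)


def summarize_bias(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(strategy, n, measure): mean difference and 2.5/97.5% quantiles."""
    if records.empty:
        raise ValidationDesignError("no records to summarise")
    out = (records.groupby(["strategy", "n", "measure"], sort=True)["difference"]
           .agg(mean_difference="mean",
                q025=lambda x: x.quantile(0.025),
                q975=lambda x: x.quantile(0.975),
                replicates="count")
           .reset_index())
    return out
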
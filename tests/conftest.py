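import numpy as np
import pandas as pd
import pytest

import predvalid as pv


@pytest.fixture(scope="session")
def default_truth():
    """Calibrated truth for the default generator (memoised in-package)."""
    return pv.resolve_truth(pv.GeneratorConfig())


@pytest.fixture(scope="session")
def cohort_small(default_truth):
    """n=500 cohort under the default conditions (4 informative + 10 noise)."""
    ds, truth = pv.generate(pv.GeneratorConfig(n=500, seed=101),
                            truth=default_truth)
    return ds, truth


@pytest.fixture(scope="session")
def cohort_medium(default_truth):
    ds, truth = pv.generate(pv.GeneratorConfig(n=4000, seed=202),
                            truth=default_truth)
    return ds, truth


@pytest.fixture(scope="session")
def builder():
    return pv.ModelBuilder()


@pytest.fixture()
def tiny_dataset():
    """Hand-made 8-row dataset, both classes, two predictors."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame({"a": rng.normal(size=8), "b": rng.normal(size=8)})
    y = np.array([0, 1, 0, 1, 0, 0, 1, 0])
    return pv.Dataset(outcome=y, predictors=X)


def c_pair_count_oracle(risks, outcome):
    """Exhaustive O(events x non-events) concordance count, ties = 1/2."""
    risks = np.asarray(risks, float)
    outcome = np.asarray(outcome)
    pos = risks[outcome == 1]
    neg = risks[outcome == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
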
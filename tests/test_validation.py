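import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import predvalid as pv
from predvalid.errors import ValidationDesignError


class TestApparent:
    def test_large_n_apparent_near_truth(self, default_truth):
        ds, truth = pv.generate(pv.GeneratorConfig(n=40_000, seed=61),
                                truth=default_truth)
        rep = pv.apparent_validation(pv.ModelBuilder(), ds, seed=1)
        assert rep.strategy_tag == "apparent"
        assert rep.c_statistic.estimate == pytest.approx(truth.true_c, abs=0.01)

    def test_small_n_apparent_optimistic_on_average(self, default_truth):
        diffs = []
        for s in range(25):
            ds, truth = pv.generate(pv.GeneratorConfig(n=200, seed=700 + s),
                                    truth=default_truth)
            rep = pv.apparent_validation(pv.ModelBuilder(), ds, seed=s)
            diffs.append(rep.c_statistic.estimate - truth.true_c)
        assert np.mean(diffs) > 0.02


class TestSplitSample:
    def test_exact_split_counts(self, cohort_small, builder):
        ds, _ = cohort_small
        dev, test = pv.split_sample(builder, ds.subset(np.arange(200)),
                                    dev_fraction=0.7, seed=3)
        assert (dev.n_eval, test.n_eval) == (140, 60)
        assert dev.strategy_tag == "split_dev" and test.strategy_tag == "split_test"

    def test_ninety_ten_split(self, cohort_small, builder):
        ds, _ = cohort_small
        dev, test = pv.split_sample(builder, ds, dev_fraction=0.9, seed=3)
        assert dev.n_eval == round(0.9 * ds.n)
        assert test.n_eval == ds.n - dev.n_eval

    def test_reproducible_bit_for_bit(self, cohort_small, builder):
        ds, _ = cohort_small
        a = pv.split_sample(builder, ds, seed=9)
        b = pv.split_sample(builder, ds, seed=9)
        assert a[1].c_statistic == b[1].c_statistic

    def test_stratified_event_balance(self, cohort_medium, builder):
        ds, _ = cohort_medium
        dev, test = pv.split_sample(builder, ds, dev_fraction=0.7, seed=11,
                                    stratify=True)
        expected_dev_events = round(0.7 * ds.n_events)
        assert abs(dev.n_events_eval - expected_dev_events) <= 1

    def test_bad_fraction_errors(self, cohort_small, builder):
        ds, _ = cohort_small
        with pytest.raises(ValidationDesignError):
            pv.split_sample(builder, ds, dev_fraction=1.0)

    def test_eventless_side_errors_not_resplit(self, builder):
        # 40 individuals, 1 event: a 50:50 split leaves one side eventless
        rng = np.random.default_rng(0)
        ds = pv.Dataset(outcome=np.array([1] + [0] * 39),
                        predictors=pd.DataFrame({"x": rng.normal(size=40)}))
        with pytest.raises(ValidationDesignError, match="never"):
            pv.split_sample(builder, ds, dev_fraction=0.5, seed=1)


class TestMakeFolds:
    def test_five_equal_folds(self):
        fa = pv.make_folds(10, 5, seed=1)[0]
        sizes = np.bincount(fa.fold_index)[1:]
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_eleven_into_five(self):
        fa = pv.make_folds(11, 5, seed=1)[0]
        sizes = sorted(np.bincount(fa.fold_index)[1:], reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_stratified_exact_event_spread(self):
        y = np.array([1] * 20 + [0] * 80)
        fa = pv.make_folds(100, 5, seed=2, stratify_on=y)[0]
        for f in range(1, 6):
            assert y[fa.test_indices(f)].sum() == 4

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n=st.integers(10, 500), k=st.sampled_from([2, 5, 10]),
           repeats=st.integers(1, 3), seed=st.integers(0, 10_000),
           stratify=st.booleans())
    def test_partition_invariants(self, n, k, repeats, seed, stratify):
        y = (np.arange(n) % 3 == 0).astype(int) if stratify else None
        for fa in pv.make_folds(n, k, repeats=repeats, seed=seed, stratify_on=y):
            assert fa.fold_index.min() >= 1 and fa.fold_index.max() <= k
            sizes = np.bincount(fa.fold_index, minlength=k + 1)[1:]
            assert sizes.sum() == n            # every individual exactly once
            assert sizes.max() - sizes.min() <= 1
            if y is not None:
                ev = np.array([y[fa.test_indices(f)].sum() for f in range(1, k + 1)])
                assert ev.max() - ev.min() <= 1

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValidationDesignError):
            pv.make_folds(5, 6)


class TestKFold:
    def test_leave_one_out_rejected(self, cohort_small, builder):
        ds, _ = cohort_small
        with pytest.raises(ValidationDesignError, match="pool"):
            pv.kfold_validation(builder, ds, k=ds.n)

    def test_large_n_kfold_near_apparent(self, cohort_medium, builder):
        ds, _ = cohort_medium
        app = pv.apparent_validation(builder, ds, seed=1)
        kf = pv.kfold_validation(builder, ds, k=10, seed=2)
        assert len(kf.per_fold) == 10
        assert kf.averaged.c_statistic.estimate == pytest.approx(
            app.c_statistic.estimate, abs=0.03)

    def test_repeats_average_within_monte_carlo_error(self, cohort_medium, builder):
        ds, _ = cohort_medium
        r1 = pv.kfold_validation(builder, ds, k=5, seed=3)
        r2 = pv.kfold_validation(builder, ds, k=5, seed=4)
        # different fold assignments, close averages
        assert any((a.c_statistic.estimate != b.c_statistic.estimate)
                   for a, b in zip(r1.per_fold, r2.per_fold))
        assert r1.averaged.c_statistic.estimate == pytest.approx(
            r2.averaged.c_statistic.estimate, abs=0.03)

    def test_median_and_pooled_variants(self, cohort_medium, builder):
        ds, _ = cohort_medium
        res = pv.kfold_validation(builder, ds, k=5, seed=5, average="median",
                                  pooled=True)
        vals = sorted(r.c_statistic.estimate for r in res.per_fold)
        assert res.averaged.c_statistic.estimate == pytest.approx(
            np.median(vals), abs=1e-12)
        assert res.pooled.strategy_tag == "kfold_pooled"
        assert res.pooled.n_eval == ds.n


class TestBootstrapOptimism:
    def test_correction_identity_exact(self, cohort_small, builder):
        ds, _ = cohort_small
        res = pv.bootstrap_optimism(builder, ds, B=30, seed=7)
        for m in pv.PerformanceResult.MEASURES:
            assert res.corrected[m] == pytest.approx(
                res.apparent.estimates()[m] - res.mean_optimism[m], abs=1e-12)
        assert res.B_completed + res.skipped_replicates == res.B_requested
        assert len(res.replicate_optimism) == res.B_completed

    def test_data_ignoring_builder_has_no_optimism(self, cohort_small, default_truth):
        """A 'builder' returning fixed coefficients cannot overfit, so the
        optimism estimate should be ~0 and corrected ~ apparent."""
        ds, truth = cohort_small

        class FixedBuilder(pv.ModelBuilder):
            def build(self, data, seed=0, context=None):
                return pv.FittedModel(truth.intercept, truth.coefficients.copy())

        res = pv.bootstrap_optimism(FixedBuilder(), ds, B=150, seed=8)
        assert abs(res.mean_optimism["c_statistic"]) < 0.01
        assert res.corrected["c_statistic"] == pytest.approx(
            res.apparent.estimates()["c_statistic"], abs=0.01)

    def test_reproducible(self, cohort_small, builder):
        ds, _ = cohort_small
        a = pv.bootstrap_optimism(builder, ds, B=20, seed=13)
        b = pv.bootstrap_optimism(builder, ds, B=20, seed=13)
        pd.testing.assert_frame_equal(a.replicate_optimism, b.replicate_optimism)

    def test_shrinkage_factor_below_one_when_overfit(self, default_truth):
        ds, _ = pv.generate(pv.GeneratorConfig(n=200, seed=77),
                            truth=default_truth)
        res = pv.bootstrap_optimism(pv.ModelBuilder(), ds, B=100, seed=14)
        assert 0 < res.shrinkage_factor < 1

    def test_corrected_result_carries_stability_spread(self, cohort_small, builder):
        ds, _ = cohort_small
        res = pv.bootstrap_optimism(builder, ds, B=40, seed=15)
        cr = res.corrected_result()
        assert cr.strategy_tag == "bootstrap_corrected"
        assert np.isfinite(cr.c_statistic.se) and cr.c_statistic.se > 0
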
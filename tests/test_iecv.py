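import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import predvalid as pv
from predvalid.errors import DataError, ValidationDesignError


def dl_textbook_oracle(y, se):
    """Independent re-coding of DerSimonian–Laird pooling, step by step."""
    y = np.asarray(y, float)
    v = np.asarray(se, float) ** 2
    w_fixed = [1.0 / vi for vi in v]
    ybar_fixed = sum(wi * yi for wi, yi in zip(w_fixed, y)) / sum(w_fixed)
    Q = sum(wi * (yi - ybar_fixed) ** 2 for wi, yi in zip(w_fixed, y))
    C = sum(w_fixed) - sum(wi ** 2 for wi in w_fixed) / sum(w_fixed)
    tau2 = max(0.0, (Q - (len(y) - 1)) / C)
    w_re = [1.0 / (vi + tau2) for vi in v]
    pooled = sum(wi * yi for wi, yi in zip(w_re, y)) / sum(w_re)
    se_pooled = (1.0 / sum(w_re)) ** 0.5
    return pooled, tau2, Q, se_pooled


@pytest.fixture(scope="module")
def clustered():
    cfg = pv.GeneratorConfig(n_clusters=6, cluster_size_range=(400, 900),
                             cluster_intercept_sd=0.0, seed=900)
    return pv.generate_clustered(cfg)


class TestPooling:
    def test_identical_estimates_pool_to_themselves(self):
        res = pv.pool_random_effects([0.8, 0.8, 0.8], [0.02, 0.02, 0.02])
        assert res.pooled == pytest.approx(0.8, abs=1e-14)
        assert res.tau2 == 0.0

    def test_equal_ses_give_arithmetic_mean(self):
        est = [0.72, 0.78, 0.81]
        res = pv.pool_random_effects(est, [0.03] * 3)
        assert res.pooled == pytest.approx(np.mean(est), abs=1e-12)

    def test_hand_computed_three_study_case(self):
        est, se = [0.70, 0.76, 0.80], [0.02, 0.01, 0.03]
        expected_pooled, expected_tau2, expected_Q, expected_se = \
            dl_textbook_oracle(est, se)
        res = pv.pool_random_effects(est, se)
        assert res.pooled == pytest.approx(expected_pooled, abs=1e-12)
        assert res.tau2 == pytest.approx(expected_tau2, abs=1e-12)
        assert res.Q == pytest.approx(expected_Q, abs=1e-12)
        assert res.pooled_se == pytest.approx(expected_se, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_textbook_oracle_randomised(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 11)
        est = rng.uniform(0.55, 0.95, m)
        se = rng.uniform(0.005, 0.08, m)
        expected_pooled, expected_tau2, _, _ = dl_textbook_oracle(est, se)
        res = pv.pool_random_effects(est, se)
        assert res.pooled == pytest.approx(expected_pooled, abs=1e-10)
        assert res.tau2 == pytest.approx(expected_tau2, abs=1e-10)
        assert est.min() - 1e-12 <= res.pooled <= est.max() + 1e-12

    def test_logit_scale_back_transforms(self):
        est, se = [0.70, 0.76, 0.80], [0.02, 0.01, 0.03]
        res = pv.pool_random_effects(est, se, scale="logit")
        assert res.scale == "logit"
        assert 0.70 <= res.pooled <= 0.80
        assert 0 < res.ci_low < res.pooled < res.ci_high < 1

    def test_nonpositive_se_errors(self):
        with pytest.raises(DataError):
            pv.pool_random_effects([0.7, 0.8], [0.02, 0.0])


class TestIECVRun:
    def test_each_cluster_held_out_once(self, clustered, builder):
        ds, _ = clustered
        res = pv.iecv_run(builder, ds, seed=1)
        labels = [r.label for r in res.cluster_results]
        assert sorted(labels) == sorted(pd.unique(ds.cluster_id).astype(str))
        assert sum(r.n for r in res.cluster_results) == ds.n

    def test_final_model_equals_all_data_build(self, clustered, builder):
        ds, _ = clustered
        res = pv.iecv_run(builder, ds, seed=1)
        direct = builder.build(ds, seed=1)
        assert res.final_model.intercept == direct.intercept
        assert (res.final_model.coefficients == direct.coefficients).all()

    def test_homogeneous_clusters_pool_near_truth(self, clustered, builder):
        ds, truth = clustered
        pooled = pv.iecv_run(builder, ds, seed=1).pooled()
        assert pooled.pooled == pytest.approx(truth.true_c, abs=0.03)
        assert pooled.tau2 < 0.01

    def test_two_clusters_error(self, builder):
        cfg = pv.GeneratorConfig(n_clusters=2, cluster_size_range=(300, 400),
                                 seed=3)
        ds, _ = pv.generate_clustered(cfg)
        with pytest.raises(ValidationDesignError):
            pv.iecv_run(builder, ds, seed=1)

    def test_eventless_cluster_excluded_with_warning(self, builder):
        cfg = pv.GeneratorConfig(n_clusters=4, cluster_size_range=(300, 500),
                                 seed=4)
        ds, _ = pv.generate_clustered(cfg)
        y = ds.outcome.copy()
        y[(ds.cluster_id == "cluster_1").to_numpy()] = 0   # kill its events
        ds2 = pv.Dataset(outcome=y, predictors=ds.predictors,
                         cluster_id=ds.cluster_id)
        with pytest.warns(UserWarning, match="cluster_1"):
            res = pv.iecv_run(builder, ds2, seed=1)
        assert res.excluded_clusters == ["cluster_1"]
        assert len(res.cluster_results) == 3

    def test_heterogeneity_detected(self, builder, default_truth):
        cfg = pv.GeneratorConfig(n_clusters=8, cluster_size_range=(500, 900),
                                 cluster_intercept_sd=0.8, seed=5)
        ds, _ = pv.generate_clustered(cfg, truth=default_truth)
        res = pv.iecv_run(builder, ds, seed=1)
        citl = [r.performance.calibration_in_the_large.estimate
                for r in res.cluster_results]
        assert np.std(citl) > 0.3   # cluster intercept shifts show up in CITL


class TestForestTable:
    def test_nine_clusters_give_ten_rows(self, builder, default_truth):
        cfg = pv.GeneratorConfig(n_clusters=9, cluster_size_range=(300, 1500),
                                 seed=6)
        ds, _ = pv.generate_clustered(cfg, truth=default_truth)
        res = pv.iecv_run(builder, ds, seed=1)
        table = pv.forest_table(res.cluster_results, res.pooled())
        assert len(table) == 10
        assert table["label"].iloc[-1].startswith("pooled")

    def test_round_trips_at_stated_precision(self, clustered, builder, tmp_path):
        ds, _ = clustered
        res = pv.iecv_run(builder, ds, seed=1)
        table = pv.forest_table(res.cluster_results, res.pooled(), precision=2)
        path = tmp_path / "forest.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            pv.forest_table([], None)


@pytest.fixture(scope="module")
def model_and_data(default_truth):
    ds, _ = pv.generate(pv.GeneratorConfig(n=6000, seed=8),
                        truth=default_truth)
    model = pv.ModelBuilder().build(ds, seed=1)
    return model, ds


class TestSubgroups:
    def test_exchangeable_groups_agree(self, model_and_data):
        model, ds = model_and_data
        rng = np.random.default_rng(9)
        labels = pd.DataFrame({"site": rng.choice(["A", "B"], ds.n)})
        ds2 = pv.Dataset(ds.outcome, ds.predictors, subgroup_labels=labels)
        res = pv.subgroup_performance(model, ds2, "site")
        assert all(r.status == "ok" for r in res)
        cs = [r.performance.c_statistic.estimate for r in res]
        assert abs(cs[0] - cs[1]) < 0.05

    def test_shifted_baseline_gives_nonzero_citl(self, default_truth):
        ds, truth = pv.generate(pv.GeneratorConfig(n=8000, seed=10),
                                truth=default_truth)
        # group "shifted": baseline log-odds raised by +0.5 -> over-events
        flag = np.arange(ds.n) % 2 == 0
        lp = truth.linear_predictor(ds)
        rng = np.random.default_rng(11)
        y = ds.outcome.copy()
        y[flag] = (rng.random(flag.sum()) < expit(lp[flag] + 0.5)).astype(int)
        ds2 = pv.Dataset(y, ds.predictors,
                         subgroup_labels=pd.DataFrame(
                             {"grp": np.where(flag, "shifted", "plain")}))
        model = pv.ModelBuilder().build(ds2, seed=1)
        res = {r.label: r for r in pv.subgroup_performance(model, ds2, "grp")}
        citl_shift = res["shifted"].performance.calibration_in_the_large.estimate
        citl_plain = res["plain"].performance.calibration_in_the_large.estimate
        # the pooled model splits the difference: risks under-estimated in the
        # shifted group (positive CITL), over-estimated in the plain one
        assert citl_shift > 0.1 and citl_plain < -0.1

    def test_tiny_group_flagged_not_dropped(self, model_and_data):
        model, ds = model_and_data
        labels = np.array(["big"] * ds.n, dtype=object)
        labels[:3] = "tiny"
        ds2 = pv.Dataset(ds.outcome, ds.predictors,
                         subgroup_labels=pd.DataFrame({"g": labels}))
        res = {r.label: r for r in pv.subgroup_performance(model, ds2, "g")}
        assert res["tiny"].status == "insufficient data"
        assert res["tiny"].performance is None
        assert res["big"].status == "ok"

    def test_unknown_column_errors(self, model_and_data):
        model, ds = model_and_data
        with pytest.raises(DataError, match="nope"):
            pv.subgroup_performance(model, ds, "nope")
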
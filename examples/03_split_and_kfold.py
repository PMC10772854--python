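"""Split-sample and k-fold validation of the same building recipe.

A single 70:30 split wastes data in both directions: the model is built on
less data (more overfit) and judged on a small test set (noisy). k-fold
cross-validation reuses all the data for both roles.
"""

import predvalid as pv

cohort, truth = pv.generate(pv.GeneratorConfig(n=400, seed=3))
builder = pv.ModelBuilder()

dev, test = pv.split_sample(builder, cohort, dev_fraction=0.7, seed=21)
print(f"70:30 split -> development n={dev.n_eval}, test n={test.n_eval}")
print(f"  development (apparent) c: {dev.c_statistic.estimate:.3f}")
print(f"  test c:                   {test.c_statistic.estimate:.3f} "
      f"(95% CI {test.c_statistic.ci_low:.3f}-{test.c_statistic.ci_high:.3f})")

kf = pv.kfold_validation(builder, cohort, k=10, seed=22)
per_fold = [round(r.c_statistic.estimate, 3) for r in kf.per_fold]
print(f"10-fold c per fold: {per_fold}")
print(f"10-fold averaged c: {kf.averaged.c_statistic.estimate:.3f}")
print(f"true large-sample c: {truth.true_c:.3f}")
# Expect: development c above the truth (optimism), split-test c below it
# and unstable, the k-fold average in between and steadier.
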
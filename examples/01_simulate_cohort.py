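"""Generate a synthetic trauma-style cohort with known ground truth.

The generator calibrates a logistic data-generating model to two anchors —
event fraction 0.15 and large-sample c statistic 0.815 — and returns both
the cohort and the truth used to create it.
"""

import predvalid as pv

config = pv.GeneratorConfig(n=5000, seed=1)
cohort, truth = pv.generate(config)

print(f"cohort: n={cohort.n}, events={cohort.n_events} "
      f"({cohort.n_events / cohort.n:.3f} of individuals)")
print(f"true large-sample c: {truth.true_c:.3f} (target 0.815)")
print(f"true intercept:      {truth.intercept:.3f}")
print("true coefficients (noise columns are exactly zero):")
print(truth.coefficients.round(3).to_string())
# The event fraction is the anchor for baseline risk; the c statistic is the
# anchor for how separable events and non-events are under the true model.
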
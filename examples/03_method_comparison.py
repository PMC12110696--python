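"""Method-comparison statistics: binary concordance and Deming regression.

Recomputes the binary classification metrics from a validation confusion
table, runs the noninferiority check on accuracy, and fits Deming lines on
a simulated quantitative comparison split by specimen type.
"""

import numpy as np

from flowmrd import validation_stats as vs

# binary concordance from a 240-sample validation: 129 true positives,
# 6 false positives, 105 true negatives, no false negatives
counts = vs.ConfusionCounts(tp=129, fp=6, fn=0, tn=105)
metrics = vs.binary_concordance(counts)
for name, m in metrics.items():
    print(f"{name:<12} {m.percent:6.1f}%  "
          f"({m.numerator}/{m.denominator}; "
          f"95% CI {100 * m.ci_low:.1f}-{100 * m.ci_high:.1f}%)")

ni = vs.noninferiority_accuracy_test(observed_correct=234, n=240, p0=0.975)
print(f"noninferiority vs 97.5%: pass={ni['pass']} "
      f"(exact p = {ni['p_value']:.3f})")

# quantitative comparison: reference vs test MRD % with measurement noise
# of similar size on both axes (the structure Deming regression assumes)
rng = np.random.default_rng(0)
def cohort(n):
    truth = rng.uniform(0.0, 5.0, n)          # MRD % spanning the range
    x = truth + rng.normal(0, 0.1, n)
    y = truth + rng.normal(0, 0.1, n)
    return x, y

bm = vs.deming_fit(*cohort(51))
pb = vs.deming_fit(*cohort(189))
for name, fit in (("BM", bm), ("PB", pb)):
    print(f"{name}: slope {fit.slope:.3f} (SE {fit.se_slope:.3f}), "
          f"intercept {fit.intercept:.4f}, r {fit.r:.3f}, n {fit.n}")
cmp = vs.compare_deming(bm, pb)
print(f"BM vs PB: p_slope {cmp['p_slope']:.2f}, "
      f"p_intercept {cmp['p_intercept']:.2f}")
# Non-significant p-values mean the two specimen types share one
# calibration line, so one method-comparison claim covers both.

ss = vs.sample_size_quantitative(r_expected=0.95, slope_tol=0.05)
print(f"planned n for the quantitative comparison: {ss['n']} "
      f"({ss['formula']})")
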
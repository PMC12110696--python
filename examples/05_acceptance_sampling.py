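"""Derive and use the negative-case acceptance-sampling plan.

A lab reporting ~74 MRD-negative cases per month accumulates a lot of ~444
per 6-month cycle. The plan finds how many to re-review so that, with 95%
confidence, at least 95% of reported negatives are truly negative when the
lot passes with at most 1 failure.
"""

from flowmrd import acceptance_sampling as asamp

plan = asamp.min_sample_size(N=444, c=1, confidence=0.95, quality=0.95,
                             periods=6)
print(f"lot N={plan.N}, acceptance number c={plan.c}")
print(f"limiting defectives d*={plan.d_star} "
      f"(lot quality drops below {plan.quality:.0%})")
print(f"exact minimal sample size: {plan.n_minimal}")
print(f"operational sample size (even 6-month split): {plan.n} "
      f"-> {asamp.allocate_periodic(plan.n, 6)} per month")

print("\nOC curve (defectives -> P(accept)):")
for D, p in zip(range(0, 45, 5), asamp.oc_curve(plan, range(0, 45, 5))):
    print(f"  D={D:>2}: {p:.4f}")
print(f"  at d*={plan.d_star}: "
      f"{plan.acceptance_probability(plan.d_star):.4f} (<= 0.05)")

for failures in (0, 1, 2):
    res = asamp.evaluate_lot(plan, failures)
    verdict = "ACCEPT" if res.accept else "REJECT -> investigate"
    print(f"{failures} failure(s) in {res.reviewed}: "
          f"{res.confirmed_fraction}% confirmed -> {verdict}")
# One failure in 84 reviewed cases (98.8% confirmed) still accepts the lot;
# two failures trigger a comprehensive investigation.
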
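"""Item analysis: Cronbach's alpha, item-rest correlations, alpha-if-deleted.

The oculomotor/visual item ("Eyes") is generated independently of the
severity trait, so the analysis should flag it as the one item with
poor discriminatory power (< 0.3) whose removal *raises* alpha --
the same anomaly the instrument's development study reported.
"""

from aspos import default_params, generate_cohort, item_analysis

cohort = generate_cohort(default_params(seed=1))
result = item_analysis(cohort.item_matrix("day1_r1"))

print(f"Cronbach's alpha: {result.alpha:.3f} "
      f"(Nunnally threshold 0.7 met: {result.meets_nunnally})")
print(f"\n{'item':<12s} {'item-rest r':>12s} {'alpha if deleted':>18s}")
for item in result.item_rest.index:
    flag = "  <- low discrimination" if item in result.low_discrimination else ""
    print(f"{item:<12s} {result.item_rest[item]:>12.2f} "
          f"{result.alpha_deleted[item]:>18.2f}{flag}")

print("\nAn item-rest correlation below 0.3 means the item does not track")
print("the attribute the other six items measure; deleting such an item")
print("increases the scale's internal consistency.")
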
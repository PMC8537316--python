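"""Model the swap's effect on nutrient adequacy in a cohort.

Generates a synthetic cohort of 171 pregnant women (right-skewed intakes
matching the study population's means/SDs, 65.5% eating beef weekly),
applies the weekly beef -> firm tofu swap to the eligible members, and
compares Nutrient Reference Value (NRV) compliance before and after.
"""
from sustainaswap import (
    SwapScenario,
    SyntheticCohortConfig,
    apply_swap_to_cohort,
    bundled_food_table,
    bundled_nrvs,
    evaluate_swap,
    generate_cohort,
    summarize_cohort,
)

table = bundled_food_table()
nrvs = bundled_nrvs()
cohort = generate_cohort(SyntheticCohortConfig(n=171, seed=42))
result = evaluate_swap(table, SwapScenario("Beef", "Tofu, firm"))
after = apply_swap_to_cohort(cohort, result, mode="per_individual")

before_df = summarize_cohort(cohort, nrvs).set_index("nutrient")
after_df = summarize_cohort(after, nrvs).set_index("nutrient")
print("NRV compliance, original -> modeled (n = 171):")
for nutrient in before_df.index:
    b, a = before_df.loc[nutrient], after_df.loc[nutrient]
    print(f"  {nutrient:14s} mean {b['mean']:7.1f} -> {a['mean']:7.1f}   "
          f"met NRV {b['met_n']:3.0f} ({b['met_pct']:.0f}%) -> "
          f"{a['met_n']:3.0f} ({a['met_pct']:.0f}%)")
# Calcium and folate means rise, zinc falls by ~0.33 mg/day on average
# (0.5 mg/day among the 65.5% of weekly beef eaters who swap).
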
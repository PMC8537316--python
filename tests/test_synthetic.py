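"""Synthetic cohort generator: determinism, moment matching, recovery."""
import numpy as np
import pytest

from sustainaswap import (
    DEFAULT_INTAKE_TARGETS,
    ShiftMode,
    SwapScenario,
    SyntheticCohortConfig,
    ValidationError,
    apply_swap_to_cohort,
    evaluate_swap,
    generate_cohort,
    lognormal_params,
    nrv_compliance,
    recover_parameters,
)


class TestConfigValidation:
    def test_defaults_describe_the_study_population(self):
        cfg = SyntheticCohortConfig()
        assert cfg.n == 171
        assert cfg.eligible_fraction == 0.655
        assert cfg.targets["iron"] == (14.2, 6.9)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticCohortConfig(targets={"iron": (14.2, 0.0)})

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValidationError, match="semi-definite"):
            SyntheticCohortConfig(
                targets={"iron": (14.2, 6.9), "zinc": (12.6, 5.0),
                         "calcium": (984.1, 332.9)},
                correlation=bad)

    def test_unknown_nutrient_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticCohortConfig(targets={"caffeine": (100, 10)})


class TestLognormalMomentMatching:
    def test_parameters_reproduce_target_moments_in_closed_form(self):
        mean, sd = 14.2, 6.9
        mu, sigma = lognormal_params(mean, sd)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-12)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(sd, rel=1e-12)


class TestGeneration:
    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(SyntheticCohortConfig(n=50, seed=7))
        b = generate_cohort(SyntheticCohortConfig(n=50, seed=7))
        assert all(x.daily_intake == y.daily_intake and
                   x.reference_serves_per_week == y.reference_serves_per_week
                   for x, y in zip(a, b))

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticCohortConfig(n=50, seed=7))
        b = generate_cohort(SyntheticCohortConfig(n=50, seed=8))
        assert any(x.daily_intake != y.daily_intake for x, y in zip(a, b))

    def test_all_intakes_strictly_positive(self):
        cohort = generate_cohort(SyntheticCohortConfig(n=2000, seed=3))
        for rec in cohort:
            for nutrient in DEFAULT_INTAKE_TARGETS:
                assert getattr(rec.daily_intake, nutrient) > 0

    def test_tiny_sd_degenerates_to_the_mean(self):
        cfg = SyntheticCohortConfig(n=100, targets={"iron": (14.2, 1e-6)},
                                    seed=0)
        cohort = generate_cohort(cfg)
        assert all(abs(r.daily_intake.iron - 14.2) < 1e-4 for r in cohort)

    def test_study_scale_iron_mean_within_3_se(self):
        cohort = generate_cohort(SyntheticCohortConfig(seed=11))
        mean = np.mean([r.daily_intake.iron for r in cohort])
        se = 6.9 / np.sqrt(171)
        assert abs(mean - 14.2) < 3 * se


class TestParameterRecovery:
    def test_large_sample_recovers_means_and_sds(self):
        cfg = SyntheticCohortConfig(n=100_000, seed=5)
        rec = recover_parameters(generate_cohort(cfg))
        for nutrient, (mean, sd) in cfg.targets.items():
            got_mean, got_sd = rec["moments"][nutrient]
            assert abs(got_mean - mean) / mean < 0.01
            assert abs(got_sd - sd) / sd < 0.03

    def test_large_sample_eligible_fraction_within_1pct(self):
        cfg = SyntheticCohortConfig(n=100_000, seed=5)
        rec = recover_parameters(generate_cohort(cfg))
        assert abs(rec["eligible_fraction"] - 0.655) < 0.01

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            recover_parameters([])


class TestEndToEnd:
    def test_swap_shifts_mean_zinc_by_fraction_times_delta(self, table):
        cfg = SyntheticCohortConfig(n=10_000, seed=13)
        cohort = generate_cohort(cfg)
        result = evaluate_swap(table, SwapScenario("Beef", "Tofu, firm"))
        after = apply_swap_to_cohort(cohort, result,
                                     mode=ShiftMode.PER_INDIVIDUAL)
        shift = (np.mean([r.daily_intake.zinc for r in after])
                 - np.mean([r.daily_intake.zinc for r in cohort]))
        expected = cfg.eligible_fraction * result.nutrient_delta.zinc / 7
        # only the eligible-fraction estimate is stochastic here
        se = abs(result.nutrient_delta.zinc / 7) * np.sqrt(
            0.655 * 0.345 / cfg.n)
        assert abs(shift - expected) < 3 * se

    def test_swap_never_decreases_calcium_compliance(self, table, nrvs):
        cohort = generate_cohort(SyntheticCohortConfig(n=2000, seed=21))
        result = evaluate_swap(table, SwapScenario("Beef", "Tofu, firm"))
        after = apply_swap_to_cohort(cohort, result)
        ca = [n for n in nrvs if n.nutrient == "calcium"]
        assert (nrv_compliance(after, ca)["calcium"][0]
                >= nrv_compliance(cohort, ca)["calcium"][0])
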
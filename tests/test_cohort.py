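"""Cohort modelling: swap application, NRV compliance, summaries."""
import numpy as np
import pytest

from sustainaswap import (
    ConfigurationError,
    NRVEntry,
    PregnancyScaling,
    ShiftMode,
    SwapScenario,
    ValidationError,
    apply_swap_to_cohort,
    evaluate_swap,
    load_cohort,
    nrv_compliance,
    summarize_cohort,
    write_cohort,
)
from sustainaswap._rounding import round_half_up

from conftest import make_record


@pytest.fixture(scope="module")
def swap_result(table):
    return evaluate_swap(table, SwapScenario("Beef", "Tofu, firm"))


class TestApplySwap:
    def test_uniform_mode_shifts_every_mean_by_delta_over_7(
            self, toy_cohort, swap_result):
        after = apply_swap_to_cohort(toy_cohort, swap_result,
                                     mode=ShiftMode.UNIFORM)
        dz = swap_result.nutrient_delta.zinc / 7
        for before, shifted in zip(toy_cohort, after):
            assert shifted.daily_intake.zinc == pytest.approx(
                before.daily_intake.zinc + dz)

    def test_uniform_shift_reproduces_published_modeled_means(
            self, swap_result, nrvs):
        # two symmetric records around each published original mean
        means = {"protein": 97.8, "dietary_fiber": 23.3, "iron": 14.2,
                 "zinc": 12.6, "calcium": 984.1, "folate_dfe": 280.2}
        lo = make_record("lo", **{k: v - 1 for k, v in means.items()})
        hi = make_record("hi", **{k: v + 1 for k, v in means.items()})
        after = apply_swap_to_cohort([lo, hi], swap_result, mode="uniform")
        summary = summarize_cohort(after, nrvs).set_index("nutrient")
        expected = {"protein": 96.5, "zinc": 12.1, "calcium": 1026.2,
                    "folate_dfe": 284.2, "iron": 14.3}
        for nutrient, value in expected.items():
            assert round_half_up(summary.loc[nutrient, "mean"], 1) == value

    def test_per_individual_touches_only_weekly_beef_eaters(
            self, toy_cohort, swap_result):
        after = apply_swap_to_cohort(toy_cohort, swap_result)
        for before, shifted in zip(toy_cohort, after):
            if before.reference_serves_per_week >= 1:
                assert shifted.daily_intake.zinc != before.daily_intake.zinc
            else:
                assert shifted.daily_intake == before.daily_intake

    def test_per_individual_mean_shift_is_fraction_times_delta(
            self, toy_cohort, swap_result):
        after = apply_swap_to_cohort(toy_cohort, swap_result)
        frac = np.mean([r.reference_serves_per_week >= 1 for r in toy_cohort])
        shift = (np.mean([r.daily_intake.zinc for r in after])
                 - np.mean([r.daily_intake.zinc for r in toy_cohort]))
        assert shift == pytest.approx(frac * swap_result.nutrient_delta.zinc / 7)

    def test_modes_agree_when_everyone_is_eligible(self, toy_cohort, swap_result):
        uni = apply_swap_to_cohort(toy_cohort, swap_result, mode="uniform")
        per = apply_swap_to_cohort(toy_cohort, swap_result,
                                   eligibility=lambda r: True)
        for a, b in zip(uni, per):
            assert a.daily_intake == b.daily_intake

    def test_zero_delta_leaves_cohort_unchanged(self, toy_cohort, swap_result):
        import dataclasses

        from sustainaswap import NutrientVector

        null = dataclasses.replace(swap_result, nutrient_delta=NutrientVector())
        after = apply_swap_to_cohort(toy_cohort, null, mode="uniform")
        for a, b in zip(after, toy_cohort):
            assert a.daily_intake == b.daily_intake

    def test_daily_frequency_is_a_configuration_error(self, table, toy_cohort):
        daily = evaluate_swap(table, SwapScenario(
            "Beef", "Tofu, firm", scaling=PregnancyScaling(270, "daily")))
        with pytest.raises(ConfigurationError, match="weekly"):
            apply_swap_to_cohort(toy_cohort, daily)

    def test_intakes_never_go_negative(self, swap_result):
        poor = [make_record("p", zinc=0.01, protein=1.0)]
        after = apply_swap_to_cohort(poor, swap_result, mode="uniform")
        assert after[0].daily_intake.zinc == 0.0


class TestNRVCompliance:
    def test_toy_iron_count_matches_hand_count(self):
        cohort = [make_record(f"p{i}", iron=fe) for i, fe in
                  enumerate([10, 22, 23, 5])]
        out = nrv_compliance(cohort, [NRVEntry("iron", 22)])
        assert out["iron"] == (2, 50.0)

    def test_all_below_threshold_gives_zero(self):
        cohort = [make_record(f"p{i}", iron=5.0) for i in range(4)]
        assert nrv_compliance(cohort, [NRVEntry("iron", 22)])["iron"] == (0, 0.0)

    def test_zero_threshold_disallowed(self):
        with pytest.raises(ValidationError):
            NRVEntry("iron", 0.0)

    def test_ai_scored_same_as_ear(self):
        cohort = [make_record("a", dietary_fiber=30), make_record("b", dietary_fiber=20)]
        ai = nrv_compliance(cohort, [NRVEntry("dietary_fiber", 28, "AI")])
        ear = nrv_compliance(cohort, [NRVEntry("dietary_fiber", 28, "EAR")])
        assert ai == ear

    def test_count_monotone_nonincreasing_in_threshold(self, toy_cohort):
        counts = [nrv_compliance(toy_cohort, [NRVEntry("iron", t)])["iron"][0]
                  for t in (5, 10, 15, 22, 30)]
        assert counts == sorted(counts, reverse=True)

    def test_positive_uniform_shift_never_lowers_compliance(
            self, toy_cohort, swap_result, nrvs):
        before = nrv_compliance(toy_cohort, nrvs)
        after_cohort = apply_swap_to_cohort(toy_cohort, swap_result,
                                            mode="uniform")
        after = nrv_compliance(after_cohort, nrvs)
        for nutrient in ("calcium", "dietary_fiber", "iron", "folate_dfe"):
            # these deltas are positive for the beef -> firm tofu swap
            assert after[nutrient][0] >= before[nutrient][0]


class TestSummaries:
    def test_uniform_shift_preserves_sd_and_iqr_width(
            self, toy_cohort, swap_result, nrvs):
        before = summarize_cohort(toy_cohort, nrvs).set_index("nutrient")
        after = summarize_cohort(
            apply_swap_to_cohort(toy_cohort, swap_result, mode="uniform"),
            nrvs).set_index("nutrient")
        for nutrient in before.index:
            d = swap_result.nutrient_delta.as_dict()[nutrient] / 7
            assert after.loc[nutrient, "sd"] == pytest.approx(
                before.loc[nutrient, "sd"], rel=1e-9)
            assert (after.loc[nutrient, "q75"] - after.loc[nutrient, "q25"]
                    ) == pytest.approx(
                before.loc[nutrient, "q75"] - before.loc[nutrient, "q25"],
                abs=1e-9)
            for col in ("mean", "median", "q25", "q75"):
                assert after.loc[nutrient, col] == pytest.approx(
                    before.loc[nutrient, col] + d, abs=1e-9)

    def test_empty_cohort_rejected(self, nrvs):
        with pytest.raises(ValidationError):
            summarize_cohort([], nrvs)

    def test_single_record_reports_sd_zero_with_warning(self, nrvs):
        with pytest.warns(UserWarning, match="SD"):
            summary = summarize_cohort([make_record("only", iron=10, protein=80,
                                                    zinc=10, calcium=900,
                                                    dietary_fiber=20,
                                                    folate_dfe=250)], nrvs)
        assert (summary["sd"] == 0).all()

    def test_identical_records_have_zero_spread(self, nrvs):
        cohort = [make_record(f"p{i}", iron=10, protein=80, zinc=10,
                              calcium=900, dietary_fiber=20, folate_dfe=250)
                  for i in range(5)]
        summary = summarize_cohort(cohort, nrvs)
        assert (summary["sd"] == 0).all()
        assert (summary["q75"] == summary["q25"]).all()


class TestCohortIO:
    def test_round_trip(self, toy_cohort, tmp_path):
        p = tmp_path / "cohort.csv"
        write_cohort(toy_cohort, p)
        again = load_cohort(p)
        assert len(again) == len(toy_cohort)
        for a, b in zip(again, toy_cohort):
            assert a.daily_intake.iron == pytest.approx(b.daily_intake.iron)
            assert a.reference_serves_per_week == b.reference_serves_per_week
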
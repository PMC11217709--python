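"""Analysis table assembly, multilevel battery, multiplicity, and classical tests."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from wearlab.analysis import (
    PREDICTORS,
    assemble_table,
    descriptive_table,
    fisher_exact_2x2,
    fit_daily_model,
    holm_bonferroni,
    paired_t_prepost,
    person_mean_correlations,
    pre_post_tests,
    run_model_battery,
    wilcoxon_prepost,
)

from _oracles import fisher_p_oracle, signed_rank_p_oracle


@pytest.fixture(scope="module")
def tiny_rows(tiny_cohort):
    co = tiny_cohort
    return assemble_table(
        co.sleep_nights, co.hrv_daily, co.activity_daily, co.surveys, co.profiles,
        skip_week1=False,
    )


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


class TestAssemble:
    def test_day_links_to_night_ending_that_morning(self, tiny_cohort):
        co = tiny_cohort
        rows = assemble_table(
            co.sleep_nights, co.hrv_daily, co.activity_daily, co.surveys,
            co.profiles, skip_week1=False,
        )
        nights = co.sleep_nights.set_index(["participant_id", "night_date"])
        checked = 0
        for _, r in rows.dropna(subset=["sfi"]).iterrows():
            night = nights.loc[(r["participant_id"], r["date"] - timedelta(days=1))]
            assert r["sfi"] == pytest.approx(night["sfi"])
            checked += 1
        assert checked > 5

    def test_last_day_has_missing_next_day_outcome(self, tiny_rows):
        last = tiny_rows.sort_values("date").groupby("participant_id").tail(1)
        assert last["symptom_next_day"].isna().all()

    def test_next_day_outcome_is_shifted_symptom(self, tiny_rows):
        for pid, sub in tiny_rows.groupby("participant_id"):
            sub = sub.sort_values("date")
            expected = sub["symptom_binary"].shift(-1)
            pd.testing.assert_series_equal(
                sub["symptom_next_day"], expected, check_names=False
            )

    def test_skip_week1_drops_exactly_first_seven_days(self, tiny_cohort):
        co = tiny_cohort
        kept = assemble_table(
            co.sleep_nights, co.hrv_daily, co.activity_daily, co.surveys,
            co.profiles, skip_week1=True,
        )
        first_survey = co.surveys.groupby("participant_id")["date"].min()
        for pid, sub in kept.groupby("participant_id"):
            assert sub["date"].min() == first_survey[pid] + timedelta(days=7)

    def test_duplicate_keys_rejected(self, tiny_cohort):
        co = tiny_cohort
        dup = pd.concat([co.surveys, co.surveys.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_table(
                co.sleep_nights, co.hrv_daily, co.activity_daily, dup, co.profiles
            )

    def test_within_person_centering_sums_to_zero(self, tiny_rows):
        """Centered predictors average to ~0 within every participant over
        their non-missing days."""
        for col in PREDICTORS:
            means = tiny_rows.groupby("participant_id")[f"{col}_c"].mean().dropna()
            assert (means.abs() < 1e-9).all(), col

    def test_covariates_grand_mean_centered(self, tiny_rows):
        per_person = tiny_rows.groupby("participant_id")[
            ["age_gmc", "sex_w_gmc", "n_chronic_gmc", "baseline_gds_gmc"]
        ].first()
        assert np.allclose(per_person.mean(), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class TestModels:
    def test_degenerate_predictor_rejected(self, tiny_rows):
        rows = tiny_rows.copy()
        rows["tst"] = 400.0
        rows["tst_c"] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_daily_model(rows, "tst", "same_day")

    def test_too_few_participants_rejected(self, tiny_rows):
        rows = tiny_rows[tiny_rows["participant_id"] == "P01"]
        with pytest.raises(ValueError, match="participants"):
            fit_daily_model(rows, "sfi", "same_day")

    def test_unknown_predictor_and_outcome_rejected(self, tiny_rows):
        with pytest.raises(ValueError):
            fit_daily_model(tiny_rows, "bp", "same_day")
        with pytest.raises(ValueError):
            fit_daily_model(tiny_rows, "sfi", "weekly")

    def test_battery_is_11_predictors_by_2_outcomes(self, tiny_rows):
        res = run_model_battery(tiny_rows, n_quad=5)
        assert len(res) == 22
        assert set(res["outcome"]) == {"same_day", "next_day"}
        assert list(res["predictor"].unique()) == list(PREDICTORS)
        conv = res[res["converged"]]
        assert (conv["ci_low"] <= conv["odds_ratio"]).all()
        assert (conv["odds_ratio"] <= conv["ci_high"]).all()
        assert (conv["odds_ratio"] > 0).all()

    def test_fixed_threshold_flag(self, tiny_rows):
        res = run_model_battery(tiny_rows, n_quad=5)
        ok = res["p_value"].notna()
        assert (
            res.loc[ok, "significant_fixed"] == (res.loc[ok, "p_value"] < 0.005)
        ).all()

    def test_recovers_known_coefficient(self):
        """The same-day sleep-fragmentation model recovers the generator's
        within-person odds ratio within its own confidence interval."""
        from wearlab.config import SimulationConfig
        from wearlab.simulate import apply_missingness, generate_cohort

        cfg = SimulationConfig(seed=12, beta_se=0.0)
        co = apply_missingness(generate_cohort(cfg))
        rows = assemble_table(
            co.sleep_nights, co.hrv_daily, co.activity_daily, co.surveys, co.profiles
        )
        m = fit_daily_model(rows, "sfi", "same_day")
        assert m.converged
        assert m.ci_low < 2.066 < m.ci_high

    def test_lagged_effect_attenuates_when_coupling_is_previous_night(self):
        """With symptoms driven by the night ending that morning, the
        same-day model shows the effect and the next-day model sits nearer
        the null."""
        from wearlab.config import SimulationConfig
        from wearlab.simulate import generate_cohort

        est_same, est_next = [], []
        for seed in (31, 32, 33):
            cfg = SimulationConfig(
                n_participants=30, n_days=40, seed=seed, beta_se=0.0,
                missing_rates={"survey": 0, "hrv": 0, "sleep": 0, "steps": 0},
            )
            co = generate_cohort(cfg)
            rows = assemble_table(
                co.sleep_nights, co.hrv_daily, co.activity_daily, co.surveys,
                co.profiles,
            )
            est_same.append(np.log(fit_daily_model(rows, "sfi", "same_day").odds_ratio))
            est_next.append(np.log(fit_daily_model(rows, "sfi", "next_day").odds_ratio))
        assert np.mean(est_same) > 0.4
        assert abs(np.mean(est_next)) < np.mean(est_same) / 2


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------


class TestHolm:
    def test_hand_stepped_example_with_larger_family(self):
        # smallest p tested at alpha/11, next at alpha/10
        flags = holm_bonferroni([0.001, 0.003], alpha=0.05, m=11)
        assert flags.tolist() == [True, True]
        flags = holm_bonferroni([0.001, 0.006], alpha=0.05, m=11)
        assert flags.tolist() == [True, False]

    def test_all_half_rejected_none(self):
        assert not holm_bonferroni([0.5] * 11).any()

    def test_empty_input_empty_output(self):
        assert holm_bonferroni([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.2, 1.2])

    def test_matches_statsmodels_reference(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 12)))
            mine = holm_bonferroni(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            assert (mine == ref).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
    @settings(max_examples=300, deadline=None)
    def test_rejections_are_monotone(self, ps):
        flags = holm_bonferroni(ps)
        if flags.any():
            thresh = max(np.asarray(ps)[flags])
            assert all(flags[i] for i, p in enumerate(ps) if p < thresh)


# ---------------------------------------------------------------------------
# correlations, pre/post, descriptives
# ---------------------------------------------------------------------------


class TestCorrelations:
    def test_self_correlation_is_one(self, tiny_rows, tiny_cohort):
        r, p = person_mean_correlations(tiny_rows, tiny_cohort.profiles)
        assert np.allclose(np.diag(r), 1.0)

    def test_fewer_than_three_persons_undefined(self, tiny_rows, tiny_cohort):
        rows2 = tiny_rows[tiny_rows["participant_id"].isin(["P01", "P02"])]
        r, p = person_mean_correlations(rows2, tiny_cohort.profiles)
        assert np.isnan(r.loc["sfi", "se"])

    def test_null_markers_uncorrelated_and_coupled_marker_negative(self):
        """HRV person means (uncoupled) hover near r=0 while symptoms and
        sleep efficiency correlate negatively when coupled."""
        from wearlab.config import SimulationConfig
        from wearlab.simulate import generate_cohort

        cfg = SimulationConfig(
            n_participants=60, n_days=35, seed=8, beta_sfi=0.0, beta_se=0.0,
            gds_loading=0.0, sleep_person_loading=0.6,
            missing_rates={"survey": 0, "hrv": 0, "sleep": 0, "steps": 0},
        )
        co = generate_cohort(cfg)
        rows = assemble_table(
            co.sleep_nights, co.hrv_daily, co.activity_daily, co.surveys, co.profiles
        )
        r, p = person_mean_correlations(rows, co.profiles)
        assert abs(r.loc["symptom_pm", "sdnn"]) < 0.25
        # fragmentation-prone persons are more symptomatic: SFI positive,
        # efficiency negative, matching the observed person-level pattern
        assert r.loc["symptom_pm", "sfi"] > 0.2
        assert r.loc["symptom_pm", "se"] < -0.1


class TestWilcoxon:
    def test_spec_pairs_drop_zero_and_rank(self):
        res = wilcoxon_prepost([3, 5, 4, 6], [1, 2, 4, 3])
        assert res["n"] == 3  # the (4,4) pair is dropped
        assert res["statistic"] == 0.0  # all remaining differences negative
        assert res["median_difference"] < 0

    def test_exact_p_matches_sign_enumeration(self, rng):
        """For n <= 8 untied pairs the p-value equals the exhaustive
        signed-rank enumeration."""
        for _ in range(30):
            n = int(rng.integers(4, 9))
            d = rng.normal(0, 1, n)
            d = np.where(np.abs(d) < 1e-3, 0.5, d)
            while len(set(np.abs(d))) < n:
                d = d + rng.normal(0, 1e-6, n)
            res = wilcoxon_prepost(np.zeros(n), d)
            assert res["p"] == pytest.approx(signed_rank_p_oracle(d), abs=1e-12)

    def test_all_zero_differences_undefined(self):
        res = wilcoxon_prepost([1, 2, 3], [1, 2, 3])
        assert np.isnan(res["p"]) and "undefined" in res["note"]

    def test_hodges_lehmann_interval_brackets_median(self, rng):
        pre = rng.normal(10, 2, 20)
        post = pre - 1.5 + rng.normal(0, 0.5, 20)
        res = wilcoxon_prepost(pre, post)
        assert res["ci_low"] <= res["median_difference"] <= res["ci_high"]
        assert res["ci_low"] < -0.5 and res["p"] < 0.01


class TestPrePost:
    def test_identical_pre_post_t_zero_p_one(self):
        res = paired_t_prepost([50, 60, 70], [50, 60, 70])
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_full_battery_on_profiles(self, tiny_cohort):
        out = pre_post_tests(tiny_cohort.profiles)
        assert set(out) == {"gds", "psqi", "sus", "sus_age_moderation"}
        assert out["sus"]["test"] == "paired_t"

    def test_age_76_in_oldest_group(self):
        profiles = pd.DataFrame(
            {
                "baseline_gds": [3, 6, 2, 8],
                "gds_post": [2, 5, 2, 7],
                "baseline_psqi": [8, 9, 7, 10],
                "psqi_post": [6, 8, 7, 9],
                "sus_pre": [50.0, 40.0, 60.0, 45.0],
                "sus_post": [55.0, 42.0, 61.0, 50.0],
                "age": [75, 76, 74, 80],  # 75 is NOT oldest; 76 is
            }
        )
        out = pre_post_tests(profiles)
        # both groups non-empty (75 -> younger, 76/80 -> oldest), so the
        # interaction is estimable with df1 = 1
        assert out["sus_age_moderation"]["df1"] == 1
        assert np.isfinite(out["sus_age_moderation"]["F"])


class TestDescriptives:
    def test_gds_five_lands_in_risk_group(self):
        profiles = pd.DataFrame(
            {
                "participant_id": ["A", "B", "C", "D"],
                "age": [70, 75, 80, 72],
                "sex": ["woman", "man", "woman", "woman"],
                "education": [1, 2, 1, 3],
                "income_band": [2, 2, 1, 3],
                "n_chronic": [4, 3, 5, 2],
                "baseline_gds": [5, 4, 10, 2],
                "baseline_psqi": [8, 6, 9, 7],
                "sus_pre": [50.0, 60.0, 40.0, 55.0],
            }
        )
        tab = descriptive_table(profiles).set_index("variable")
        age_row = tab.loc["age"]
        # risk group = GDS >= 5 -> participants A (70) and C (80)
        assert age_row["mean_yes"] == pytest.approx(75.0)
        assert age_row["mean_no"] == pytest.approx(73.5)

    def test_fisher_matches_hypergeometric_enumeration(self):
        for table in ([(1, 9), (6, 9)], [(2, 3), (4, 1)], [(0, 5), (5, 0)]):
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(fisher_p_oracle(table), abs=1e-10)

    def test_equal_group_means_give_t_near_zero(self):
        profiles = pd.DataFrame(
            {
                "participant_id": list("ABCDEF"),
                "age": [70, 80, 75, 70, 80, 75],
                "sex": ["woman"] * 6,
                "education": [1] * 6,
                "income_band": [2] * 6,
                "n_chronic": [4] * 6,
                "baseline_gds": [2, 3, 4, 6, 7, 8],
                "baseline_psqi": [8] * 6,
                "sus_pre": [50.0] * 6,
            }
        )
        tab = descriptive_table(profiles).set_index("variable")
        assert abs(tab.loc["age", "statistic"]) < 1e-12
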
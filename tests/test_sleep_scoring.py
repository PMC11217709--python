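"""Sleep rescoring, onset/offset detection, and nightly metrics."""

from datetime import date, datetime
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearlab import sleep
from wearlab.sleep import (
    ASLEEP,
    AWAKE,
    MISSING,
    SleepWakeSeries,
    compute_metrics,
    decode_runs,
    detect_onset_offset,
    encode_runs,
    extract_window,
    metrics_from_runs,
    rescore,
    rescore_runs,
    window_bounds,
)

from _oracles import metrics_oracle, onset_offset_oracle, rescore_oracle

W, S, M = AWAKE, ASLEEP, MISSING


def _rescore_seq(seq, direction="as_printed"):
    return list(decode_runs(rescore_runs(encode_runs(np.array(seq, dtype=np.int8)), direction)))


class TestRescoreRules:
    def test_three_sleep_minutes_after_ten_awake_become_awake(self):
        seq = [W] * 10 + [S] * 5
        assert _rescore_seq(seq) == [W] * 13 + [S] * 2

    def test_short_bout_flanked_by_long_wake_is_removed(self):
        seq = [W] * 16 + [S] * 5 + [W] * 16
        assert _rescore_seq(seq) == [W] * 37

    def test_flank_of_exactly_15_does_not_remove_bout(self):
        seq = [W] * 15 + [S] * 5 + [W] * 15
        # rule (2) still takes the first 3 minutes after the 15-minute wake run
        assert _rescore_seq(seq) == [W] * 18 + [S] * 2 + [W] * 15

    def test_nine_minute_bout_flanked_by_21_awake_removed_by_rule5(self):
        seq = [W] * 21 + [S] * 9 + [W] * 21
        assert _rescore_seq(seq) == [W] * 51

    def test_all_asleep_unchanged(self):
        seq = [S] * 30
        assert _rescore_seq(seq) == seq

    def test_as_printed_rule1_is_noop_webster_rescores_first_minute(self):
        seq = [W] * 4 + [S] * 30
        assert _rescore_seq(seq, "as_printed") == seq
        assert _rescore_seq(seq, "webster") == [W] * 5 + [S] * 29

    def test_missing_minutes_break_wake_runs(self):
        # the 10-minute wake context is interrupted by a gap: rule 2 idle
        seq = [W] * 5 + [M] + [W] * 5 + [S] * 12
        assert _rescore_seq(seq) == seq

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            rescore_runs([(S, 5)], "cole_kripke")


class TestOracleEquivalence:
    def test_exhaustive_binary_sequences_up_to_length_14(self):
        """Both rule directions agree with the literal-scan oracle on every
        sleep/wake sequence of length <= 14."""
        for n in range(1, 15):
            for bits in product((W, S), repeat=n):
                seq = np.array(bits, dtype=np.int8)
                for direction in ("as_printed", "webster"):
                    got = _rescore_seq(seq, direction)
                    assert got == rescore_oracle(list(bits), direction), (
                        bits, direction)

    def test_random_sequences_with_missing_up_to_length_22(self, rng):
        for _ in range(4000):
            n = int(rng.integers(1, 23))
            seq = rng.choice([W, S, M], size=n, p=[0.45, 0.45, 0.10])
            got = _rescore_seq(seq)
            exp = rescore_oracle(list(seq))
            assert got == exp
            # onset/offset and metrics agree on the rescored series
            runs = encode_runs(np.array(exp, dtype=np.int8))
            oo = sleep.onset_offset_runs(runs)
            assert oo == onset_offset_oracle(exp)
            if oo is not None:
                m = metrics_from_runs(runs)
                tib, tst, n_awak, n_long, n_missing = metrics_oracle(exp)
                if m.valid:
                    assert (m.time_in_bed, m.tst, m.n_awakenings, m.n_long_episodes) == (
                        tib, tst, n_awak, n_long)

    @given(
        st.lists(st.sampled_from([W, S, M]), min_size=1, max_size=22),
        st.sampled_from(["as_printed", "webster"]),
    )
    @settings(max_examples=400, deadline=None)
    def test_property_equivalence(self, seq, direction):
        assert _rescore_seq(seq, direction) == rescore_oracle(seq, direction)

    @given(st.lists(st.sampled_from([W, S, M]), min_size=1, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_isolated_bout_rules_idempotent(self, seq):
        """Rules (3)-(5) are idempotent: removing isolated bouts twice
        equals removing them once."""
        runs = encode_runs(np.array(seq, dtype=np.int8))
        once = sleep._rule_isolated_bout(sleep._rule_isolated_bout(runs, 6, 15), 10, 20)
        twice = sleep._rule_isolated_bout(sleep._rule_isolated_bout(once, 6, 15), 10, 20)
        assert once == twice

    @given(
        st.lists(st.sampled_from([W, S, M]), min_size=1, max_size=60),
        st.sampled_from(["as_printed", "webster"]),
    )
    @settings(max_examples=300, deadline=None)
    def test_rescoring_never_increases_sleep(self, seq, direction):
        before = seq.count(S)
        after = _rescore_seq(seq, direction).count(S)
        assert after <= before


class TestOnsetOffset:
    def test_single_qualifying_run(self):
        seq = [W] * 100 + [S] * 10 + [W] * 50
        assert detect_onset_offset(_series(seq)) == (100, 109)

    def test_nine_minute_runs_do_not_qualify(self):
        seq = ([S] * 9 + [W]) * 5
        assert detect_onset_offset(_series(seq)) is None

    def test_onset_first_run_offset_last_run(self):
        seq = [W] * 20 + [S] * 12 + [W] * 30 + [S] * 15 + [W] * 5
        assert detect_onset_offset(_series(seq)) == (20, 76)


def _series(seq, night=date(2022, 9, 5)):
    return SleepWakeSeries("P01", night, datetime(2022, 9, 5, 18), np.array(seq, dtype=np.int8))


class TestMetrics:
    def test_sleep_efficiency_formula(self):
        # 400 minutes in bed, 320 asleep -> SE 80%
        seq = [S] * 10 + ([W] * 8 + [S] * 31) * 10 + [S]
        m = compute_metrics(_series(seq))
        assert m.time_in_bed == 401
        assert m.tst == 321
        assert m.se == pytest.approx(100 * 321 / 401)

    def test_fragmentation_index_formula(self):
        # TST 300 with 3 awakenings > 1 min -> SFI 0.01
        seq = [S] * 75 + [W] * 3 + [S] * 75 + [W] * 2 + [S] * 75 + [W] * 4 + [S] * 75
        m = compute_metrics(_series(seq))
        assert m.tst == 300
        assert m.n_awakenings == 3
        assert m.sfi == pytest.approx(0.01)

    def test_uninterrupted_sleep(self):
        m = compute_metrics(_series([S] * 200))
        assert m.sfi == 0 and m.se == 100.0 and m.n_awakenings == 0

    def test_single_minute_awakenings_do_not_count(self):
        seq = [S] * 50 + [W] + [S] * 50
        m = compute_metrics(_series(seq))
        assert m.n_awakenings == 0
        assert m.tst == 100

    def test_long_episode_threshold(self):
        seq = [S] * 20 + [W] * 5 + [S] * 20 + [W] * 4 + [S] * 20
        m = compute_metrics(_series(seq), long_episode_min=5)
        assert m.n_long_episodes == 1 and m.n_awakenings == 2

    def test_excess_missing_invalidates_night(self):
        seq = [S] * 20 + [M] * 20 + [S] * 40
        m = compute_metrics(_series(seq))
        assert not m.valid and m.invalid_reason == "missing_gt_20pct"

    def test_no_sleep_run_invalid(self):
        m = compute_metrics(_series([W] * 100))
        assert not m.valid and np.isnan(m.sfi)


class TestWindowExtraction:
    def _minutes(self, start, n, pid="P01"):
        ts = pd.date_range(start, periods=n, freq="min")
        return pd.DataFrame(
            {"participant_id": pid, "timestamp": ts, "sleep_class": ["asleep"] * n}
        )

    def test_full_window_is_1080_minutes(self):
        m = self._minutes(datetime(2022, 9, 5, 18), 1080)
        w = extract_window(m, "P01", date(2022, 9, 5))
        assert len(w) == 1080
        assert (w.classes == ASLEEP).all()

    def test_reversed_cycle_window_is_daytime(self):
        lo, hi = window_bounds(date(2022, 9, 5), reversed_cycle=True)
        assert lo == datetime(2022, 9, 5, 6) and hi == datetime(2022, 9, 6, 0)
        m = self._minutes(datetime(2022, 9, 5, 6), 1080)
        w = extract_window(m, "P01", date(2022, 9, 5), reversed_cycle=True)
        assert len(w) == 1080 and (w.classes == ASLEEP).all()

    def test_absent_minutes_fill_as_missing(self):
        m = self._minutes(datetime(2022, 9, 5, 18), 60)
        w = extract_window(m, "P01", date(2022, 9, 5))
        assert (w.classes[:60] == ASLEEP).all()
        assert (w.classes[60:] == MISSING).all()

    def test_empty_window_flags_invalid_downstream(self):
        m = self._minutes(datetime(2022, 9, 5, 18), 10)
        w = extract_window(m, "P01", date(2023, 1, 1))
        assert (w.classes == MISSING).all()
        assert not compute_metrics(rescore(w)).valid


def test_generator_truth_matches_pipeline_scoring(tiny_complete_cohort):
    """Scoring the rendered minute stream reproduces the generator's nightly
    metrics exactly (both modes share one scored night structure)."""
    co = tiny_complete_cohort
    scored = sleep.score_nights(co.minutes, co.profiles)
    merged = scored.merge(
        co.sleep_nights, on=["participant_id", "night_date"], suffixes=("_p", "_g")
    )
    assert len(merged) == len(co.sleep_nights)
    for col in ("tst", "sfi", "se", "time_in_bed", "n_awakenings"):
        assert np.allclose(merged[f"{col}_p"], merged[f"{col}_g"], equal_nan=True)
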
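"""Lag-CRP counting, checked against an independent brute-force enumerator."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from spinfill.crp import (
    aggregate_crp,
    crp_by_participant,
    error_ratio,
    error_ratio_summary,
    group_position_counts,
    overall_lag_crp,
    position_counts,
    postanticipation_lag_crp,
    transition_lags,
)
from spinfill.scoring import score_trial
from spinfill.synthetic_recall import Response, Trial

from conftest import make_trial


# ---------------------------------------------------------------------------
# Brute-force oracle: recount numerators and denominators directly from the
# definitions, listing possible target positions per transition.

def oracle_overall(input_list, output, policy):
    n = len(input_list)
    inpos = {s: i + 1 for i, s in enumerate(input_list)}
    num, den = Counter(), Counter()
    for i in range(1, len(output)):
        prev, cur = output[i - 1], output[i]
        if prev not in inpos or cur not in inpos:
            continue
        before = {x for x in output[:i] if x in inpos}
        for lag in [l for l in range(-(n - 1), n) if l != 0]:
            target = inpos[prev] + lag
            if not 1 <= target <= n:
                continue
            if policy == "excluded" and input_list[target - 1] in before:
                continue
            den[lag] += 1
        if policy == "excluded" and cur in before:
            continue  # repeat: opportunities counted, no occurrence scored
        lag = inpos[cur] - inpos[prev]
        if lag != 0:
            num[lag] += 1
    return num, den


def oracle_postanticipation(input_list, output, policy):
    n = len(input_list)
    inpos = {s: i + 1 for i, s in enumerate(input_list)}
    num, den = Counter(), Counter()
    labels = []
    emitted = set()
    for k, s in enumerate(output, start=1):
        if s not in inpos:
            labels.append("other")
        elif s in emitted:
            labels.append("repeat")
        elif inpos[s] == k:
            labels.append("correct")
        elif inpos[s] > k:
            labels.append("anticipation")
        else:
            labels.append("postponement")
        emitted.add(s)
    if "anticipation" not in labels:
        return num, den
    i = labels.index("anticipation")
    if any(l != "correct" for l in labels[:i]) or i + 1 >= len(output):
        return num, den
    response = output[i + 1]
    if response not in inpos:
        return num, den
    before = {x for x in output[: i + 1] if x in inpos}
    m = inpos[output[i]]
    lags = [l for l in range(-(n - 1), n - 1) if l != 0]
    for lag in lags:
        target = m + lag
        if not 1 <= target <= n:
            continue
        if policy == "excluded" and input_list[target - 1] in before:
            continue
        den[lag] += 1
    if policy == "excluded" and response in before:
        return num, den
    lag = inpos[response] - m
    if lag != 0 and lags[0] <= lag <= lags[-1]:
        num[lag] += 1
    return num, den


def as_trial(output, input_list="ABCD"):
    return Trial(
        "p1", "scrambled", tuple(input_list),
        tuple(Response(i + 1, s, 300.0) for i, s in enumerate(output)),
    )


class TestTransitionLags:
    def test_worked_example(self, worked_example):
        assert transition_lags(score_trial(worked_example)) == [1, 2, -1]

    def test_fully_correct_output_all_plus_one(self):
        assert transition_lags(score_trial(make_trial("ABCDEF"))) == [1] * 5

    def test_wrap_transition_is_minus_five(self):
        assert transition_lags(score_trial(make_trial("FA"))) == [-5]

    def test_intrusion_voids_both_adjacent_transitions(self):
        st = score_trial(make_trial("A9C"))
        assert transition_lags(st) == []


class TestOverallLagCRP:
    def test_worked_example_counts(self, worked_example):
        table = overall_lag_crp([score_trial(worked_example)], "scored")
        assert table.numerator == {1: 1, 2: 1, -1: 1}
        # -1 opportunities arise after B (inpos 2) and D (inpos 4), not
        # after A (the first list item).
        assert table.denominator[-1] == 2

    def test_all_correct_trial_peaks_at_plus_one(self):
        table = overall_lag_crp([score_trial(make_trial("ABCDEF"))], "scored")
        assert table.crp(1) == 1.0
        for lag in table.lags:
            if lag != 1 and not math.isnan(table.crp(lag)):
                assert table.crp(lag) == 0.0

    def test_empty_input_gives_empty_table(self):
        table = overall_lag_crp([], "scored")
        assert table.denominator == {}
        assert math.isnan(table.crp(1))

    @pytest.mark.parametrize("policy", ["scored", "excluded"])
    def test_matches_oracle_on_all_short_outputs(self, policy):
        items = "ABCD"
        for length in range(0, 5):
            for output in itertools.product(items, repeat=length):
                table = overall_lag_crp([score_trial(as_trial(output))], policy)
                num, den = oracle_overall(items, output, policy)
                assert table.numerator == dict(num), (output, policy)
                assert table.denominator == dict(den), (output, policy)

    def test_numerator_bounded_by_denominator(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            output = [str(x) if x > 5 else "ABCDEF"[x]
                      for x in rng.integers(0, 8, rng.integers(1, 7))]
            for policy in ("scored", "excluded"):
                t = overall_lag_crp(
                    [score_trial(make_trial("".join(output)))], policy
                )
                for lag in t.lags:
                    assert t.numerator.get(lag, 0) <= t.denominator.get(lag, 0)


class TestPostanticipationLagCRP:
    def test_worked_example_scored_response(self, worked_example):
        table = postanticipation_lag_crp([score_trial(worked_example)], "scored")
        # Anticipated D sits at input position 4: reachable lags -3..+2.
        assert sorted(table.denominator) == [-3, -2, -1, 1, 2]
        assert table.numerator == {-1: 1}
        assert table.crp(-1) == 1.0

    def test_no_anticipations_gives_all_missing(self):
        table = postanticipation_lag_crp(
            [score_trial(make_trial("ABCDEF"))], "scored"
        )
        assert all(math.isnan(table.crp(l)) for l in table.lags)

    def test_lag_range_excludes_plus_five(self):
        table = postanticipation_lag_crp([], "scored")
        assert max(table.lags) == 4
        assert min(table.lags) == -5

    @pytest.mark.parametrize("policy", ["scored", "excluded"])
    def test_matches_oracle_on_all_short_outputs(self, policy):
        items = "ABCD"
        for length in range(0, 5):
            for output in itertools.product(items, repeat=length):
                table = postanticipation_lag_crp(
                    [score_trial(as_trial(output))], policy
                )
                num, den = oracle_postanticipation(items, output, policy)
                assert table.numerator == dict(num), (output, policy)
                assert table.denominator == dict(den), (output, policy)

    def test_fill_in_and_infill_invariant_to_repeat_policy(self):
        rng = np.random.default_rng(1)
        symbols = list("ABCDEF")
        trials = []
        for i in range(300):
            k = rng.integers(2, 7)
            out = "".join(symbols[j] for j in rng.integers(0, 6, k))
            trials.append(score_trial(make_trial(out, trial_index=i + 1)))
        scored = postanticipation_lag_crp(trials, "scored")
        excluded = postanticipation_lag_crp(trials, "excluded")
        for lag in (-1, 1):
            a, b = scored.crp(lag), excluded.crp(lag)
            assert (math.isnan(a) and math.isnan(b)) or a == b

    def test_mixed_participants_rejected(self):
        trials = [score_trial(make_trial("ABDC", participant="a")),
                  score_trial(make_trial("ABDC", participant="b"))]
        with pytest.raises(ValueError):
            postanticipation_lag_crp(trials, "scored")


class TestErrorRatio:
    def test_simple_quotient(self, worked_example):
        # Build a participant with fill-in rate 0.5 and infill rate 0.25 is
        # cumbersome by hand; check the arithmetic on a table directly.
        table = postanticipation_lag_crp([score_trial(worked_example)], "scored")
        table.numerator = {-1: 2, 1: 1}
        table.denominator = {-1: 4, 1: 4}
        summary = error_ratio(table)
        assert summary.p_fill_in == 0.5
        assert summary.p_infill == 0.25
        assert summary.error_ratio == 2.0

    def test_zero_infill_is_undefined_not_infinite(self, worked_example, caplog):
        table = postanticipation_lag_crp([score_trial(worked_example)], "scored")
        table.numerator = {-1: 1}
        with caplog.at_level("WARNING", logger="spinfill.crp"):
            summary = error_ratio(table)
        assert math.isnan(summary.error_ratio)
        assert "undefined" in caplog.text

    def test_overall_table_rejected(self, worked_example):
        with pytest.raises(ValueError):
            error_ratio(overall_lag_crp([score_trial(worked_example)], "scored"))

    def test_ratio_of_means_aggregation(self):
        trials = [
            score_trial(make_trial("ABDC", participant=p, trial_index=1))
            for p in ("a", "b")
        ]
        tables = crp_by_participant(trials, "postanticipation", "scored")
        frame = error_ratio_summary(tables, "group")
        assert frame.loc[0, "p_fill_in"] == 1.0
        frame_p = error_ratio_summary(tables, "participant")
        assert len(frame_p) == 2

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            error_ratio_summary([], "site")


class TestPositionCounts:
    def test_single_fill_in_at_anticipation_position(self, worked_example):
        counts = position_counts([score_trial(worked_example)])
        at3 = counts[counts["position"] == 3].iloc[0]
        assert at3["fill_in_count"] == 1
        assert counts["fill_in_count"].sum() == 1
        assert counts["infill_count"].sum() == 0

    def test_no_anticipations_all_zero(self):
        counts = position_counts([score_trial(make_trial("ABCDEF"))])
        assert counts["fill_in_count"].sum() == 0
        assert counts["infill_count"].sum() == 0

    def test_totals_conserve_pa_lag_counts(self):
        rng = np.random.default_rng(2)
        trials = []
        for i in range(200):
            out = "".join("ABCDEF"[j] for j in rng.integers(0, 6, 6))
            trials.append(score_trial(make_trial(out, trial_index=i + 1)))
        table = postanticipation_lag_crp(trials, "scored")
        counts = position_counts(trials)
        assert counts["fill_in_count"].sum() == table.numerator.get(-1, 0)
        assert counts["infill_count"].sum() == table.numerator.get(1, 0)

    def test_group_average(self, worked_example):
        trials = [
            score_trial(make_trial("ABDC", participant=p))
            for p in ("a", "b", "c", "d")
        ]
        grouped = group_position_counts(position_counts(trials))
        at3 = grouped[grouped["position"] == 3].iloc[0]
        assert at3["fill_in_count"] == 1.0


class TestAggregateCRP:
    def make_tables(self, values, lag=-1):
        tables = []
        for i, v in enumerate(values):
            t = postanticipation_lag_crp(
                [score_trial(make_trial("ABDC", participant=f"p{i}"))], "scored"
            )
            if v is None:
                t.numerator, t.denominator = {}, {}
            else:
                t.numerator = {lag: int(v * 10)}
                t.denominator = {lag: 10}
            tables.append(t)
        return tables

    def test_two_point_mean_and_se(self):
        frame = aggregate_crp(self.make_tables([0.4, 0.6]))
        row = frame[frame["lag"] == -1].iloc[0]
        assert row["mean_crp"] == pytest.approx(0.5)
        assert row["sem_crp"] == pytest.approx(0.1)
        assert row["n_participants"] == 2

    def test_participant_missing_at_lag_excluded_at_that_lag_only(self):
        frame = aggregate_crp(self.make_tables([0.4, 0.6, None]))
        assert frame[frame["lag"] == -1].iloc[0]["n_participants"] == 2

    def test_identical_tables_have_zero_se(self):
        frame = aggregate_crp(self.make_tables([0.5, 0.5, 0.5]))
        row = frame[frame["lag"] == -1].iloc[0]
        assert row["mean_crp"] == pytest.approx(0.5)
        assert row["sem_crp"] == pytest.approx(0.0)

    def test_mixed_modes_rejected(self, worked_example):
        st = score_trial(worked_example)
        with pytest.raises(ValueError):
            aggregate_crp([postanticipation_lag_crp([st], "scored"),
                           overall_lag_crp([st], "scored")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_crp([])
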
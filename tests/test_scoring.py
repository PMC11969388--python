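"""Event aggregation and the defence score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antdol import (
    aggregate_events,
    colony_efficiency,
    colony_mean_score,
    defence_score,
    norm_sting_rate,
    pooled_scores,
    read_events,
    score_records,
)
from antdol.scoring import BORIS_DIALECT


def events_frame(rows):
    return pd.DataFrame(
        rows, columns=["colony_id", "trial", "ant_id", "event_type", "onset", "offset"]
    )


ROSTER = pd.DataFrame(
    {"colony_id": ["c1"] * 4, "ant_id": ["a1", "a2", "a3", "a4"]}
)


class TestDefenceScore:
    def test_highly_defensive_ant(self):
        # 13 stings in 18 encounters, 629.25 s of stinging
        assert round(defence_score(13, 18, 629.25), 2) == 4.66

    def test_never_stung_scores_zero(self):
        assert defence_score(0, 14, 0) == 0.0

    def test_log_term_unit_case(self):
        assert defence_score(1, 1, np.e - 1) == pytest.approx(1.0)

    def test_no_encounters_assigned_zero(self):
        assert defence_score(2, 0, 10.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            defence_score(-1, 3, 0)

    @given(
        s=st.integers(0, 30), e=st.integers(1, 30),
        d=st.floats(0, 1e4, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_stings_and_duration(self, s, e, d):
        base = defence_score(s, e, d)
        assert defence_score(s + 1, e, d) > base or d == 0 and s >= 0 and np.isclose(
            defence_score(s + 1, e, d), base
        )
        if s > 0:
            assert defence_score(s, e, d + 1.0) > base

    def test_norm_sting_rate(self):
        assert norm_sting_rate(13, 18) == pytest.approx(13 / 18)
        assert norm_sting_rate(0, 14) == 0.0
        assert norm_sting_rate(2, 0) == 0.0


class TestAggregate:
    def test_counts_and_durations(self):
        ev = events_frame(
            [
                ("c1", 1, "a1", "encounter", 5.0, 5.0),
                ("c1", 1, "a1", "encounter", 50.0, 50.0),
                ("c1", 1, "a1", "encounter", 100.0, 100.0),
                ("c1", 1, "a1", "sting", 50.0, 54.0),
                ("c1", 1, "a1", "sting", 100.0, 106.0),
            ]
        )
        agg = aggregate_events(ev, ROSTER, n_trials=3)
        row = agg[(agg["ant_id"] == "a1") & (agg["trial"] == 1)].iloc[0]
        assert (row["n_encounters"], row["n_stings"], row["sting_seconds"]) == (3, 2, 10.0)

    def test_empty_events_give_zero_records_for_whole_roster(self):
        agg = aggregate_events(events_frame([]), ROSTER, n_trials=3)
        assert len(agg) == 4 * 3
        assert (agg[["n_encounters", "n_stings", "sting_seconds"]] == 0).all().all()

    def test_unknown_ant_is_hard_error(self):
        ev = events_frame([("c1", 1, "zz", "encounter", 1.0, 1.0)])
        with pytest.raises(ValueError, match="unknown"):
            aggregate_events(ev, ROSTER)

    def test_stings_exceeding_encounters_flagged_not_rejected(self):
        ev = events_frame(
            [("c1", 1, "a1", "encounter", 1.0, 1.0), ("c1", 1, "a1", "sting", 1.0, 2.0),
             ("c1", 1, "a1", "sting", 1.2, 2.5)]
        )
        rec = score_records(aggregate_events(ev, ROSTER))
        row = rec[(rec["ant_id"] == "a1") & (rec["trial"] == 1)].iloc[0]
        assert row["stings_exceed_encounters"]
        assert row["norm_sting_rate"] == 2.0


class TestPooled:
    def test_pooled_sums_then_scores(self):
        # one 4 s sting per trial, 1 encounter per trial -> ln(13)
        rows = []
        for t in (1, 2, 3):
            rows += [("c1", t, "a1", "encounter", 1.0, 1.0), ("c1", t, "a1", "sting", 1.0, 5.0)]
        agg = aggregate_events(events_frame(rows), ROSTER)
        pooled = pooled_scores(agg)
        row = pooled[pooled["ant_id"] == "a1"].iloc[0]
        assert (row["n_encounters"], row["n_stings"], row["sting_seconds"]) == (3, 3, 12.0)
        assert row["score"] == pytest.approx(np.log(13), abs=1e-12)

    def test_no_events_pooled_zero(self):
        pooled = pooled_scores(aggregate_events(events_frame([]), ROSTER))
        assert (pooled["score"] == 0).all()

    def test_single_trial_pooling_is_identity(self):
        rows = [("c1", 1, "a1", "encounter", 1.0, 1.0), ("c1", 1, "a1", "sting", 1.0, 3.0)]
        agg = aggregate_events(events_frame(rows), ROSTER)
        pooled = pooled_scores(agg)
        t1 = score_records(agg)
        a1_pooled = pooled[pooled["ant_id"] == "a1"].iloc[0]
        a1_t1 = t1[(t1["ant_id"] == "a1") & (t1["trial"] == 1)].iloc[0]
        assert a1_pooled["score"] == a1_t1["score"]


class TestColonyAggregates:
    def test_mean_score_includes_zeros(self):
        rows = [("c1", 1, "a1", "encounter", 1.0, 1.0), ("c1", 1, "a1", "sting", 1.0, 629.25)]
        rows = events_frame(
            [("c1", 1, "a1", "encounter", t, t) for t in np.linspace(1, 100, 18)]
            + [("c1", 1, "a1", "sting", t, t + 629.25 / 13) for t in np.linspace(1, 100, 13)]
        )
        rec = score_records(aggregate_events(rows, ROSTER, n_trials=1))
        means = colony_mean_score(rec, ROSTER)
        expected = defence_score(13, 18, 629.25) / 4
        assert means["mean_score"].iloc[0] == pytest.approx(expected)
        # at the printed 2 d.p. precision the colony mean is 4.66 / 4 = 1.165
        assert round(round(defence_score(13, 18, 629.25), 2) / 4, 3) == 1.165

    def test_missing_member_is_hard_error(self):
        rec = pd.DataFrame(
            {"colony_id": ["c1"] * 3, "trial": [1] * 3, "ant_id": ["a1", "a2", "a3"],
             "score": [0.0, 1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="member"):
            colony_mean_score(rec, ROSTER)

    def test_efficiency_totals_and_conservation(self):
        rows = (
            [("c1", 1, "a1", "sting", t, t + 1) for t in (1.0, 2.0, 3.0)]
            + [("c1", 2, "a2", "sting", t, t + 1) for t in (1.0, 2.0)]
        )
        ev = events_frame(rows)
        eff = colony_efficiency(ev)
        assert eff.set_index("colony_id").loc["c1", "total_stings"] == 5
        pooled = pooled_scores(aggregate_events(ev, ROSTER))
        assert pooled["n_stings"].sum() == 5

    def test_efficiency_zero_with_design(self):
        design = pd.DataFrame({"colony_id": ["c1"], "group_size": [4], "brood": ["none"]})
        eff = colony_efficiency(events_frame([]), design)
        assert eff.loc[0, "total_stings"] == 0


class TestReadEvents:
    def test_native_schema_round_trip(self, tmp_path):
        p = tmp_path / "events.csv"
        events_frame(
            [("c1", 1, "a1", "encounter", 1.0, 1.0), ("c1", 1, "a1", "sting", 1.0, 4.5)]
        ).to_csv(p, index=False)
        ev = read_events(p)
        assert len(ev) == 2

    def test_offset_before_onset_rejected(self, tmp_path):
        p = tmp_path / "events.csv"
        events_frame([("c1", 1, "a1", "sting", 5.0, 2.0)]).to_csv(p, index=False)
        with pytest.raises(ValueError, match="onset"):
            read_events(p)

    def test_boris_dialect_with_behaviour_map(self, tmp_path):
        p = tmp_path / "boris.csv"
        pd.DataFrame(
            {
                "colony_id": ["c1", "c1"],
                "trial": [1, 1],
                "subject": ["a1", "a1"],
                "behavior": ["contact intruder", "sting intruder"],
                "start": [3.0, 3.0],
                "stop": [3.0, 9.0],
            }
        ).to_csv(p, index=False)
        ev = read_events(
            p,
            dialect=BORIS_DIALECT,
            behaviour_map={"contact intruder": "encounter", "sting intruder": "sting"},
        )
        assert list(ev["event_type"]) == ["encounter", "sting"]

    def test_unknown_behaviour_rejected(self, tmp_path):
        p = tmp_path / "events.csv"
        events_frame([("c1", 1, "a1", "groom", 1.0, 1.0)]).to_csv(p, index=False)
        with pytest.raises(ValueError, match="unknown event type"):
            read_events(p)


class TestScoreVsNormRate:
    def test_positive_rank_correlation_on_simulated_ants(self, small_records):
        from scipy.stats import spearmanr

        per_trial, _ = small_records
        active = per_trial[per_trial["n_encounters"] > 0]
        rho = spearmanr(active["score"], active["norm_sting_rate"]).statistic
        assert rho > 0.8
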
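"""Alignment rules 1-5, bundling, criterion L and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from glupair.config import PairingParams
from glupair.pairing import pair_events

from conftest import make_events, make_readings, make_stays, ts
from reference_pairing import brute_force_pairs, random_micro_instance

STAY = [(1000, 10, 0, 2880)]


def _pair_one(readings_rows, event_rows, params=None):
    readings = make_readings(readings_rows)
    events = make_events(event_rows)
    pairs, _ = pair_events(events, readings, make_stays(STAY), params)
    return pairs.set_index("event_row_id")


class TestRules:
    def test_rule1_preceding_within_window(self):
        pairs = _pair_one(
            [(1, 10, 570, 150.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        row = pairs.loc[101]
        assert row["rule"] == 1 and row["glc_al"] == 150.0

    def test_rule2_following_when_nothing_precedes(self):
        pairs = _pair_one(
            [(1, 10, 660, 140.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        row = pairs.loc[101]
        assert row["rule"] == 2 and row["glc_al"] == 140.0

    def test_rule3_straddle_takes_higher_value(self):
        pairs = _pair_one(
            [(1, 10, 560, 120.0, "FINGERSTICK", "CHART"),
             (2, 10, 620, 180.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        row = pairs.loc[101]
        assert row["rule"] == 3 and row["glc_al"] == 180.0

    def test_rule3_tie_resolves_to_preceding(self):
        pairs = _pair_one(
            [(1, 10, 560, 150.0, "FINGERSTICK", "CHART"),
             (2, 10, 620, 150.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        row = pairs.loc[101]
        assert row["rule"] == 3 and row["glc_row_id"] == 1

    def test_rule5_floor_blocks_low_candidates_in_both_directions(self):
        pairs = _pair_one(
            [(1, 10, 590, 85.0, "FINGERSTICK", "CHART"),
             (2, 10, 620, 89.9, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        assert pairs.loc[101, "rule"] is pd.NA

    def test_floor_value_itself_is_eligible(self):
        pairs = _pair_one(
            [(1, 10, 590, 90.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        assert pairs.loc[101, "glc_al"] == 90.0

    @pytest.mark.parametrize("reading_min,paired", [
        (510, True),    # exactly 90 min before: inclusive
        (509, False),   # 91 min: outside
        (690, True),    # exactly 90 min after
        (691, False),
    ])
    def test_window_is_inclusive_at_the_boundary(self, reading_min, paired):
        pairs = _pair_one(
            [(1, 10, reading_min, 150.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        assert (pairs.loc[101, "rule"] is not pd.NA) is paired

    def test_identical_timestamp_tiebreak_value_then_lab(self):
        pairs = _pair_one(
            [(1, 10, 580, 150.0, "FINGERSTICK", "CHART"),
             (2, 10, 580, 170.0, "FINGERSTICK", "CHART"),
             (3, 10, 580, 170.0, "BLOOD", "LAB")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        assert pairs.loc[101, "glc_row_id"] == 3  # higher value, LAB origin


class TestBundles:
    def test_bolus_then_infusion_share_the_preceding_reading(self):
        pairs = _pair_one(
            [(1, 10, 580, 200.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
             (102, 10, 1000, 605, "SHORT", "INFUSION", {"rate": 3.0})])
        assert pairs.loc[101, "rule"] == 4 and pairs.loc[102, "rule"] == 4
        assert pairs.loc[101, "glc_row_id"] == 1
        assert pairs.loc[102, "glc_row_id"] == 1

    def test_higher_following_reading_wins_within_bundle_window(self):
        pairs = _pair_one(
            [(1, 10, 580, 150.0, "FINGERSTICK", "CHART"),
             (2, 10, 640, 220.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
             (102, 10, 1000, 605, "SHORT", "INFUSION", {"rate": 3.0})])
        assert pairs.loc[101, "glc_row_id"] == 2
        assert pairs.loc[102, "glc_row_id"] == 2
        assert pairs.loc[101, "rule"] == 4

    def test_distant_events_do_not_bundle(self):
        pairs = _pair_one(
            [(1, 10, 580, 200.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
             (102, 10, 1000, 720, "SHORT", "INFUSION", {"rate": 3.0})])
        assert pairs.loc[101, "rule"] == 1
        # 720 - 580 = 140 min > window: the lone infusion pairs nothing
        assert pairs.loc[102, "rule"] is pd.NA

    def test_bundle_with_no_eligible_reading_stays_unpaired(self):
        pairs = _pair_one(
            [(1, 10, 100, 200.0, "FINGERSTICK", "CHART")],
            [(101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
             (102, 10, 1000, 605, "SHORT", "INFUSION", {"rate": 3.0})])
        assert pairs.loc[101, "rule"] is pd.NA
        assert pairs.loc[102, "rule"] is pd.NA


class TestCriterionL:
    def test_events_outside_the_stay_are_excluded(self):
        readings = make_readings([(1, 10, 570, 150.0, "FINGERSTICK", "CHART")])
        events = make_events([
            (101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
            (102, 10, 1000, 3000, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
        ])
        pairs, summary = pair_events(events, readings, make_stays(STAY))
        assert set(pairs["event_row_id"]) == {101}
        assert summary.n_events_excluded == 1

    def test_readings_outside_the_stay_are_ineligible(self):
        readings = make_readings([
            (1, 10, -30, 150.0, "FINGERSTICK", "CHART"),  # before admission
        ])
        events = make_events([
            (101, 10, 1000, 30, "SHORT", "BOLUS_INYECTION", {"dose": 4.0})])
        pairs, _ = pair_events(events, readings, make_stays(STAY))
        assert pairs.loc[0, "rule"] is pd.NA


class TestProperties:
    def test_every_pair_respects_gap_floor_and_stay(self, clean_cohort):
        pairs, _ = pair_events(clean_cohort.events, clean_cohort.readings,
                               clean_cohort.stays)
        paired = pairs[pairs["rule"].notna()]
        slack = np.where(paired["rule"] == 4, 15.0, 0.0)
        assert (paired["gap_minutes"] <= 90.0 + slack).all()
        assert (paired["glc_al"] >= 90.0).all()

    def test_shrinking_window_never_gains_pairs(self, clean_cohort):
        counts = []
        for w in (90.0, 60.0, 30.0):
            _, summary = pair_events(
                clean_cohort.events, clean_cohort.readings,
                clean_cohort.stays, PairingParams(window_minutes=w))
            counts.append(summary.n_paired)
        assert counts[0] >= counts[1] >= counts[2]

    def test_rule1_dominates_on_protocol_driven_data(self, clean_cohort):
        _, summary = pair_events(clean_cohort.events, clean_cohort.readings,
                                 clean_cohort.stays)
        counts = summary.rule_counts
        assert counts.get(1, 0) == max(counts.values())

    def test_matches_brute_force_oracle_on_micro_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            events, readings, stays = random_micro_instance(rng)
            pairs, _ = pair_events(events, readings, stays)
            got = {}
            for r in pairs.itertuples():
                rid = None if pd.isna(r.glc_row_id) else int(r.glc_row_id)
                rl = None if pd.isna(r.rule) else int(r.rule)
                got[int(r.event_row_id)] = (rid, rl)
            assert got == brute_force_pairs(events, readings, stays)


class TestSummary:
    def test_group_breakdown_accounts_for_every_event(self, clean_cohort):
        pairs, summary = pair_events(clean_cohort.events,
                                     clean_cohort.readings,
                                     clean_cohort.stays)
        bg = summary.by_group
        assert bg["inputs_icu"].sum() == summary.n_events_in_icu
        assert bg["paired"].sum() == summary.n_paired
        assert ((bg["paired"] + bg["not_paired"]) == bg["inputs_icu"]).all()
        assert summary.n_events_input == len(clean_cohort.events)
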
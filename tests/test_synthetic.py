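"""The synthetic-EHR generator: determinism, schema, artefacts, ledger."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glupair import io_mimic
from glupair.synthetic import (SimConfig, expected_surviving_row_ids,
                               inject_artifacts, pairing_recovery,
                               simulate_cohort)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = SimConfig(n_stays=12, seed=42)
        simulate_cohort(cfg, out_dir=tmp_path / "a")
        simulate_cohort(cfg, out_dir=tmp_path / "b")
        for name in ("CHARTEVENTS.csv", "LABEVENTS.csv", "INPUTEVENTS_MV.csv",
                     "ICUSTAYS.csv", "truth_links.jsonl",
                     "truth_artifacts.jsonl"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimConfig(n_stays=5, seed=1))
        b = simulate_cohort(SimConfig(n_stays=5, seed=2))
        assert not a.chartevents["VALUENUM"].equals(b.chartevents["VALUENUM"])


class TestSchema:
    def test_tables_parse_through_the_readers(self, clean_cohort):
        assert len(clean_cohort.raw_readings) > 0
        assert len(clean_cohort.raw_events) > 0
        assert set(clean_cohort.raw_readings["source"]) <= {"FINGERSTICK",
                                                            "BLOOD"}
        assert set(clean_cohort.raw_events["acting_type"]) <= {
            "SHORT", "INTERMEDIATE", "LONG"}

    def test_every_insulin_row_has_a_ledger_link(self, clean_cohort):
        links = clean_cohort.tables.links
        inputs = clean_cohort.tables.inputevents
        assert set(links["INPUT_ROW_ID"]) == set(inputs["ROW_ID"])
        # triggers precede administrations and respect the protocol floor
        assert (links["TRUE_GAP_MINUTES"] >= 0).all()
        assert (links["BAND_LO"] >= 90.0).all()

    def test_zero_stays_give_header_only_tables(self, tmp_path):
        simulate_cohort(SimConfig(n_stays=0, seed=0), out_dir=tmp_path)
        for name in ("CHARTEVENTS", "LABEVENTS", "INPUTEVENTS_MV",
                     "ICUSTAYS"):
            lines = (tmp_path / f"{name}.csv").read_text().strip().splitlines()
            assert len(lines) == 1, name

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_stays=-1)
        with pytest.raises(ValueError):
            SimConfig(duplicate_rate=1.5)


class TestArtifacts:
    def test_zero_rates_leave_tables_unchanged(self):
        cfg = SimConfig(n_stays=8, seed=5).without_artifacts()
        clean = simulate_cohort(cfg)
        again = inject_artifacts(clean, cfg, np.random.default_rng(0))
        pd.testing.assert_frame_equal(clean.chartevents, again.chartevents)
        pd.testing.assert_frame_equal(clean.inputevents, again.inputevents)
        assert len(again.artifacts) == 0

    def test_ceiling_codes_fingersticks_as_500(self, corrupted_cohort):
        art = corrupted_cohort.tables.artifacts
        ceil = art[art["ARTIFACT"] == "ceiling"]
        chart = corrupted_cohort.tables.chartevents.set_index("ROW_ID")
        for row_id in ceil["ROW_ID"]:
            assert chart.loc[int(row_id), "VALUENUM"] == 500.0

    def test_delay_shifts_charttime_and_preserves_storetime(self,
                                                            corrupted_cohort):
        art = corrupted_cohort.tables.artifacts
        delayed = art[art["ARTIFACT"] == "charting_delay"]
        assert len(delayed) > 0
        chart = corrupted_cohort.tables.chartevents.set_index("ROW_ID")
        for _, a in delayed.iterrows():
            row = chart.loc[int(a["ROW_ID"])]
            true_time = pd.Timestamp(a["ORIGINAL"])
            assert row["STORETIME"] == true_time
            assert row["CHARTTIME"] > true_time

    def test_duplicate_count_is_binomial(self, tmp_path):
        cfg = SimConfig(n_stays=40, seed=13, duplicate_rate=0.1)
        tables = simulate_cohort(cfg)
        n_lab = len(tables.labevents)
        n_dup = int((tables.artifacts["ARTIFACT"] == "duplicate").sum())
        mean = 0.1 * n_lab
        sigma = np.sqrt(n_lab * 0.1 * 0.9)
        assert abs(n_dup - mean) <= 3 * sigma

    def test_delayed_charting_rate_matches_config(self, corrupted_cohort):
        # the curation pipeline's delayed flags are exactly the injected
        # charting-delay artefacts that survived curation
        art = corrupted_cohort.tables.artifacts
        injected = set(art.loc[art["ARTIFACT"] == "charting_delay",
                               "ROW_ID"].astype(int))
        cur = corrupted_cohort.readings
        flagged = set(cur.loc[cur["delayed"] & (cur["origin_table"] ==
                                                "CHART"), "row_id"])
        assert flagged <= injected
        surviving = injected & set(cur.loc[cur["origin_table"] == "CHART",
                                           "row_id"])
        assert flagged == surviving
        # and the injection rate is the configured one within binomial error
        n_chart = len(corrupted_cohort.tables.chartevents) - int(
            (art["ROLE"] == "injected").sum())
        p = corrupted_cohort.config.charting_delay_prob
        assert abs(len(injected) - p * n_chart) <= \
            3 * np.sqrt(n_chart * p * (1 - p)) + 1


class TestLedgerRecovery:
    def test_curation_recovers_clean_minus_unrecoverable(self,
                                                         corrupted_cohort):
        expected = expected_surviving_row_ids(corrupted_cohort.tables)
        cur = corrupted_cohort.readings
        got_chart = set(cur.loc[cur["origin_table"] == "CHART", "row_id"]
                        .astype(int))
        got_lab = set(cur.loc[cur["origin_table"] == "LAB", "row_id"]
                      .astype(int))
        got_inputs = set(corrupted_cohort.events["row_id"].astype(int))
        assert got_chart == expected["chart"]
        assert got_lab == expected["lab"]
        assert got_inputs == expected["input"]

    def test_recovered_effective_times_equal_true_times(self,
                                                        corrupted_cohort):
        # delayed rows resolve back to the true check time
        art = corrupted_cohort.tables.artifacts
        delayed = art[art["ARTIFACT"] == "charting_delay"]
        cur = corrupted_cohort.readings.set_index(["origin_table", "row_id"])
        for _, a in delayed.iterrows():
            key = ("CHART", int(a["ROW_ID"]))
            if key in cur.index:
                assert cur.loc[key, "effective_time"] \
                    == pd.Timestamp(a["ORIGINAL"])

    def test_imputed_rates_match_the_clean_rates(self, corrupted_cohort):
        art = corrupted_cohort.tables.artifacts
        missing = art[art["ARTIFACT"] == "rate_missing"]
        assert len(missing) > 0
        cur = corrupted_cohort.events.set_index("row_id")
        for _, a in missing.iterrows():
            rid = int(a["ROW_ID"])
            if rid in cur.index:
                assert cur.loc[rid, "rate"] == float(a["ORIGINAL"])
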
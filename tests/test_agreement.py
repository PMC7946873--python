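"""Validation assays: agreement pairing, Bland-Altman, moments, scenarios."""

import numpy as np
import pandas as pd
import pytest

from glupair import agreement as ag
from glupair.config import AgreementConfig

from conftest import make_events, make_readings, make_stays


def _pairs_from_deltas(delta, theta=10.0, mean=150.0):
    delta = np.asarray(delta, dtype=float)
    fs = mean + delta / 2.0
    lab = mean - delta / 2.0
    return pd.DataFrame({
        "icustay_id": np.arange(len(delta)),
        "fingerstick_value": fs, "lab_value": lab, "delta_glucose": delta,
        "delta_theta_minutes": np.full(len(delta), theta),
        "mean_value": (fs + lab) / 2.0,
    })


class TestFirstFingerstickPairs:
    def test_first_fingerstick_meets_closest_lab(self):
        readings = make_readings([
            (1, 10, 600, 150.0, "FINGERSTICK", "CHART"),
            (2, 10, 900, 160.0, "FINGERSTICK", "CHART"),  # not the first
            (3, 10, 620, 148.0, "BLOOD", "LAB"),          # closest lab
            (4, 10, 840, 160.0, "BLOOD", "LAB"),
        ])
        stays = make_stays([(1000, 10, 0, 1440)])
        pairs = ag.first_fingerstick_pairs(readings, stays)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["fingerstick_value"] == 150.0
        assert row["lab_value"] == 148.0
        assert row["delta_glucose"] == pytest.approx(2.0)  # fingerstick - lab
        assert row["delta_theta_minutes"] == pytest.approx(20.0)
        assert row["mean_value"] == pytest.approx(149.0)

    def test_single_method_stays_yield_no_pair(self):
        readings = make_readings([
            (1, 10, 600, 150.0, "FINGERSTICK", "CHART"),
            (2, 11, 600, 150.0, "BLOOD", "LAB"),
        ])
        stays = make_stays([(1000, 10, 0, 1440), (1001, 11, 0, 1440)])
        assert len(ag.first_fingerstick_pairs(readings, stays)) == 0

    def test_empty_input(self):
        assert len(ag.first_fingerstick_pairs(make_readings([]),
                                              make_stays([]))) == 0


class TestBlandAltman:
    def test_all_zero_differences_mean_perfect_agreement(self):
        table = ag.bland_altman(_pairs_from_deltas(np.zeros(30)))
        row = table[table["n"] > 0].iloc[0]
        assert row["bias"] == 0.0 and row["sd"] == 0.0
        assert row["p_value"] == 1.0  # no evidence against the null

    def test_constant_offset_gives_bias_and_zero_sd(self):
        table = ag.bland_altman(_pairs_from_deltas(np.full(25, 5.0)))
        row = table[table["n"] > 0].iloc[0]
        assert row["bias"] == pytest.approx(5.0)
        assert row["sd"] == 0.0
        assert row["loa_low"] == row["loa_high"] == pytest.approx(5.0)

    def test_limits_satisfy_their_defining_identity(self):
        rng = np.random.default_rng(5)
        table = ag.bland_altman(_pairs_from_deltas(rng.normal(3, 8, 500)),
                                k=1.96)
        row = table[table["n"] > 0].iloc[0]
        assert row["loa_low"] == pytest.approx(row["bias"] - 1.96 * row["sd"])
        assert row["loa_high"] == pytest.approx(row["bias"] + 1.96 * row["sd"])
        assert row["q1"] <= row["median"] <= row["q3"]

    def test_monte_carlo_bias_recovered_in_the_short_gap_bin(self):
        # deltas ~ Normal(2, 10) at gaps inside [0, 30): the estimated bias
        # must recover the simulated 2 mg/dL within Monte-Carlo error
        rng = np.random.default_rng(99)
        n = 4454
        pairs = _pairs_from_deltas(rng.normal(2.0, 10.0, n),
                                   theta=15.0)
        table = ag.bland_altman(pairs).set_index("bin")
        row = table.loc["[0, 30)"]
        assert row["n"] == n
        assert row["bias"] == pytest.approx(2.0, abs=3 * 10.0 / np.sqrt(n))

    def test_lowess_smooth_tracks_a_linear_trend(self):
        rng = np.random.default_rng(3)
        mean = rng.uniform(80, 300, 400)
        delta = 0.1 * mean + rng.normal(0, 1.0, 400)
        pairs = pd.DataFrame({
            "icustay_id": np.arange(400), "fingerstick_value": mean,
            "lab_value": mean, "delta_glucose": delta,
            "delta_theta_minutes": 10.0, "mean_value": mean,
        })
        curve = ag.lowess_delta_curve(pairs)
        mid = curve[(curve["mean_value"] > 120) & (curve["mean_value"] < 260)]
        assert np.allclose(mid["delta_smooth"], 0.1 * mid["mean_value"],
                           atol=1.0)


class TestDistributionSummary:
    def test_constant_sample_is_symmetric_with_zero_sd(self):
        readings = make_readings([
            (i, 10, i, 120.0, "FINGERSTICK", "CHART") for i in range(1, 6)])
        row = ag.distribution_summary(readings).set_index("group") \
            .loc["FINGERSTICK"]
        assert row["sd"] == 0.0 and row["skewness"] == 0.0

    def test_two_point_symmetric_sample(self):
        readings = make_readings([
            (1, 10, 0, 100.0, "BLOOD", "LAB"),
            (2, 10, 10, 200.0, "BLOOD", "LAB"),
        ])
        row = ag.distribution_summary(readings).set_index("group").loc["BLOOD"]
        assert row["skewness"] == pytest.approx(0.0)
        assert row["mean"] == 150.0 and row["min"] == 100.0 \
            and row["max"] == 200.0

    def test_normal_sample_has_null_moments(self):
        # closed form: Normal(150, 60) has zero skewness and excess kurtosis
        rng = np.random.default_rng(21)
        vals = rng.normal(150, 60, 200_000)
        readings = pd.DataFrame({
            "value": vals, "source": "BLOOD", "subject_id": 1,
        })
        row = ag.distribution_summary(readings).set_index("group").loc["BLOOD"]
        assert row["skewness"] == pytest.approx(0.0, abs=0.05)
        assert row["excess_kurtosis"] == pytest.approx(0.0, abs=0.1)
        assert row["mean"] == pytest.approx(150.0, abs=1.0)
        assert row["sd"] == pytest.approx(60.0, rel=0.02)


class TestScenarios:
    def _tiny_cohort(self):
        # stay 1000: trigger inside 90 min -> A and C agree
        # stay 1001: nearest preceding reading is 2 mg/dL (below the floor)
        #            and 120 min old -> C takes it, A pairs the later reading
        #            via the following rule, B(60) pairs nothing
        readings = make_readings([
            (1, 10, 570, 150.0, "FINGERSTICK", "CHART"),
            (2, 11, 480, 2.0, "FINGERSTICK", "CHART"),
            (3, 11, 665, 180.0, "FINGERSTICK", "CHART"),
        ])
        events = make_events([
            (101, 10, 1000, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
            (102, 11, 1001, 600, "SHORT", "BOLUS_INYECTION", {"dose": 4.0}),
        ])
        stays = make_stays([(1000, 10, 0, 1440), (1001, 11, 0, 1440)])
        return events, readings, stays

    def test_hand_enumerated_cohort(self):
        comp = ag.compare_scenarios(*self._tiny_cohort())
        per = comp.per_stay.set_index("icustay_id")
        assert per.loc[1000, "glc_a"] == 150.0
        assert per.loc[1000, "glc_c"] == 150.0  # same reading: zero diff
        assert per.loc[1001, "glc_c"] == 2.0    # no floor in scenario C
        assert per.loc[1001, "glc_a"] == 180.0  # following reading, rule 2
        assert per.loc[1001, "rule_a"] == 2
        assert np.isnan(per.loc[1001, "glc_b"])  # 60-min window pairs nothing
        assert comp.paired_counts == {"a": 2, "b": 1, "c": 2}
        assert comp.n_excluded == {"a": 0, "b": 1}

    def test_zero_difference_instances_are_counted(self):
        comp = ag.compare_scenarios(*self._tiny_cohort())
        table = comp.tables["A_vs_C"].set_index("bin")
        assert table.loc["[30, 60)", "n_zero"] == 1  # stay 1000, gap 30 min

    def test_scenario_counts_are_nested(self, clean_cohort):
        comp = ag.compare_scenarios(clean_cohort.events,
                                    clean_cohort.readings,
                                    clean_cohort.stays)
        c = comp.paired_counts
        assert c["c"] >= c["a"] >= c["b"]

    def test_agreement_when_triggers_are_inside_the_window(self, clean_cohort):
        # artifact-free cohort, delays <= 30 min: scenarios A and C choose
        # the same reading for every stay whose first bolus has a trigger
        comp = ag.compare_scenarios(clean_cohort.events,
                                    clean_cohort.readings,
                                    clean_cohort.stays)
        per = comp.per_stay.dropna(subset=["glc_a", "glc_c"])
        within = per[per["theta_c"] <= 90.0]
        assert (within["glc_a"] == within["glc_c"]).all()

    def test_empty_cohort(self):
        comp = ag.compare_scenarios(make_events([]), make_readings([]),
                                    make_stays([]))
        assert comp.n_stays == 0
        assert comp.paired_counts == {"a": 0, "b": 0, "c": 0}
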
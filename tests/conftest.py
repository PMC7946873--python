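"""Shared builders and cohort fixtures.

All fixtures are generated programmatically; nothing is loaded from disk
except through the package's own writers/readers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glupair import glucose_curation, insulin_curation, io_mimic
from glupair.synthetic import SimConfig, simulate_cohort

T0 = pd.Timestamp("2130-01-01 00:00:00")


def ts(minutes: float) -> pd.Timestamp:
    return T0 + pd.Timedelta(minutes=minutes)


def make_readings(rows) -> pd.DataFrame:
    """Rows: (row_id, subject, chart_min, value, source, origin[, kwargs])."""
    out = []
    for row in rows:
        row_id, subject, minute, value, source, origin, *rest = row
        kw = rest[0] if rest else {}
        store = kw.get("store_min")
        out.append({
            "row_id": row_id, "subject_id": subject,
            "hadm_id": kw.get("hadm", subject),
            "icustay_id": kw.get("icustay", pd.NA),
            "item_id": kw.get("item_id", 225664),
            "chart_time": ts(minute),
            "store_time": ts(store) if store is not None else pd.NaT,
            "effective_time": ts(minute),
            "value": value, "source": source,
            "error_flag": kw.get("error", False),
            "origin_table": origin,
        })
    df = pd.DataFrame(out, columns=io_mimic.GLUCOSE_COLUMNS)
    df["icustay_id"] = df["icustay_id"].astype("Int64")
    return df


def make_events(rows) -> pd.DataFrame:
    """Rows: (row_id, subject, icustay, start_min, acting, kind[, kwargs])."""
    out = []
    for row in rows:
        row_id, subject, icustay, minute, acting, kind, *rest = row
        kw = rest[0] if rest else {}
        end = kw.get("end_min")
        out.append({
            "row_id": row_id, "subject_id": subject,
            "hadm_id": kw.get("hadm", subject),
            "icustay_id": icustay if icustay is not None else pd.NA,
            "item_id": kw.get("item_id", 223258),
            "start_time": ts(minute),
            "end_time": ts(end) if end is not None else pd.NaT,
            "dose": kw.get("dose", np.nan),
            "rate": kw.get("rate", np.nan),
            "original_rate": kw.get("original_rate", np.nan),
            "acting_type": acting, "event_kind": kind,
            "infusion_stop": kw.get("infusion_stop", False),
            "rewritten": kw.get("rewritten", False),
        })
    df = pd.DataFrame(out, columns=io_mimic.INSULIN_COLUMNS)
    df["icustay_id"] = df["icustay_id"].astype("Int64")
    return df


def make_stays(rows) -> pd.DataFrame:
    """Rows: (icustay, subject, in_min, out_min)."""
    out = []
    for icustay, subject, in_min, out_min in rows:
        out.append({
            "icustay_id": icustay, "hadm_id": subject, "subject_id": subject,
            "in_time": ts(in_min), "out_time": ts(out_min),
            "los_days": (out_min - in_min) / (24 * 60.0),
            "first_icu_stay": True,
        })
    return pd.DataFrame(out, columns=io_mimic.STAY_COLUMNS)


class Cohort:
    """A simulated cohort read back through the package's own readers."""

    def __init__(self, config: SimConfig, tmpdir):
        self.config = config
        self.tables = simulate_cohort(config, out_dir=tmpdir)
        self.raw_readings = io_mimic.read_glucose_tables(
            f"{tmpdir}/CHARTEVENTS.csv", f"{tmpdir}/LABEVENTS.csv")
        self.raw_events = io_mimic.read_insulin_table(
            f"{tmpdir}/INPUTEVENTS_MV.csv")
        self.stays = io_mimic.read_icustays(f"{tmpdir}/ICUSTAYS.csv")
        self.events, self.insulin_report = insulin_curation.curate_insulin(
            self.raw_events)
        self.readings, self.glucose_report = glucose_curation.curate_glucose(
            self.raw_readings, self.events)


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory) -> Cohort:
    """Artifact-free cohort with treatment delays capped at 30 min."""
    cfg = SimConfig(n_stays=60, seed=7).without_artifacts()
    return Cohort(cfg, tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def corrupted_cohort(tmp_path_factory) -> Cohort:
    """Cohort with every artefact type injected at its default rate."""
    cfg = SimConfig(n_stays=60, seed=7)
    return Cohort(cfg, tmp_path_factory.mktemp("corrupted"))
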
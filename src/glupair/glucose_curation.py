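"""Inclusion criteria A-F for charted glucose readings.

The raw CHARTEVENTS/LABEVENTS extraction contains artefacts of bedside
charting: error-flagged rows, zero and null results, the same laboratory
value charted in two tables, ceiling-coded meter readings, and save
timestamps that precede the charted measurement time. The criteria below
remove or repair each class in a fixed order, and every step is accounted
for in a :class:`~glupair.report.CurationReport` so that row counts are
conserved end to end.

Order of application (mirrors the published curation flow):

A error-flagged rows -> B zero values -> C null values -> D restrict to
insulin recipients -> E cross-table deduplication -> F analytic limits and
measurement-time resolution.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import BLOOD, CHART, CurationConfig, FINGERSTICK, LAB
from .report import CurationReport


def drop_error_flagged(readings: pd.DataFrame,
                       report: Optional[CurationReport] = None
                       ) -> pd.DataFrame:
    """Criterion A: drop rows whose ERROR flag was recorded as 1."""
    keep = ~readings["error_flag"].astype(bool)
    if report is not None:
        report.add("A", "error-flagged rows removed", len(readings),
                   int((~keep).sum()))
    return readings[keep].reset_index(drop=True)


def drop_zero_values(readings: pd.DataFrame,
                     report: Optional[CurationReport] = None) -> pd.DataFrame:
    """Criterion B: drop rows whose recorded glucose is zero."""
    keep = readings["value"].isna() | (readings["value"] != 0)
    if report is not None:
        report.add("B", "zero glucose values removed", len(readings),
                   int((~keep).sum()))
    return readings[keep].reset_index(drop=True)


def drop_error_and_zero(readings: pd.DataFrame,
                        report: Optional[CurationReport] = None
                        ) -> pd.DataFrame:
    """Criteria A+B in sequence (error flag first, then zeros)."""
    return drop_zero_values(drop_error_flagged(readings, report), report)


def drop_null_values(readings: pd.DataFrame,
                     report: Optional[CurationReport] = None) -> pd.DataFrame:
    """Criterion C: drop rows where no numeric result was recorded."""
    keep = readings["value"].notna()
    if report is not None:
        report.add("C", "null glucose values removed", len(readings),
                   int((~keep).sum()))
    return readings[keep].reset_index(drop=True)


def restrict_to_insulin_recipients(readings: pd.DataFrame,
                                   insulin_events: pd.DataFrame,
                                   report: Optional[CurationReport] = None
                                   ) -> pd.DataFrame:
    """Criterion D: keep readings of patients with >=1 insulin event.

    Keyed on subject_id: glycemic management is only interpretable for the
    treated population, and the published cohort restricts to it.
    """
    recipients = set(insulin_events["subject_id"].unique())
    keep = readings["subject_id"].isin(recipients)
    if report is not None:
        report.add("D", "readings of patients without insulin removed",
                   len(readings), int((~keep).sum()))
    return readings[keep].reset_index(drop=True)


def deduplicate_cross_source(readings: pd.DataFrame,
                             report: Optional[CurationReport] = None
                             ) -> pd.DataFrame:
    """Criterion E: collapse identical readings charted in both tables.

    A laboratory result is routinely charted in CHARTEVENTS as well as
    LABEVENTS; when a (subject, timestamp, value) group spans both origin
    tables, a single representative is kept. The LAB-origin row wins the
    tie (laboratory values are the authoritative record); within a table
    the lowest row_id wins, so the choice is deterministic. Groups confined
    to one table are left alone. The pre-resolution chart_time is the time
    key, since deduplication runs before criterion F.
    """
    key = ["subject_id", "chart_time", "value"]
    origin_rank = readings["origin_table"].map({LAB: 0, CHART: 1})
    order = readings.assign(_rank=origin_rank).sort_values(
        ["_rank", "row_id"], kind="mergesort")
    grouped = order.groupby(key, sort=False, dropna=False)["origin_table"]
    spans_both = grouped.transform("nunique") > 1
    first_in_group = ~order.duplicated(subset=key, keep="first")
    keep = first_in_group | ~spans_both
    kept = order[keep].drop(columns="_rank").sort_index()
    if report is not None:
        report.add("E", "cross-table duplicate readings removed",
                   len(readings), len(readings) - len(kept))
    return kept.reset_index(drop=True)


def apply_analytic_limits(readings: pd.DataFrame,
                          config: Optional[CurationConfig] = None,
                          report: Optional[CurationReport] = None
                          ) -> pd.DataFrame:
    """Criterion F (value part): drop readings beyond analyzer accuracy.

    Laboratory-analyzer readings are kept strictly below 1000 mg/dL;
    fingerstick readings strictly below 500 mg/dL (meters ceiling-code
    anything higher as "500").
    """
    config = config or CurationConfig()
    limit = readings["source"].map({BLOOD: config.blood_limit,
                                    FINGERSTICK: config.fingerstick_limit})
    keep = readings["value"] < limit
    if report is not None:
        report.add("F", "values beyond analytic measurement limits removed",
                   len(readings), int((~keep).sum()))
    return readings[keep].reset_index(drop=True)


def resolve_measurement_time(readings: pd.DataFrame) -> pd.DataFrame:
    """Criterion F (time part): resolve when the glycemic check occurred.

    When the save timestamp (STORETIME) precedes the charted time, charting
    was delayed and the save time is the better estimate of the actual
    check; otherwise the charted time stands. Adds a ``delayed`` flag.
    """
    out = readings.copy()
    delayed = out["store_time"].notna() & (out["store_time"] < out["chart_time"])
    out["effective_time"] = out["chart_time"].where(~delayed, out["store_time"])
    out["delayed"] = delayed.to_numpy()
    return out


def curate_glucose(raw_readings: pd.DataFrame, insulin_events: pd.DataFrame,
                   config: Optional[CurationConfig] = None
                   ) -> Tuple[pd.DataFrame, CurationReport]:
    """Run criteria A-F in order and account for every removed row."""
    config = config or CurationConfig()
    report = CurationReport(patients_in=int(raw_readings["subject_id"]
                                            .nunique()))
    out = drop_error_and_zero(raw_readings, report)
    out = drop_null_values(out, report)
    out = restrict_to_insulin_recipients(out, insulin_events, report)
    out = deduplicate_cross_source(out, report)
    out = apply_analytic_limits(out, config, report)
    out = resolve_measurement_time(out)
    report.patients_out = int(out["subject_id"].nunique())
    report.extras["delayed_rows"] = int(out["delayed"].sum())
    report.extras["delayed_fraction"] = (
        float(out["delayed"].mean()) if len(out) else 0.0)
    report.verify()
    return out.reset_index(drop=True), report
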
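"""Readers and writers for MIMIC-III-shaped event tables.

Raw inputs are the four CSV tables CHARTEVENTS, LABEVENTS, INPUTEVENTS_MV and
ICUSTAYS (comma separated, RFC-4180, ISO-8601 timestamps, uppercase headers).
They are parsed into three tidy pandas frames used throughout the package:

glucose readings
    ``row_id, subject_id, hadm_id, icustay_id, item_id, chart_time,
    store_time, effective_time, value, source, error_flag, origin_table``
insulin events
    ``row_id, subject_id, hadm_id, icustay_id, item_id, start_time, end_time,
    dose, rate, original_rate, acting_type, event_kind, infusion_stop,
    rewritten``
ICU stays
    ``icustay_id, hadm_id, subject_id, in_time, out_time, los_days,
    first_icu_stay``

The two published outputs, a 16-column event timeline and a 21-column paired
timeline, are written and re-read losslessly by :func:`write_timeline` /
:func:`write_paired` and their ``read_*`` counterparts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import (BLOOD, BOLUS_INYECTION, BOLUS_PUSH, CHART, CurationConfig,
                     FINGERSTICK, INFUSION, LAB)

logger = logging.getLogger(__name__)

GLUCOSE_COLUMNS = [
    "row_id", "subject_id", "hadm_id", "icustay_id", "item_id", "chart_time",
    "store_time", "effective_time", "value", "source", "error_flag",
    "origin_table",
]

INSULIN_COLUMNS = [
    "row_id", "subject_id", "hadm_id", "icustay_id", "item_id", "start_time",
    "end_time", "dose", "rate", "original_rate", "acting_type", "event_kind",
    "infusion_stop", "rewritten",
]

STAY_COLUMNS = [
    "icustay_id", "hadm_id", "subject_id", "in_time", "out_time", "los_days",
    "first_icu_stay",
]

#: column order of glucose_insulin_ICU.csv
TIMELINE_COLUMNS = [
    "SUBJECT_ID", "HADM_ID", "ICUSTAY_ID", "LOS_ICU_days", "first_ICU_stay",
    "TIMER", "STARTTIME", "INPUT", "INPUT_HRS", "ENDTIME", "INSULINTYPE",
    "EVENT", "INFXSTOP", "GLCTIMER", "GLC", "GLCSOURCE",
]

#: column order of glucose_insulin_pair.csv
PAIRED_COLUMNS = TIMELINE_COLUMNS + [
    "GLC_AL", "GLCTIMER_AL", "GLCSOURCE_AL", "RULE", "Repeated",
]

_TS_FORMAT = "%Y-%m-%d %H:%M:%S"


class SchemaError(ValueError):
    """A required input column is missing or an output row is malformed."""


def _require(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _to_datetime(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s, errors="raise", format="mixed")


def _nullable_int(s: pd.Series) -> pd.Series:
    # treat blank strings as missing (criterion H wording: "blanks or null")
    if s.dtype == object:
        s = s.replace("", np.nan)
    return pd.to_numeric(s, errors="coerce").astype("Int64")


def read_glucose_tables(chart_path, lab_path,
                        config: Optional[CurationConfig] = None
                        ) -> pd.DataFrame:
    """Read CHARTEVENTS + LABEVENTS and keep configured glucose item IDs.

    Rows whose ITEMID is not in the item map are skipped (counted in the
    log); no other filtering happens here. ``source`` (fingerstick vs lab
    analyzer) follows the item map; ``origin_table`` records which table the
    row came from, which criterion E needs to spot cross-table duplicates.
    """
    config = config or CurationConfig()
    frames = []

    chart = pd.read_csv(chart_path, low_memory=False)
    _require(chart, ["SUBJECT_ID", "ITEMID", "CHARTTIME", "VALUENUM"],
             "CHARTEVENTS")
    n_raw = len(chart)
    chart = chart[chart["ITEMID"].isin(config.chart_glucose_items)].copy()
    skipped = n_raw - len(chart)
    g = pd.DataFrame({
        "row_id": (chart["ROW_ID"] if "ROW_ID" in chart.columns
                   else pd.RangeIndex(len(chart))).to_numpy(),
        "subject_id": chart["SUBJECT_ID"].astype(np.int64).to_numpy(),
        "hadm_id": _nullable_int(chart["HADM_ID"]) if "HADM_ID" in chart.columns
                   else pd.array([pd.NA] * len(chart), dtype="Int64"),
        "icustay_id": _nullable_int(chart["ICUSTAY_ID"])
                      if "ICUSTAY_ID" in chart.columns
                      else pd.array([pd.NA] * len(chart), dtype="Int64"),
        "item_id": chart["ITEMID"].astype(np.int64).to_numpy(),
        "chart_time": _to_datetime(chart["CHARTTIME"]).to_numpy(),
        "store_time": (_to_datetime(chart["STORETIME"])
                       if "STORETIME" in chart.columns
                       else pd.Series(pd.NaT, index=chart.index)).to_numpy(),
        "value": pd.to_numeric(chart["VALUENUM"], errors="coerce").to_numpy(),
        "error_flag": (pd.to_numeric(chart["ERROR"], errors="coerce")
                       .fillna(0).astype(int).eq(1)
                       if "ERROR" in chart.columns
                       else pd.Series(False, index=chart.index)).to_numpy(),
    })
    g["source"] = g["item_id"].map(config.chart_glucose_items)
    g["origin_table"] = CHART
    frames.append(g)

    lab = pd.read_csv(lab_path, low_memory=False)
    _require(lab, ["SUBJECT_ID", "ITEMID", "CHARTTIME", "VALUENUM"],
             "LABEVENTS")
    skipped += (~lab["ITEMID"].isin(config.lab_glucose_items)).sum()
    lab = lab[lab["ITEMID"].isin(config.lab_glucose_items)].copy()
    l = pd.DataFrame({
        "row_id": (lab["ROW_ID"] if "ROW_ID" in lab.columns
                   else pd.RangeIndex(len(lab))).to_numpy(),
        "subject_id": lab["SUBJECT_ID"].astype(np.int64).to_numpy(),
        "hadm_id": _nullable_int(lab["HADM_ID"]) if "HADM_ID" in lab.columns
                   else pd.array([pd.NA] * len(lab), dtype="Int64"),
        "icustay_id": pd.array([pd.NA] * len(lab), dtype="Int64"),
        "item_id": lab["ITEMID"].astype(np.int64).to_numpy(),
        "chart_time": _to_datetime(lab["CHARTTIME"]).to_numpy(),
        "store_time": pd.Series(pd.NaT, index=lab.index).to_numpy(),
        "value": pd.to_numeric(lab["VALUENUM"], errors="coerce").to_numpy(),
        "error_flag": False,
    })
    l["source"] = l["item_id"].map(config.lab_glucose_items)
    l["origin_table"] = LAB
    frames.append(l)

    if skipped:
        logger.info("read_glucose_tables: skipped %d rows with unmapped "
                    "item IDs", skipped)
    out = pd.concat(frames, ignore_index=True)
    # measurement time resolved later by criterion F; start from CHARTTIME
    out["effective_time"] = out["chart_time"]
    return out[GLUCOSE_COLUMNS]


def read_insulin_table(path, config: Optional[CurationConfig] = None
                       ) -> pd.DataFrame:
    """Read INPUTEVENTS_MV (MetaVision) and keep configured insulin items.

    Acting type follows the item map. The event kind (subcutaneous bolus /
    IV push / infusion) is derived from a configurable route column, by
    default MetaVision's ORDERCATEGORYDESCRIPTION. Bolus rows carry ``dose``
    (AMOUNT, U); infusion rows carry ``rate`` (RATE, U/hr) and keep the
    charted ORIGINALRATE as a carry-forward fallback for criterion I.
    """
    config = config or CurationConfig()
    df = pd.read_csv(path, low_memory=False)
    _require(df, ["SUBJECT_ID", "ITEMID", "STARTTIME"], "INPUTEVENTS_MV")
    n_raw = len(df)
    df = df[df["ITEMID"].isin(config.insulin_items)].copy()
    if n_raw - len(df):
        logger.info("read_insulin_table: skipped %d non-insulin rows",
                    n_raw - len(df))

    kind_col = config.event_kind_column
    if kind_col in df.columns:
        kind = df[kind_col].map(config.event_kind_map)
        unknown = kind.isna() & df[kind_col].notna()
        if unknown.any():
            logger.warning("read_insulin_table: %d rows with unmapped %s",
                           int(unknown.sum()), kind_col)
    else:
        kind = pd.Series(np.nan, index=df.index)
    # fall back on charted rate presence when the route column is absent
    if "RATE" in df.columns:
        kind = kind.fillna(
            pd.Series(np.where(pd.to_numeric(df["RATE"], errors="coerce")
                               .notna(), INFUSION, BOLUS_INYECTION),
                      index=df.index))
    else:
        kind = kind.fillna(BOLUS_INYECTION)

    status = (df["STATUSDESCRIPTION"].astype("string").fillna("")
              if "STATUSDESCRIPTION" in df.columns
              else pd.Series("", index=df.index, dtype="string"))

    amount = (pd.to_numeric(df["AMOUNT"], errors="coerce")
              if "AMOUNT" in df.columns else pd.Series(np.nan, index=df.index))
    rate = (pd.to_numeric(df["RATE"], errors="coerce")
            if "RATE" in df.columns else pd.Series(np.nan, index=df.index))
    orig_rate = (pd.to_numeric(df["ORIGINALRATE"], errors="coerce")
                 if "ORIGINALRATE" in df.columns
                 else pd.Series(np.nan, index=df.index))
    is_inf = (kind == INFUSION).to_numpy()

    out = pd.DataFrame({
        "row_id": (df["ROW_ID"] if "ROW_ID" in df.columns
                   else pd.RangeIndex(len(df))).to_numpy(),
        "subject_id": df["SUBJECT_ID"].astype(np.int64).to_numpy(),
        "hadm_id": _nullable_int(df["HADM_ID"]) if "HADM_ID" in df.columns
                   else pd.array([pd.NA] * len(df), dtype="Int64"),
        "icustay_id": _nullable_int(df["ICUSTAY_ID"])
                      if "ICUSTAY_ID" in df.columns
                      else pd.array([pd.NA] * len(df), dtype="Int64"),
        "item_id": df["ITEMID"].astype(np.int64).to_numpy(),
        "start_time": _to_datetime(df["STARTTIME"]).to_numpy(),
        "end_time": (_to_datetime(df["ENDTIME"]) if "ENDTIME" in df.columns
                     else pd.Series(pd.NaT, index=df.index)).to_numpy(),
        "dose": np.where(is_inf, np.nan, amount.to_numpy(dtype=float)),
        "rate": np.where(is_inf, rate.to_numpy(dtype=float), np.nan),
        "original_rate": np.where(is_inf, orig_rate.to_numpy(dtype=float),
                                  np.nan),
        "acting_type": df["ITEMID"].map(config.insulin_items).to_numpy(),
        "event_kind": kind.to_numpy(),
        "infusion_stop": status.str.contains("Stopped|Paused", regex=True)
                              .fillna(False).astype(bool).to_numpy(),
        "rewritten": status.eq("Rewritten").astype(bool).to_numpy(),
    })
    return out[INSULIN_COLUMNS]


def read_icustays(path) -> pd.DataFrame:
    """Read ICUSTAYS; derives LOS and first-stay flags when absent."""
    df = pd.read_csv(path, low_memory=False)
    _require(df, ["SUBJECT_ID", "HADM_ID", "ICUSTAY_ID", "INTIME", "OUTTIME"],
             "ICUSTAYS")
    out = pd.DataFrame({
        "icustay_id": df["ICUSTAY_ID"].astype(np.int64).to_numpy(),
        "hadm_id": df["HADM_ID"].astype(np.int64).to_numpy(),
        "subject_id": df["SUBJECT_ID"].astype(np.int64).to_numpy(),
        "in_time": _to_datetime(df["INTIME"]).to_numpy(),
        "out_time": _to_datetime(df["OUTTIME"]).to_numpy(),
    })
    if (out["in_time"] >= out["out_time"]).any():
        raise SchemaError("ICUSTAYS: INTIME must precede OUTTIME")
    if "LOS" in df.columns:
        out["los_days"] = pd.to_numeric(df["LOS"], errors="coerce").to_numpy()
    else:
        out["los_days"] = ((out["out_time"] - out["in_time"])
                           / pd.Timedelta(days=1))
    if "FIRST_ICU_STAY" in df.columns:
        out["first_icu_stay"] = df["FIRST_ICU_STAY"].astype(bool).to_numpy()
    else:
        out["first_icu_stay"] = (out.groupby("hadm_id")["in_time"]
                                 .rank(method="first").eq(1).to_numpy())
    return out[STAY_COLUMNS]


# ---------------------------------------------------------------------------
# ICU-stay window assignment (criterion L support)

def assign_stays(readings: pd.DataFrame, stays: pd.DataFrame) -> pd.DataFrame:
    """Attach ``icustay_id`` (and stay metadata) to glucose readings.

    A reading belongs to the stay of the same subject whose
    ``[in_time, out_time]`` window (inclusive) contains its effective time.
    Readings falling outside every stay get a null icustay_id; criterion L
    drops them downstream.
    """
    if len(readings) == 0:
        out = readings.copy()
        out["icustay_id"] = pd.array([], dtype="Int64")
        return out[GLUCOSE_COLUMNS]
    merged = readings.drop(columns=["icustay_id"]).merge(
        stays[["subject_id", "icustay_id", "in_time", "out_time"]],
        on="subject_id", how="left")
    for col in ("in_time", "out_time"):
        merged[col] = pd.to_datetime(merged[col])
    inside = (merged["effective_time"] >= merged["in_time"]) & \
             (merged["effective_time"] <= merged["out_time"])
    merged.loc[~inside, "icustay_id"] = pd.NA
    merged = merged.sort_values("icustay_id", na_position="last")
    merged = merged.drop_duplicates(subset=["row_id", "origin_table"],
                                    keep="first")
    merged["icustay_id"] = merged["icustay_id"].astype("Int64")
    return (merged.drop(columns=["in_time", "out_time"])
            .sort_index()[GLUCOSE_COLUMNS]
            .reset_index(drop=True))


def restrict_events_to_stay(events: pd.DataFrame, stays: pd.DataFrame
                            ) -> pd.DataFrame:
    """Keep insulin events whose start falls inside their own ICU stay.

    Events referencing an unknown icustay_id are excluded (logged), matching
    criterion L's removal of administrations outside the recorded stay.
    """
    merged = events.merge(stays[["icustay_id", "in_time", "out_time"]],
                          on="icustay_id", how="left")
    unknown = merged["in_time"].isna()
    if unknown.any():
        logger.warning("restrict_events_to_stay: %d events reference an "
                       "unknown ICU stay", int(unknown.sum()))
    inside = (merged["start_time"] >= merged["in_time"]) & \
             (merged["start_time"] <= merged["out_time"])
    out = merged[inside.fillna(False)].drop(columns=["in_time", "out_time"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Published outputs

def _assemble_timeline(readings: pd.DataFrame, events: pd.DataFrame,
                       stays: pd.DataFrame) -> pd.DataFrame:
    """Merge curated streams into one chronological per-stay timeline.

    Applies criterion L on both streams, then stacks glucose and insulin rows
    with TIMER = GLCTIMER (glucose) or STARTTIME (insulin). Keeps private
    ``_kind/_row_id/_origin`` columns for downstream joins.
    """
    from .insulin_curation import infusion_amount  # local import, no cycle

    readings = assign_stays(readings, stays)
    readings = readings[readings["icustay_id"].notna()]
    events = restrict_events_to_stay(events, stays)

    meta = stays.set_index("icustay_id")[["los_days", "first_icu_stay"]]

    g = pd.DataFrame({
        "SUBJECT_ID": readings["subject_id"].to_numpy(),
        "HADM_ID": readings["hadm_id"].to_numpy(),
        "ICUSTAY_ID": readings["icustay_id"].to_numpy(),
        "TIMER": readings["effective_time"].to_numpy(),
        "GLCTIMER": readings["effective_time"].to_numpy(),
        "GLC": readings["value"].to_numpy(),
        "GLCSOURCE": readings["source"].to_numpy(),
        "_kind": "glucose",
        "_row_id": readings["row_id"].to_numpy(),
        "_origin": readings["origin_table"].to_numpy(),
    })
    is_inf = events["event_kind"].eq(INFUSION)
    has_span = is_inf & events["end_time"].notna() & events["rate"].notna() \
        & (events["end_time"] > events["start_time"])
    input_col = events["dose"].copy()
    input_col[has_span] = infusion_amount(
        events.loc[has_span, "rate"].to_numpy(),
        events.loc[has_span, "start_time"],
        events.loc[has_span, "end_time"])
    i = pd.DataFrame({
        "SUBJECT_ID": events["subject_id"].to_numpy(),
        "HADM_ID": events["hadm_id"].to_numpy(),
        "ICUSTAY_ID": events["icustay_id"].to_numpy(),
        "TIMER": events["start_time"].to_numpy(),
        "STARTTIME": events["start_time"].to_numpy(),
        "INPUT": input_col.to_numpy(),
        "INPUT_HRS": events["rate"].to_numpy(),
        "ENDTIME": events["end_time"].to_numpy(),
        "INSULINTYPE": events["acting_type"].to_numpy(),
        "EVENT": events["event_kind"].to_numpy(),
        "INFXSTOP": events["infusion_stop"].to_numpy(),
        "_kind": "insulin",
        "_row_id": events["row_id"].to_numpy(),
        "_origin": "INPUT",
    })
    tl = pd.concat([g, i], ignore_index=True)
    tl = tl.join(meta, on="ICUSTAY_ID")
    tl = tl.rename(columns={"los_days": "LOS_ICU_days",
                            "first_icu_stay": "first_ICU_stay"})
    for col in TIMELINE_COLUMNS:
        if col not in tl.columns:
            tl[col] = np.nan
    tl = tl.sort_values(["ICUSTAY_ID", "TIMER", "_kind"],
                        kind="mergesort").reset_index(drop=True)
    return tl


def build_timeline(readings: pd.DataFrame, events: pd.DataFrame,
                   stays: pd.DataFrame) -> pd.DataFrame:
    """The 16-column glucose_insulin_ICU table from curated inputs."""
    tl = _assemble_timeline(readings, events, stays)
    return tl[TIMELINE_COLUMNS]


def build_paired_timeline(readings: pd.DataFrame, events: pd.DataFrame,
                          stays: pd.DataFrame, pairs: pd.DataFrame
                          ) -> pd.DataFrame:
    """The 21-column glucose_insulin_pair table.

    ``pairs`` is the event-level output of :func:`glupair.pairing.pair_events`
    (one row per in-ICU insulin event, with the aligned reading where a rule
    fired). Insulin rows gain GLC_AL/GLCTIMER_AL/GLCSOURCE_AL/RULE; each
    glucose row's ``Repeated`` flag records whether that reading was aligned
    to at least one insulin row in this table.
    """
    tl = _assemble_timeline(readings, events, stays)
    pcols = pairs[["event_row_id", "glc_al", "glctimer_al", "glcsource_al",
                   "rule"]].rename(columns={
                       "event_row_id": "_row_id", "glc_al": "GLC_AL",
                       "glctimer_al": "GLCTIMER_AL",
                       "glcsource_al": "GLCSOURCE_AL", "rule": "RULE"})
    ins = tl["_kind"].eq("insulin")
    tl = tl.merge(pcols, on="_row_id", how="left",
                  suffixes=(None, None))
    tl.loc[~ins, ["GLC_AL", "GLCTIMER_AL", "GLCSOURCE_AL", "RULE"]] = np.nan
    tl["RULE"] = pd.array(tl["RULE"], dtype="Int64")

    used = pairs.loc[pairs["glc_row_id"].notna(),
                     ["glc_row_id", "glc_origin"]].drop_duplicates()
    used_keys = set(zip(used["glc_row_id"].astype(np.int64),
                        used["glc_origin"]))
    tl["Repeated"] = [
        (int(r), o) in used_keys if k == "glucose" else np.nan
        for k, r, o in zip(tl["_kind"], tl["_row_id"], tl["_origin"])
    ]
    return tl[PAIRED_COLUMNS]


# ---------------------------------------------------------------------------
# CSV round-trip

def _validate_timeline(df: pd.DataFrame, paired: bool,
                       glucose_floor: float = 90.0,
                       window_minutes: float = 90.0,
                       bundle_gap_minutes: float = 15.0) -> None:
    cols = PAIRED_COLUMNS if paired else TIMELINE_COLUMNS
    if list(df.columns) != cols:
        raise SchemaError(f"expected columns {cols}, got {list(df.columns)}")
    has_glc = df["GLC"].notna()
    has_ins = df["INPUT"].notna() | df["INPUT_HRS"].notna()
    bad = ~(has_glc ^ has_ins)
    if bad.any():
        raise SchemaError("rows must carry exactly one of GLC or "
                          f"INPUT/INPUT_HRS; offending rows "
                          f"{df.index[bad][:5].tolist()}")
    timer = pd.to_datetime(df["TIMER"])
    ref = pd.to_datetime(df["GLCTIMER"]).where(
        has_glc, pd.to_datetime(df["STARTTIME"]))
    if not timer.equals(ref):
        off = df.index[timer != ref][:5].tolist()
        raise SchemaError(f"TIMER must equal GLCTIMER or STARTTIME; rows {off}")
    for stay, grp in df.groupby("ICUSTAY_ID", sort=False):
        t = pd.to_datetime(grp["TIMER"])
        if not t.is_monotonic_increasing:
            raise SchemaError(f"timeline not sorted within stay {stay}")
    if paired:
        rules = df["RULE"].dropna()
        if not rules.isin([1, 2, 3, 4]).all():
            raise SchemaError("RULE must be one of 1-4 when set")
        al = df["GLC_AL"].dropna()
        if (al < glucose_floor).any():
            raise SchemaError(f"GLC_AL below the {glucose_floor} mg/dL floor")
        has_al = df["GLC_AL"].notna()
        gap = (pd.to_datetime(df.loc[has_al, "GLCTIMER_AL"])
               - pd.to_datetime(df.loc[has_al, "STARTTIME"])).abs()
        # rule-4 bundles are windowed at the bundle anchor (the earlier
        # member), so the later member's own gap may exceed the window by
        # at most the bundle gap
        slack = np.where(df.loc[has_al, "RULE"] == 4,
                         pd.Timedelta(minutes=bundle_gap_minutes),
                         pd.Timedelta(0))
        if (gap > pd.Timedelta(minutes=window_minutes) + slack).any():
            raise SchemaError("aligned reading outside the pairing window")


def _write_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(_TS_FORMAT)
    out.to_csv(path, index=False, float_format="%.10g",
               date_format=_TS_FORMAT)


def write_timeline(df: pd.DataFrame, path) -> None:
    """Write glucose_insulin_ICU.csv; refuses rows violating invariants."""
    _validate_timeline(df, paired=False)
    _write_csv(df, path)


def write_paired(df: pd.DataFrame, path, glucose_floor: float = 90.0,
                 window_minutes: float = 90.0) -> None:
    """Write glucose_insulin_pair.csv; refuses rows violating invariants."""
    _validate_timeline(df, paired=True, glucose_floor=glucose_floor,
                       window_minutes=window_minutes)
    _write_csv(df, path)


def _read_output(path, paired: bool) -> pd.DataFrame:
    cols = PAIRED_COLUMNS if paired else TIMELINE_COLUMNS
    df = pd.read_csv(path)
    if list(df.columns) != cols:
        raise SchemaError(f"{path}: expected columns {cols}")
    for col in ["TIMER", "STARTTIME", "ENDTIME", "GLCTIMER"] + \
               (["GLCTIMER_AL"] if paired else []):
        df[col] = pd.to_datetime(df[col], format=_TS_FORMAT, errors="coerce")
    df["first_ICU_stay"] = df["first_ICU_stay"].map(
        {True: True, False: False, "True": True, "False": False})
    df["INFXSTOP"] = df["INFXSTOP"].map(
        {True: True, False: False, "True": True, "False": False})
    if paired:
        df["RULE"] = pd.array(df["RULE"], dtype="Int64")
        df["Repeated"] = df["Repeated"].map(
            {True: True, False: False, "True": True, "False": False})
    return df


def read_timeline(path) -> pd.DataFrame:
    return _read_output(path, paired=False)


def read_paired(path) -> pd.DataFrame:
    return _read_output(path, paired=True)
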
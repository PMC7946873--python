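"""Synthetic MetaVision-style EHR tables with a ground-truth ledger.

The generator emulates the charting behaviours the curation pipeline must
survive, without any access to real patient data:

- glucose measured by two methods (bedside fingerstick meter in CHARTEVENTS,
  laboratory analyzer in LABEVENTS) on jittered schedules, driven by a
  mean-reverting latent glucose process with meal excursions and an insulin
  response;
- a sliding-scale protocol that triggers a short-acting bolus, an infusion
  rate change, or a bolus+infusion bundle from each qualifying fingerstick,
  and a once-daily basal (long/intermediate) dose adjusted to the morning
  reading — every administration is linked to its triggering reading in a
  ground-truth ledger;
- charting artefacts injected at configurable rates on top of the clean
  tables: delayed charting (CHARTTIME late, STORETIME keeping the true check
  time), cross-table duplicate charting of lab values, error-flagged rows,
  zero and null results, ceiling-coded fingersticks ("500"), rewritten
  insulin entries, implausible outlier doses, and missing infusion rates
  recoverable from ORIGINALRATE.

Every artefact is itemised in the ledger with whether curation can recover
the row, so expected post-curation tables are computable in closed form.

A structural guarantee worth spelling out: consecutive charted readings
within a stay are at least ``min_reading_spacing_minutes`` apart (default
185 min, i.e. more than twice the 90-min pairing window). Whenever the
treatment delay is at most the window, the triggering reading is therefore
the unique latest eligible preceding reading and no following reading can
compete, so alignment recovers the link via rule 1 (or 4 for bundles); a
link can only be missed when its true reading-to-administration gap exceeds
the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

CHARTEVENTS_COLUMNS = ["ROW_ID", "SUBJECT_ID", "HADM_ID", "ICUSTAY_ID",
                       "ITEMID", "CHARTTIME", "STORETIME", "VALUENUM",
                       "VALUEUOM", "ERROR"]
LABEVENTS_COLUMNS = ["ROW_ID", "SUBJECT_ID", "HADM_ID", "ITEMID", "CHARTTIME",
                     "VALUENUM", "VALUEUOM"]
INPUTEVENTS_COLUMNS = ["ROW_ID", "SUBJECT_ID", "HADM_ID", "ICUSTAY_ID",
                       "STARTTIME", "ENDTIME", "ITEMID", "AMOUNT",
                       "AMOUNTUOM", "RATE", "RATEUOM", "ORIGINALRATE",
                       "ORDERCATEGORYDESCRIPTION", "STATUSDESCRIPTION"]
ICUSTAYS_COLUMNS = ["ROW_ID", "SUBJECT_ID", "HADM_ID", "ICUSTAY_ID", "INTIME",
                    "OUTTIME", "LOS"]
LINK_COLUMNS = ["INPUT_ROW_ID", "GLC_ROW_ID", "GLC_TABLE", "ICUSTAY_ID",
                "SUBJECT_ID", "TRUE_GAP_MINUTES", "BAND_LO", "BAND_HI",
                "KIND"]
ARTIFACT_COLUMNS = ["ARTIFACT", "TABLE", "ROW_ID", "ROLE", "RECOVERABLE",
                    "ORIGINAL"]

# ROW_ID namespaces keep identifiers unique across all four tables
_CHART_BASE = 1
_LAB_BASE = 10_000_000
_INPUT_BASE = 20_000_000

_TS = "%Y-%m-%d %H:%M:%S"


class SimConfig(BaseModel):
    """Full parameterisation of one synthetic cohort.

    The defaults encode an ICU on a conventional sliding-scale protocol:
    fingersticks roughly every 4 h, lab glucose about twice a day, modal
    short-acting doses of 2-4 U (boluses, glucose 140-165 mg/dL) and
    2-4 U/hr (infusions, 115-140 mg/dL), no treatment below 110 mg/dL,
    delayed charting on 8.4% of chart rows with a 25-min median delay, and
    treatment following its triggering check by a ~10-min median (capped at
    30 min; lift the cap and raise the median/sigma to study heavy-tailed
    charting behaviour).
    """

    model_config = {"frozen": True}

    n_stays: int = 50
    seed: int = 0
    start_date: str = "2130-01-01"

    # latent glucose process, evaluated at the charting grid
    glucose_setpoint: float = 140.0
    glucose_autocorr: float = 0.8
    glucose_noise_sd: float = 25.0
    meal_bump_prob: float = 0.25
    meal_bump_mean: float = 30.0
    insulin_effect_per_unit: float = 6.0  # mg/dL drop at the next reading

    # observation model
    fingerstick_bias: float = 2.0
    fingerstick_sd: float = 7.0
    lab_sd: float = 3.0

    # stay lengths (lognormal, days)
    los_days_median: float = 3.0
    los_days_sigma: float = 0.7
    los_days_min: float = 0.75

    # measurement schedule (minutes)
    fingerstick_interval_minutes: float = 240.0
    lab_interval_minutes: float = 480.0
    schedule_jitter_minutes: float = 10.0
    min_reading_spacing_minutes: float = 185.0

    # sliding-scale protocol: (band low, band high, dose or rate)
    bolus_bands: Tuple[Tuple[float, float, float], ...] = (
        (140.0, 165.0, 3.0), (165.0, 200.0, 4.0), (200.0, 250.0, 6.0),
        (250.0, math.inf, 8.0))
    infusion_bands: Tuple[Tuple[float, float, float], ...] = (
        (115.0, 140.0, 3.0), (140.0, 165.0, 4.0), (165.0, 200.0, 5.0),
        (200.0, math.inf, 6.0))
    infusion_stay_fraction: float = 0.3
    basal_fraction: float = 0.4
    basal_threshold: float = 100.0
    bundle_prob: float = 0.5
    iv_push_prob: float = 0.1
    humalog_prob: float = 0.1

    # treatment delay: reading -> administration (lognormal, minutes)
    admin_delay_median_minutes: float = 10.0
    admin_delay_sigma: float = 0.35
    admin_delay_max_minutes: Optional[float] = 30.0

    # artefact rates
    charting_delay_prob: float = 0.084
    charting_delay_median_minutes: float = 25.0
    charting_delay_sigma: float = 0.6
    duplicate_rate: float = 0.05
    error_rate: float = 0.01
    zero_rate: float = 0.005
    null_rate: float = 0.01
    ceiling_rate: float = 0.002
    rewritten_rate: float = 0.03
    outlier_dose_rate: float = 0.005
    rate_missing_rate: float = 0.05

    @field_validator("n_stays")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_stays must be >= 0")
        return v

    @field_validator("charting_delay_prob", "duplicate_rate", "error_rate",
                     "zero_rate", "null_rate", "ceiling_rate",
                     "rewritten_rate", "outlier_dose_rate",
                     "rate_missing_rate", "infusion_stay_fraction",
                     "basal_fraction", "bundle_prob", "iv_push_prob",
                     "humalog_prob", "meal_bump_prob")
    @classmethod
    def _rate(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        return v

    def without_artifacts(self) -> "SimConfig":
        """Copy with every artefact rate (incl. charting delay) at zero."""
        return self.model_copy(update={
            "charting_delay_prob": 0.0, "duplicate_rate": 0.0,
            "error_rate": 0.0, "zero_rate": 0.0, "null_rate": 0.0,
            "ceiling_rate": 0.0, "rewritten_rate": 0.0,
            "outlier_dose_rate": 0.0, "rate_missing_rate": 0.0})


@dataclass
class SimTables:
    """The four event tables plus the ground-truth ledger."""

    chartevents: pd.DataFrame
    labevents: pd.DataFrame
    inputevents: pd.DataFrame
    icustays: pd.DataFrame
    links: pd.DataFrame      # insulin row -> triggering glucose row
    artifacts: pd.DataFrame  # itemised corruptions/injections

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in [("CHARTEVENTS", self.chartevents),
                         ("LABEVENTS", self.labevents),
                         ("INPUTEVENTS_MV", self.inputevents),
                         ("ICUSTAYS", self.icustays)]:
            df.to_csv(out / f"{name}.csv", index=False,
                      float_format="%.10g", date_format=_TS)
        self.links.to_json(out / "truth_links.jsonl", orient="records",
                           lines=True, date_format="iso")
        self.artifacts.to_json(out / "truth_artifacts.jsonl",
                               orient="records", lines=True)


def _round_min(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor("min")


def _band(bands, value: float):
    for lo, hi, dose in bands:
        if lo <= value < hi:
            return lo, hi, dose
    return None


def _lognormal_minutes(rng: np.random.Generator, median: float,
                       sigma: float) -> float:
    return float(rng.lognormal(mean=math.log(median), sigma=sigma))


def _generate_clean(config: SimConfig, rng: np.random.Generator) -> SimTables:
    chart_rows: List[dict] = []
    lab_rows: List[dict] = []
    input_rows: List[dict] = []
    stay_rows: List[dict] = []
    link_rows: List[dict] = []

    chart_id = _CHART_BASE
    lab_id = _LAB_BASE
    input_id = _INPUT_BASE
    start = pd.Timestamp(config.start_date)
    spacing = pd.Timedelta(minutes=config.min_reading_spacing_minutes)

    def draw_delay() -> pd.Timedelta:
        d = _lognormal_minutes(rng, config.admin_delay_median_minutes,
                               config.admin_delay_sigma)
        if config.admin_delay_max_minutes is not None:
            d = min(d, config.admin_delay_max_minutes)
        return pd.Timedelta(minutes=round(d))

    for i in range(config.n_stays):
        subject = 10_000 + i
        hadm = 20_000 + i
        icustay = 30_000 + i
        in_time = _round_min(start + pd.Timedelta(
            minutes=float(rng.uniform(0, 60 * 24 * 60))))
        los = max(config.los_days_min,
                  float(rng.lognormal(math.log(config.los_days_median),
                                      config.los_days_sigma)))
        out_time = _round_min(in_time + pd.Timedelta(days=los))
        stay_rows.append({
            "ROW_ID": i + 1, "SUBJECT_ID": subject, "HADM_ID": hadm,
            "ICUSTAY_ID": icustay, "INTIME": in_time, "OUTTIME": out_time,
            "LOS": (out_time - in_time) / pd.Timedelta(days=1),
        })

        # jittered schedules for both methods, then enforce minimum spacing
        sched: List[Tuple[pd.Timestamp, str]] = []
        horizon = out_time - pd.Timedelta(minutes=120)
        t = in_time + pd.Timedelta(minutes=float(rng.uniform(20, 60)))
        while t <= horizon:
            sched.append((_round_min(t), "fs"))
            t += pd.Timedelta(minutes=config.fingerstick_interval_minutes
                              + float(rng.uniform(
                                  -config.schedule_jitter_minutes,
                                  config.schedule_jitter_minutes)))
        t = in_time + pd.Timedelta(minutes=float(rng.uniform(60, 240)))
        while t <= horizon:
            sched.append((_round_min(t), "lab"))
            t += pd.Timedelta(minutes=config.lab_interval_minutes
                              + float(rng.uniform(
                                  -config.schedule_jitter_minutes,
                                  config.schedule_jitter_minutes)))
        sched.sort(key=lambda x: (x[0], 0 if x[1] == "fs" else 1))
        kept: List[Tuple[pd.Timestamp, str]] = []
        for tt, src in sched:
            if not kept or tt - kept[-1][0] >= spacing:
                kept.append((tt, src))

        infusion_managed = bool(rng.random() < config.infusion_stay_fraction)
        has_basal = bool(rng.random() < config.basal_fraction)
        basal_item = 223260 if rng.random() < 0.7 else 223259
        infusion_running = False
        last_basal_day = None
        g = config.glucose_setpoint + float(rng.normal(0,
                                                       config.glucose_noise_sd))
        pending_drop = 0.0

        for tt, src in kept:
            g = (config.glucose_setpoint
                 + config.glucose_autocorr * (g - config.glucose_setpoint)
                 - pending_drop
                 + float(rng.normal(0, config.glucose_noise_sd)))
            if rng.random() < config.meal_bump_prob:
                g += float(rng.exponential(config.meal_bump_mean))
            g = float(np.clip(g, 45.0, 540.0))
            pending_drop = 0.0

            if src == "fs":
                val = float(np.clip(round(g + config.fingerstick_bias
                                          + rng.normal(0,
                                                       config.fingerstick_sd)),
                                    40.0, 499.0))
                glc_row_id = chart_id
                chart_rows.append({
                    "ROW_ID": chart_id, "SUBJECT_ID": subject,
                    "HADM_ID": hadm, "ICUSTAY_ID": icustay,
                    "ITEMID": 225664 if rng.random() < 0.9 else 807,
                    "CHARTTIME": tt, "STORETIME": tt, "VALUENUM": val,
                    "VALUEUOM": "mg/dL", "ERROR": 0,
                })
                chart_id += 1
            else:
                val = float(np.clip(round(g + rng.normal(0, config.lab_sd)),
                                    40.0, 950.0))
                glc_row_id = lab_id
                lab_rows.append({
                    "ROW_ID": lab_id, "SUBJECT_ID": subject, "HADM_ID": hadm,
                    "ITEMID": 50931 if rng.random() < 0.7 else 50809,
                    "CHARTTIME": tt, "VALUENUM": val, "VALUEUOM": "mg/dL",
                })
                lab_id += 1
                continue  # only bedside checks drive the protocol

            def emit_input(t_adm: pd.Timestamp, item: int, kind: str,
                           dose: Optional[float], rate: Optional[float],
                           band: Tuple[float, float], link_kind: str,
                           stopped: bool = False) -> None:
                nonlocal input_id
                end = None
                amount = dose
                if kind == "Continuous IV":
                    end = min(_round_min(t_adm + pd.Timedelta(hours=1)),
                              out_time)
                    hours = (end - t_adm) / pd.Timedelta(hours=1)
                    amount = rate * hours if hours > 0 else None
                input_rows.append({
                    "ROW_ID": input_id, "SUBJECT_ID": subject,
                    "HADM_ID": hadm, "ICUSTAY_ID": icustay,
                    "STARTTIME": t_adm, "ENDTIME": end, "ITEMID": item,
                    "AMOUNT": amount, "AMOUNTUOM": "U", "RATE": rate,
                    "RATEUOM": "units/hour" if rate is not None else None,
                    "ORIGINALRATE": rate,
                    "ORDERCATEGORYDESCRIPTION": kind,
                    "STATUSDESCRIPTION": "Stopped" if stopped
                                          else "FinishedRunning",
                })
                link_rows.append({
                    "INPUT_ROW_ID": input_id, "GLC_ROW_ID": glc_row_id,
                    "GLC_TABLE": "chart", "ICUSTAY_ID": icustay,
                    "SUBJECT_ID": subject,
                    "TRUE_GAP_MINUTES": (t_adm - tt)
                                        / pd.Timedelta(minutes=1),
                    "BAND_LO": band[0], "BAND_HI": band[1],
                    "KIND": link_kind,
                })
                input_id += 1

            # sliding scale on the bedside value
            if infusion_managed:
                band = _band(config.infusion_bands, val)
                if band is not None:
                    t_adm = _round_min(tt + draw_delay())
                    if t_adm <= out_time:
                        lo, hi, rate = band
                        if (not infusion_running
                                and rng.random() < config.bundle_prob):
                            b_band = _band(config.bolus_bands, val) \
                                or (lo, hi, 2.0)
                            emit_input(t_adm, 223258, "Bolus", b_band[2],
                                       None, (b_band[0], b_band[1]),
                                       "bundle_bolus")
                            t_inf = _round_min(
                                t_adm + pd.Timedelta(
                                    minutes=float(rng.uniform(2, 6))))
                            if t_inf <= out_time:
                                emit_input(t_inf, 223258, "Continuous IV",
                                           None, rate, (lo, hi),
                                           "bundle_infusion")
                                infusion_running = True
                        else:
                            emit_input(t_adm, 223258, "Continuous IV", None,
                                       rate, (lo, hi),
                                       "infusion_start" if not
                                       infusion_running else "rate_change")
                            infusion_running = True
                        pending_drop = min(
                            70.0, config.insulin_effect_per_unit * rate * 1.5)
                else:
                    infusion_running = False
            else:
                band = _band(config.bolus_bands, val)
                if band is not None:
                    t_adm = _round_min(tt + draw_delay())
                    if t_adm <= out_time:
                        lo, hi, dose = band
                        item = (223262 if rng.random() < config.humalog_prob
                                else 223258)
                        kind = ("Drug Push"
                                if rng.random() < config.iv_push_prob
                                else "Bolus")
                        emit_input(t_adm, item, kind, dose, None, (lo, hi),
                                   "bolus")
                        pending_drop = min(
                            70.0, config.insulin_effect_per_unit * dose)

            # daily basal dose, adjusted to the first qualifying check of
            # the day
            if has_basal and val >= config.basal_threshold \
                    and tt.date() != last_basal_day:
                t_adm = _round_min(tt + draw_delay())
                if t_adm <= out_time:
                    emit_input(t_adm, basal_item, "Bolus",
                               float(rng.integers(10, 31)), None,
                               (config.basal_threshold, math.inf), "basal")
                    last_basal_day = tt.date()
                    pending_drop += 10.0

    chart = pd.DataFrame(chart_rows, columns=CHARTEVENTS_COLUMNS)
    lab = pd.DataFrame(lab_rows, columns=LABEVENTS_COLUMNS)
    inputs = pd.DataFrame(input_rows, columns=INPUTEVENTS_COLUMNS)
    stays = pd.DataFrame(stay_rows, columns=ICUSTAYS_COLUMNS)
    links = pd.DataFrame(link_rows, columns=LINK_COLUMNS)
    artifacts = pd.DataFrame(columns=ARTIFACT_COLUMNS)
    return SimTables(chart, lab, inputs, stays, links, artifacts)


def inject_artifacts(tables: SimTables, config: SimConfig,
                     rng: Optional[np.random.Generator] = None) -> SimTables:
    """Corrupt clean tables at the configured rates; itemise in the ledger.

    Each corruption targets a distinct row (types are applied in a fixed
    order and never stack), so expected post-curation row sets follow from
    the ledger by subtraction. Injected duplicate rows are brand-new rows
    and are expected to vanish during curation. With all rates zero the
    tables are returned unchanged (modulo a copy).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    chart = tables.chartevents.copy()
    lab = tables.labevents.copy()
    inputs = tables.inputevents.copy()
    art_rows: List[dict] = []
    used: set = set()

    def sample(pool_index, table: str, rate: float) -> List:
        avail = [ix for ix in pool_index if (table, ix) not in used]
        picked = [ix for ix in avail if rng.random() < rate]
        used.update((table, ix) for ix in picked)
        return picked

    # cross-table duplicates: lab results also charted as "Glucose (serum)"
    next_chart_id = (int(chart["ROW_ID"].max()) + 1) if len(chart) \
        else _CHART_BASE
    dup_rows = []
    for ix in sample(lab.index, "lab", config.duplicate_rate):
        src = lab.loc[ix]
        dup_rows.append({
            "ROW_ID": next_chart_id, "SUBJECT_ID": src["SUBJECT_ID"],
            "HADM_ID": src["HADM_ID"], "ICUSTAY_ID": pd.NA,
            "ITEMID": 220621, "CHARTTIME": src["CHARTTIME"],
            "STORETIME": src["CHARTTIME"], "VALUENUM": src["VALUENUM"],
            "VALUEUOM": "mg/dL", "ERROR": 0,
        })
        art_rows.append({"ARTIFACT": "duplicate", "TABLE": "chart",
                         "ROW_ID": next_chart_id, "ROLE": "injected",
                         "RECOVERABLE": True,
                         "ORIGINAL": str(int(src["ROW_ID"]))})
        next_chart_id += 1

    fingerstick_items = {807, 811, 1529, 3744, 225664, 226537}
    fs_pool = chart.index[chart["ITEMID"].isin(fingerstick_items)]
    for ix in sample(fs_pool, "chart", config.ceiling_rate):
        art_rows.append({"ARTIFACT": "ceiling", "TABLE": "chart",
                         "ROW_ID": int(chart.at[ix, "ROW_ID"]),
                         "ROLE": "corrupted", "RECOVERABLE": False,
                         "ORIGINAL": str(chart.at[ix, "VALUENUM"])})
        chart.at[ix, "VALUENUM"] = 500.0

    for ix in sample(chart.index, "chart", config.error_rate):
        art_rows.append({"ARTIFACT": "error_flag", "TABLE": "chart",
                         "ROW_ID": int(chart.at[ix, "ROW_ID"]),
                         "ROLE": "corrupted", "RECOVERABLE": False,
                         "ORIGINAL": str(chart.at[ix, "VALUENUM"])})
        chart.at[ix, "ERROR"] = 1

    for table_name, df in (("chart", chart), ("lab", lab)):
        for ix in sample(df.index, table_name, config.zero_rate):
            art_rows.append({"ARTIFACT": "zero", "TABLE": table_name,
                             "ROW_ID": int(df.at[ix, "ROW_ID"]),
                             "ROLE": "corrupted", "RECOVERABLE": False,
                             "ORIGINAL": str(df.at[ix, "VALUENUM"])})
            df.at[ix, "VALUENUM"] = 0.0
        for ix in sample(df.index, table_name, config.null_rate):
            art_rows.append({"ARTIFACT": "null", "TABLE": table_name,
                             "ROW_ID": int(df.at[ix, "ROW_ID"]),
                             "ROLE": "corrupted", "RECOVERABLE": False,
                             "ORIGINAL": str(df.at[ix, "VALUENUM"])})
            df.at[ix, "VALUENUM"] = np.nan

    # delayed charting: CHARTTIME slips late, STORETIME keeps the true time
    for ix in sample(chart.index, "chart", config.charting_delay_prob):
        true_time = chart.at[ix, "CHARTTIME"]
        delay = max(1.0, _lognormal_minutes(
            rng, config.charting_delay_median_minutes,
            config.charting_delay_sigma))
        chart.at[ix, "CHARTTIME"] = _round_min(
            true_time + pd.Timedelta(minutes=round(delay)))
        chart.at[ix, "STORETIME"] = true_time
        art_rows.append({"ARTIFACT": "charting_delay", "TABLE": "chart",
                         "ROW_ID": int(chart.at[ix, "ROW_ID"]),
                         "ROLE": "corrupted", "RECOVERABLE": True,
                         "ORIGINAL": true_time.strftime(_TS)})

    for ix in sample(inputs.index, "input", config.rewritten_rate):
        art_rows.append({"ARTIFACT": "rewritten", "TABLE": "input",
                         "ROW_ID": int(inputs.at[ix, "ROW_ID"]),
                         "ROLE": "corrupted", "RECOVERABLE": False,
                         "ORIGINAL": str(inputs.at[ix, "STATUSDESCRIPTION"])})
        inputs.at[ix, "STATUSDESCRIPTION"] = "Rewritten"

    short_mask = inputs["ITEMID"].isin([223258, 223262])
    for ix in sample(inputs.index[short_mask], "input",
                     config.outlier_dose_rate):
        if inputs.at[ix, "ORDERCATEGORYDESCRIPTION"] == "Continuous IV":
            art_rows.append({"ARTIFACT": "outlier_rate", "TABLE": "input",
                             "ROW_ID": int(inputs.at[ix, "ROW_ID"]),
                             "ROLE": "corrupted", "RECOVERABLE": False,
                             "ORIGINAL": str(inputs.at[ix, "RATE"])})
            inputs.at[ix, "RATE"] = float(rng.uniform(30.0, 80.0))
            inputs.at[ix, "ORIGINALRATE"] = inputs.at[ix, "RATE"]
        else:
            art_rows.append({"ARTIFACT": "outlier_dose", "TABLE": "input",
                             "ROW_ID": int(inputs.at[ix, "ROW_ID"]),
                             "ROLE": "corrupted", "RECOVERABLE": False,
                             "ORIGINAL": str(inputs.at[ix, "AMOUNT"])})
            inputs.at[ix, "AMOUNT"] = float(rng.uniform(18.0, 90.0))

    inf_mask = inputs["ORDERCATEGORYDESCRIPTION"].eq("Continuous IV")
    for ix in sample(inputs.index[inf_mask], "input",
                     config.rate_missing_rate):
        art_rows.append({"ARTIFACT": "rate_missing", "TABLE": "input",
                         "ROW_ID": int(inputs.at[ix, "ROW_ID"]),
                         "ROLE": "corrupted", "RECOVERABLE": True,
                         "ORIGINAL": str(inputs.at[ix, "RATE"])})
        inputs.at[ix, "RATE"] = np.nan

    if dup_rows:
        chart = pd.concat([chart, pd.DataFrame(dup_rows,
                                               columns=CHARTEVENTS_COLUMNS)],
                          ignore_index=True)
    artifacts = pd.concat(
        [tables.artifacts,
         pd.DataFrame(art_rows, columns=ARTIFACT_COLUMNS)],
        ignore_index=True) if art_rows else tables.artifacts.copy()
    return SimTables(chart, lab, inputs, tables.icustays.copy(),
                     tables.links.copy(), artifacts)


def simulate_cohort(config: SimConfig, out_dir=None) -> SimTables:
    """Generate a cohort (clean process + configured artefacts).

    The seed fully determines the output; writing the same cohort twice
    produces byte-identical files. With ``out_dir`` the four tables and the
    two ledger files are also written to disk.
    """
    rng = np.random.default_rng(config.seed)
    tables = _generate_clean(config, rng)
    tables = inject_artifacts(tables, config, rng)
    if out_dir is not None:
        tables.write(out_dir)
    return tables


# ---------------------------------------------------------------------------
# Closed-form expectations from the ledger

def expected_surviving_row_ids(tables: SimTables) -> Dict[str, set]:
    """Row IDs that ideal curation must retain, from the ledger alone.

    Unrecoverable corruptions and injected rows vanish; glucose readings of
    subjects left without any surviving insulin vanish too (the cohort is
    restricted to insulin recipients).
    """
    art = tables.artifacts
    removed = {(t, int(r)) for t, r, rec, role in
               zip(art["TABLE"], art["ROW_ID"], art["RECOVERABLE"],
                   art["ROLE"])
               if role == "injected" or not rec}

    inputs = tables.inputevents
    surviving_inputs = {int(r) for r in inputs["ROW_ID"]
                        if ("input", int(r)) not in removed}
    survivors = inputs[inputs["ROW_ID"].isin(surviving_inputs)]
    recipients = set(survivors["SUBJECT_ID"].astype(int))

    chart_ok = set()
    for r, s in zip(tables.chartevents["ROW_ID"],
                    tables.chartevents["SUBJECT_ID"]):
        if ("chart", int(r)) not in removed and int(s) in recipients:
            chart_ok.add(int(r))
    lab_ok = set()
    for r, s in zip(tables.labevents["ROW_ID"],
                    tables.labevents["SUBJECT_ID"]):
        if ("lab", int(r)) not in removed and int(s) in recipients:
            lab_ok.add(int(r))
    return {"chart": chart_ok, "lab": lab_ok, "input": surviving_inputs}


def pairing_recovery(pairs: pd.DataFrame, links: pd.DataFrame
                     ) -> pd.DataFrame:
    """Join alignment output against the ground-truth trigger links.

    One row per ledger link whose insulin event appears in ``pairs``:
    whether the event was paired, via which rule, whether the paired reading
    is the true trigger, and the link's true reading-to-administration gap.
    """
    merged = links.merge(
        pairs[["event_row_id", "rule", "glc_row_id"]],
        left_on="INPUT_ROW_ID", right_on="event_row_id", how="inner")
    merged["paired"] = merged["rule"].notna()
    merged["recovered"] = merged["paired"] & (
        merged["glc_row_id"].astype("Float64")
        == merged["GLC_ROW_ID"].astype("Float64"))
    return merged[["INPUT_ROW_ID", "GLC_ROW_ID", "KIND", "TRUE_GAP_MINUTES",
                   "paired", "rule", "glc_row_id", "recovered"]]
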
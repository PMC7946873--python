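"""Literal brute-force reference for the alignment rules.

Independent of the package's vectorised implementation: plain Python loops
that transcribe rules 1-5, rule-4 bundling and the documented tie-breaks
directly, enumerating every (insulin event, glucose reading) combination.
Used as the oracle in equivalence tests and by the acceptance script.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

BOLUS_KINDS = ("BOLUS_INYECTION", "BOLUS_PUSH")


def _tie_break(cands):
    """Among readings at one timestamp: higher value, LAB origin, low id."""
    return sorted(cands, key=lambda r: (-r["value"],
                                        0 if r["origin_table"] == "LAB" else 1,
                                        r["row_id"]))[0]


def _preceding(readings, t, window_min, floor):
    elig = [r for r in readings
            if r["value"] >= floor and r["effective_time"] <= t
            and (t - r["effective_time"]) <= pd.Timedelta(minutes=window_min)]
    if not elig:
        return None
    latest = max(r["effective_time"] for r in elig)
    return _tie_break([r for r in elig if r["effective_time"] == latest])


def _following(readings, t, window_min, floor):
    elig = [r for r in readings
            if r["value"] >= floor and r["effective_time"] > t
            and (r["effective_time"] - t) <= pd.Timedelta(minutes=window_min)]
    if not elig:
        return None
    earliest = min(r["effective_time"] for r in elig)
    return _tie_break([r for r in elig if r["effective_time"] == earliest])


def _choose(prec, foll):
    if prec is not None and foll is not None:
        return (foll, 3) if foll["value"] > prec["value"] else (prec, 3)
    if prec is not None:
        return prec, 1
    if foll is not None:
        return foll, 2
    return None, None


def brute_force_pairs(events: pd.DataFrame, readings: pd.DataFrame,
                      stays: pd.DataFrame, window_min: float = 90.0,
                      floor: float = 90.0, bundle_gap_min: float = 15.0
                      ) -> Dict[int, Tuple[Optional[int], Optional[int]]]:
    """Map event row_id -> (paired reading row_id or None, rule or None).

    Only events starting inside their own ICU stay appear as keys; readings
    are assigned to stays by subject and time window.
    """
    stay_info = {int(s["icustay_id"]): s for _, s in stays.iterrows()}
    out: Dict[int, Tuple[Optional[int], Optional[int]]] = {}

    for stay_id, stay in stay_info.items():
        evs = []
        for _, e in events.iterrows():
            if pd.isna(e["icustay_id"]) or int(e["icustay_id"]) != stay_id:
                continue
            if stay["in_time"] <= e["start_time"] <= stay["out_time"]:
                evs.append(dict(e))
        rds = []
        for _, r in readings.iterrows():
            if r["subject_id"] != stay["subject_id"]:
                continue
            if stay["in_time"] <= r["effective_time"] <= stay["out_time"]:
                rds.append(dict(r))

        # rule-4 bundles: chronological boluses grab the nearest free
        # short-acting infusion within the bundle gap
        taken = set()
        bundles = {}  # event row_id -> anchor time
        for b in sorted([e for e in evs if e["acting_type"] == "SHORT"
                         and e["event_kind"] in BOLUS_KINDS],
                        key=lambda e: (e["start_time"], e["row_id"])):
            best = None
            for inf in sorted([e for e in evs if e["acting_type"] == "SHORT"
                               and e["event_kind"] == "INFUSION"],
                              key=lambda e: (abs(e["start_time"]
                                                 - b["start_time"]),
                                             e["start_time"], e["row_id"])):
                if inf["row_id"] in taken:
                    continue
                if abs(inf["start_time"] - b["start_time"]) \
                        <= pd.Timedelta(minutes=bundle_gap_min):
                    best = inf
                break  # candidates are sorted: the first free one decides
            if best is not None:
                taken.add(best["row_id"])
                anchor = min(b["start_time"], best["start_time"])
                bundles[b["row_id"]] = anchor
                bundles[best["row_id"]] = anchor

        for e in evs:
            if e["row_id"] in bundles:
                anchor = bundles[e["row_id"]]
                reading, rule = _choose(
                    _preceding(rds, anchor, window_min, floor),
                    _following(rds, anchor, window_min, floor))
                if rule is not None:
                    rule = 4
            else:
                reading, rule = _choose(
                    _preceding(rds, e["start_time"], window_min, floor),
                    _following(rds, e["start_time"], window_min, floor))
            out[int(e["row_id"])] = (
                int(reading["row_id"]) if reading is not None else None, rule)
    return out


# ---------------------------------------------------------------------------
# random micro-instances

_T0 = pd.Timestamp("2130-01-01 00:00:00")


def random_micro_instance(rng: np.random.Generator):
    """One random single-stay instance with <= 20 events.

    Times land on a 5-minute grid over 48 h so that boundary gaps (exactly
    the window), identical timestamps and floor-value readings all occur
    with non-trivial probability; some events fall outside the stay.
    """
    in_time = _T0
    out_time = _T0 + pd.Timedelta(minutes=2880)
    n_read = int(rng.integers(0, 13))
    n_ev = int(rng.integers(1, 9))

    values = rng.choice([85.0, 88.0, 90.0, 95.0, 120.0, 140.0, 140.0,
                         180.0, 200.0, 320.0], size=n_read)
    r_minutes = rng.choice(np.arange(0, 2881, 5), size=n_read)
    readings = pd.DataFrame({
        "row_id": np.arange(1, n_read + 1, dtype=np.int64),
        "subject_id": 1, "hadm_id": 1,
        "icustay_id": pd.array([1] * n_read, dtype="Int64"),
        "item_id": 225664,
        "chart_time": [in_time + pd.Timedelta(minutes=int(m))
                       for m in r_minutes],
        "store_time": pd.NaT,
        "value": values,
        "error_flag": False,
        "origin_table": rng.choice(["CHART", "LAB"], size=n_read),
    })
    readings["source"] = np.where(readings["origin_table"] == "LAB",
                                  "BLOOD", "FINGERSTICK")
    readings["effective_time"] = readings["chart_time"]

    kinds = [("SHORT", "BOLUS_INYECTION"), ("SHORT", "BOLUS_PUSH"),
             ("SHORT", "INFUSION"), ("INTERMEDIATE", "BOLUS_INYECTION"),
             ("LONG", "BOLUS_INYECTION")]
    rows = []
    minute_pool = np.arange(-60, 3001, 5)  # includes out-of-stay times
    for j in range(n_ev):
        act, kind = kinds[int(rng.integers(0, len(kinds)))]
        if rows and rng.random() < 0.35:
            # place near the previous event to provoke rule-4 bundles
            m = rows[-1]["_m"] + int(rng.integers(0, 5)) * 5
            act, kind = "SHORT", ("INFUSION" if rows[-1]["kind"] != "INFUSION"
                                  else "BOLUS_INYECTION")
        else:
            m = int(rng.choice(minute_pool))
        rows.append({"_m": m, "act": act, "kind": kind})
    events = pd.DataFrame({
        "row_id": np.arange(101, 101 + n_ev, dtype=np.int64),
        "subject_id": 1, "hadm_id": 1,
        "icustay_id": pd.array([1] * n_ev, dtype="Int64"),
        "item_id": 223258,
        "start_time": [in_time + pd.Timedelta(minutes=r["_m"]) for r in rows],
        "end_time": pd.NaT,
        "dose": [np.nan if r["kind"] == "INFUSION" else 4.0 for r in rows],
        "rate": [3.0 if r["kind"] == "INFUSION" else np.nan for r in rows],
        "original_rate": np.nan,
        "acting_type": [r["act"] for r in rows],
        "event_kind": [r["kind"] for r in rows],
        "infusion_stop": False,
        "rewritten": False,
    })
    stays = pd.DataFrame({
        "icustay_id": [1], "hadm_id": [1], "subject_id": [1],
        "in_time": [in_time], "out_time": [out_time],
        "los_days": [2.0], "first_icu_stay": [True],
    })
    return events, readings, stays
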
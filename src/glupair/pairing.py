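"""Rule-based alignment of insulin events to triggering glucose readings.

Each curated insulin administration inside an ICU stay is linked to the
glucose reading that plausibly triggered it, using five clinically derived
rules:

1. a reading preceding the event by up to the window (default 90 min);
2. else a reading following the event within the window;
3. when the event sits between two in-window readings, the higher wins;
4. a short-acting bolus immediately followed (or preceded) by a short-acting
   infusion start is one clinical action: both members receive the same
   reading, selected as in rule 3 relative to the earlier member;
5. readings below the floor (default 90 mg/dL) are never paired - no
   clinician treats hypoglycemia with regular insulin.

Rule evaluation order: bundles (4) are detected first; for every remaining
event the straddle comparison (3) subsumes precede (1) and follow (2); the
floor (5) is an eligibility filter on all candidates. Window comparisons are
inclusive at the boundary. Deterministic tie-breaks: equal-value straddle
candidates resolve to the preceding reading; among readings at the identical
timestamp the higher value wins, then the LAB-origin row, then the lowest
row_id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import (BOLUS_INYECTION, BOLUS_PUSH, INFUSION, LAB,
                     PairingParams, SHORT)
from .io_mimic import assign_stays, restrict_events_to_stay

PRECEDING = "PRECEDING"
FOLLOWING = "FOLLOWING"


class _ReadingIndex:
    """Floor-filtered, tie-break-aware view of one stay's readings."""

    def __init__(self, readings: pd.DataFrame, floor: float):
        elig = readings[readings["value"] >= floor]
        self.times = elig["effective_time"].to_numpy(dtype="datetime64[ns]")
        self.values = elig["value"].to_numpy(dtype=float)
        self.row_ids = elig["row_id"].to_numpy(dtype=np.int64)
        self.origins = elig["origin_table"].to_numpy()
        self.sources = elig["source"].to_numpy()
        self.n = len(elig)

    def _best_at(self, mask: np.ndarray, target_time) -> int:
        """Among masked readings at target_time: higher value, LAB, low id."""
        at = np.flatnonzero(mask & (self.times == target_time))
        order = sorted(at, key=lambda i: (-self.values[i],
                                          0 if self.origins[i] == LAB else 1,
                                          self.row_ids[i]))
        return order[0]

    def preceding(self, t: np.datetime64, window: np.timedelta64
                  ) -> Optional[int]:
        """Latest eligible reading at or before ``t`` within the window."""
        mask = (self.times <= t) & (self.times >= t - window)
        if not mask.any():
            return None
        return self._best_at(mask, self.times[mask].max())

    def following(self, t: np.datetime64, window: np.timedelta64
                  ) -> Optional[int]:
        """Earliest eligible reading strictly after ``t`` within the window."""
        mask = (self.times > t) & (self.times <= t + window)
        if not mask.any():
            return None
        return self._best_at(mask, self.times[mask].min())


def select_pair(index: _ReadingIndex, preceding: Optional[int],
                following: Optional[int]) -> Tuple[Optional[int], Optional[int]]:
    """Apply rules 1-3 to the two candidates; returns (reading idx, rule)."""
    if preceding is not None and following is not None:
        # rule 3: higher value wins; the tie goes to the preceding reading,
        # preserving trigger-precedes-treatment semantics
        if index.values[following] > index.values[preceding]:
            return following, 3
        return preceding, 3
    if preceding is not None:
        return preceding, 1
    if following is not None:
        return following, 2
    return None, None


def bundle_bolus_with_infusion(events: pd.DataFrame,
                               params: Optional[PairingParams] = None
                               ) -> Dict[int, int]:
    """Rule 4 detection: match short-acting boluses to infusion starts.

    Returns a map from the frame index of each bundled event to a bundle id.
    Boluses are scanned chronologically; each takes the nearest unbundled
    short-acting infusion event whose start lies within the bundle gap
    (ties: earlier start, then lower row_id).
    """
    params = params or PairingParams()
    gap = pd.Timedelta(minutes=params.bundle_gap_minutes)
    short = events["acting_type"].eq(SHORT)
    boluses = events[short & events["event_kind"]
                     .isin([BOLUS_INYECTION, BOLUS_PUSH])]
    infusions = events[short & events["event_kind"].eq(INFUSION)]
    boluses = boluses.sort_values(["start_time", "row_id"], kind="mergesort")
    taken: set = set()
    bundles: Dict[int, int] = {}
    bundle_id = 0
    for bix, brow in boluses.iterrows():
        cand = infusions[~infusions.index.isin(taken)]
        if cand.empty:
            break
        delta = (cand["start_time"] - brow["start_time"]).abs()
        cand = cand[delta <= gap]
        if cand.empty:
            continue
        delta = delta.loc[cand.index]
        best = cand.assign(_d=delta).sort_values(
            ["_d", "start_time", "row_id"], kind="mergesort").index[0]
        bundles[bix] = bundle_id
        bundles[best] = bundle_id
        taken.add(best)
        bundle_id += 1
    return bundles


@dataclass
class PairingSummary:
    """Table-style overview of the alignment outcome."""

    n_events_input: int
    n_events_in_icu: int
    n_events_excluded: int
    n_paired: int
    rule_counts: Dict[int, int]
    by_group: pd.DataFrame

    @property
    def paired_pct(self) -> float:
        return (100.0 * self.n_paired / self.n_events_in_icu
                if self.n_events_in_icu else 0.0)

    def to_dict(self) -> dict:
        return {
            "n_events_input": self.n_events_input,
            "n_events_in_icu": self.n_events_in_icu,
            "n_events_excluded": self.n_events_excluded,
            "n_paired": self.n_paired,
            "paired_pct": self.paired_pct,
            "rule_counts": {int(k): int(v)
                            for k, v in sorted(self.rule_counts.items())},
            "by_group": self.by_group.to_dict(orient="records"),
        }


PAIR_COLUMNS = [
    "event_row_id", "subject_id", "icustay_id", "start_time", "acting_type",
    "event_kind", "rule", "glc_row_id", "glc_origin", "glc_al",
    "glctimer_al", "glcsource_al", "gap_minutes", "bundled",
]


def pair_events(insulin_events: pd.DataFrame, readings: pd.DataFrame,
                stays: pd.DataFrame,
                params: Optional[PairingParams] = None
                ) -> Tuple[pd.DataFrame, PairingSummary]:
    """Align every in-ICU insulin event to its triggering glucose reading.

    Both streams are first restricted to their ICU stay windows (criterion
    L). Within each stay, rule-4 bundles are detected, then every event (or
    bundle) selects a reading via rules 1-3 with rule 5 as the floor filter.

    Returns one row per in-ICU insulin event (paired or not) plus a
    :class:`PairingSummary`.
    """
    params = params or PairingParams()
    window = np.timedelta64(int(params.window_minutes * 60), "s")

    readings = assign_stays(readings, stays)
    readings = readings[readings["icustay_id"].notna()]
    n_input = len(insulin_events)
    events = restrict_events_to_stay(insulin_events, stays)
    events = events.sort_values(["icustay_id", "start_time", "row_id"],
                                kind="mergesort").reset_index(drop=True)

    readings_by_stay = dict(tuple(readings.groupby("icustay_id")))
    rows = []
    for stay_id, ev in events.groupby("icustay_id", sort=False):
        stay_readings = readings_by_stay.get(stay_id)
        index = _ReadingIndex(
            stay_readings if stay_readings is not None
            else readings.iloc[0:0], params.glucose_floor)
        bundles = bundle_bolus_with_infusion(ev, params)
        # bundle id -> (anchor time, latest member start)
        anchors: Dict[int, Tuple[np.datetime64, np.datetime64]] = {}
        for bid in set(bundles.values()):
            starts = ev.loc[[ix for ix, b in bundles.items() if b == bid],
                            "start_time"]
            anchors[bid] = (starts.min().to_datetime64(),
                            starts.max().to_datetime64())
        for ix, event in ev.iterrows():
            t = event["start_time"].to_datetime64()
            if ix in bundles:
                anchor, _latest = anchors[bundles[ix]]
                prec = index.preceding(anchor, window)
                foll = index.following(anchor, window)
                ridx, rule = select_pair(index, prec, foll)
                if rule is not None:
                    rule = 4
            else:
                prec = index.preceding(t, window)
                foll = index.following(t, window)
                ridx, rule = select_pair(index, prec, foll)
            if ridx is None:
                rows.append((event["row_id"], event["subject_id"], stay_id,
                             event["start_time"], event["acting_type"],
                             event["event_kind"], pd.NA, pd.NA, np.nan,
                             np.nan, pd.NaT, np.nan, np.nan, ix in bundles))
            else:
                gap = abs(pd.Timestamp(index.times[ridx])
                          - event["start_time"]) / pd.Timedelta(minutes=1)
                rows.append((event["row_id"], event["subject_id"], stay_id,
                             event["start_time"], event["acting_type"],
                             event["event_kind"], rule,
                             int(index.row_ids[ridx]), index.origins[ridx],
                             index.values[ridx],
                             pd.Timestamp(index.times[ridx]),
                             index.sources[ridx], float(gap),
                             ix in bundles))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs["rule"] = pd.array(pairs["rule"], dtype="Int64")
    pairs["glc_row_id"] = pd.array(pairs["glc_row_id"], dtype="Int64")

    rule_counts = pairs["rule"].value_counts().to_dict()
    admin = np.where(pairs["event_kind"].eq(INFUSION), "INFUSION", "BOLUS")
    grp_pairs = pairs.assign(_admin=admin)
    ev_admin = np.where(events["event_kind"].eq(INFUSION), "INFUSION", "BOLUS")
    all_admin = np.where(insulin_events["event_kind"].eq(INFUSION),
                         "INFUSION", "BOLUS")
    groups = []
    for (adm, act), g in grp_pairs.groupby(["_admin", "acting_type"]):
        in_all = insulin_events[(all_admin == adm)
                                & insulin_events["acting_type"].eq(act)]
        paired = int(g["rule"].notna().sum())
        groups.append({
            "administration": adm, "acting_type": act,
            "patients": int(in_all["subject_id"].nunique()),
            "inputs": len(in_all), "inputs_icu": len(g), "paired": paired,
            "not_paired": len(g) - paired,
            "not_paired_pct": 100.0 * (len(g) - paired) / len(g) if len(g)
                              else 0.0,
        })
    by_group = pd.DataFrame(groups)
    summary = PairingSummary(
        n_events_input=n_input,
        n_events_in_icu=len(pairs),
        n_events_excluded=n_input - len(pairs),
        n_paired=int(pairs["rule"].notna().sum()),
        rule_counts={int(k): int(v) for k, v in rule_counts.items()},
        by_group=by_group,
    )
    return pairs, summary


def align_single_event(readings: pd.DataFrame, t: pd.Timestamp,
                       window_minutes: float, glucose_floor: float
                       ) -> Optional[dict]:
    """Rules 1/2/3/5 for one event time against one stay's readings.

    Used by the scenario-comparison assay, where events are evaluated one at
    a time without bundle detection. Returns None when no rule fires.
    """
    index = _ReadingIndex(readings, glucose_floor)
    window = np.timedelta64(int(window_minutes * 60), "s")
    t64 = pd.Timestamp(t).to_datetime64()
    ridx, rule = select_pair(index, index.preceding(t64, window),
                             index.following(t64, window))
    if ridx is None:
        return None
    return {
        "row_id": int(index.row_ids[ridx]),
        "value": float(index.values[ridx]),
        "time": pd.Timestamp(index.times[ridx]),
        "rule": rule,
        "gap_minutes": float(abs(pd.Timestamp(index.times[ridx])
                                 - pd.Timestamp(t))
                             / pd.Timedelta(minutes=1)),
    }


def nearest_preceding(readings: pd.DataFrame, t: pd.Timestamp
                      ) -> Optional[dict]:
    """Scenario-C pairing: nearest preceding reading, no window, no floor."""
    times = readings["effective_time"].to_numpy(dtype="datetime64[ns]")
    t64 = pd.Timestamp(t).to_datetime64()
    mask = times <= t64
    if not mask.any():
        return None
    target = times[mask].max()
    at = readings[(times == target)]
    at = at.sort_values(["value", "row_id"],
                        ascending=[False, True], kind="mergesort")
    row = at.iloc[0]
    # LAB wins among equal-value rows at the identical timestamp
    top = at[at["value"] == row["value"]]
    lab = top[top["origin_table"] == LAB]
    row = lab.iloc[0] if len(lab) else row
    return {
        "row_id": int(row["row_id"]),
        "value": float(row["value"]),
        "time": pd.Timestamp(row["effective_time"]),
        "gap_minutes": float((pd.Timestamp(t)
                              - pd.Timestamp(row["effective_time"]))
                             / pd.Timedelta(minutes=1)),
    }
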
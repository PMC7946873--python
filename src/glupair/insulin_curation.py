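"""Inclusion criteria G-K for MetaVision insulin administrations.

Rewritten (never-delivered) entries and events charted outside any ICU stay
are removed; missing infusion rates are carried forward from the charted
ORIGINALRATE; and dose/rate outliers above the 99th-percentile caps are
dropped along with non-positive values.

Cap boundaries are deliberately asymmetric: short-acting bolus doses are
kept strictly below 18.0 U (the retained maximum is 17.0 U), while infusion
rates are kept up to and including 29.8 U/hr (the retained maximum). The
18.0 U cap applies to short-acting boluses only; intermediate- and
long-acting boluses legitimately reach 180 U and are filtered only for
non-positive values.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .config import (BOLUS_INYECTION, BOLUS_PUSH, CurationConfig, INFUSION,
                     SHORT)
from .report import CurationReport


def drop_rewritten(events: pd.DataFrame,
                   report: Optional[CurationReport] = None) -> pd.DataFrame:
    """Criterion G: remove rewritten entries (inputs never delivered)."""
    keep = ~events["rewritten"].astype(bool)
    if report is not None:
        report.add("G", "rewritten entries removed", len(events),
                   int((~keep).sum()))
    return events[keep].reset_index(drop=True)


def drop_unassigned_stay(events: pd.DataFrame,
                         report: Optional[CurationReport] = None
                         ) -> pd.DataFrame:
    """Criterion H: remove events with a blank/null ICU stay ID."""
    keep = events["icustay_id"].notna()
    if report is not None:
        report.add("H", "events without an ICU stay ID removed", len(events),
                   int((~keep).sum()))
    return events[keep].reset_index(drop=True)


def impute_infusion_rate(events: pd.DataFrame) -> pd.DataFrame:
    """Criterion I (carry-forward): fill missing infusion rates.

    A missing rate on an infusion row means the rate has not changed since
    the previous charted input, which MetaVision keeps in ORIGINALRATE.
    """
    out = events.copy()
    is_inf = out["event_kind"].eq(INFUSION)
    fill = is_inf & out["rate"].isna() & out["original_rate"].notna()
    out.loc[fill, "rate"] = out.loc[fill, "original_rate"]
    return out


def filter_dose_outliers(events: pd.DataFrame,
                         config: Optional[CurationConfig] = None,
                         report: Optional[CurationReport] = None
                         ) -> pd.DataFrame:
    """Criteria I/J/K: drop non-positive and above-cap doses and rates.

    - infusions (criterion I): kept iff 0 < rate <= infusion cap
    - short-acting boluses (criterion J): kept iff 0 < dose < bolus cap
    - other boluses (criterion K): kept iff dose > 0

    With ``config.recompute_caps`` the caps are re-estimated as the
    configured percentile (default 99th) of the positive doses/rates in the
    input, instead of the published constants.
    """
    config = config or CurationConfig()
    is_inf = events["event_kind"].eq(INFUSION)
    is_short_bolus = events["event_kind"].isin([BOLUS_INYECTION, BOLUS_PUSH]) \
        & events["acting_type"].eq(SHORT)

    bolus_cap, infusion_cap = config.bolus_cap, config.infusion_cap
    if config.recompute_caps:
        doses = events.loc[is_short_bolus, "dose"]
        doses = doses[doses > 0]
        if len(doses):
            bolus_cap = float(np.percentile(doses, config.cap_percentile))
        rates = events.loc[is_inf, "rate"]
        rates = rates[rates > 0]
        if len(rates):
            infusion_cap = float(np.percentile(rates, config.cap_percentile))

    keep_inf = is_inf & (events["rate"] > 0) & (events["rate"] <= infusion_cap)
    keep_short = is_short_bolus & (events["dose"] > 0) \
        & (events["dose"] < bolus_cap)
    keep_other = ~is_inf & ~is_short_bolus & (events["dose"] > 0)
    keep = keep_inf | keep_short | keep_other

    if report is not None:
        n_i = int((is_inf & ~keep).sum())
        n_j = int((is_short_bolus & ~keep).sum())
        n_k = int((~is_inf & ~is_short_bolus & ~keep).sum())
        report.add("I", "infusions with non-positive or above-cap rate "
                        "removed", len(events), n_i)
        report.add("J", "short-acting boluses with non-positive or above-cap "
                        "dose removed", len(events) - n_i, n_j)
        report.add("K", "other boluses with non-positive dose removed",
                   len(events) - n_i - n_j, n_k)
        report.extras["bolus_cap"] = float(bolus_cap)
        report.extras["infusion_cap"] = float(infusion_cap)
    return events[keep].reset_index(drop=True)


def infusion_amount(rate: Union[float, np.ndarray], start, end
                    ) -> Union[float, np.ndarray]:
    """Amount of insulin (U) delivered at ``rate`` (U/hr) over [start, end).

    Raises ValueError on non-positive durations or rates: an infusion row
    with no time span delivers nothing and indicates a charting problem
    upstream.
    """
    hours = (pd.to_datetime(end) - pd.to_datetime(start)) \
        / pd.Timedelta(hours=1)
    hours = np.asarray(hours, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(hours <= 0):
        raise ValueError("infusion interval must have positive duration")
    if np.any(rate <= 0):
        raise ValueError("infusion rate must be positive")
    out = rate * hours
    return float(out) if out.ndim == 0 else out


def curate_insulin(raw_events: pd.DataFrame,
                   config: Optional[CurationConfig] = None
                   ) -> Tuple[pd.DataFrame, CurationReport]:
    """Run criteria G -> H -> I/J/K in order with full row accounting."""
    config = config or CurationConfig()
    report = CurationReport(patients_in=int(raw_events["subject_id"]
                                            .nunique()))
    out = drop_rewritten(raw_events, report)
    out = drop_unassigned_stay(out, report)
    out = impute_infusion_rate(out)
    out = filter_dose_outliers(out, config, report)
    report.patients_out = int(out["subject_id"].nunique())
    report.verify()
    return out.reset_index(drop=True), report


def loss_by_item(raw_events: pd.DataFrame, curated_events: pd.DataFrame
                 ) -> pd.DataFrame:
    """Per-item-ID raw/curated counts and percentage loss."""
    raw = raw_events.groupby("item_id").size().rename("raw")
    cur = curated_events.groupby("item_id").size().rename("curated")
    tab = pd.concat([raw, cur], axis=1).fillna(0).astype(int)
    tab["loss_pct"] = 100.0 * (tab["raw"] - tab["curated"]) / tab["raw"]
    return tab.reset_index()
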
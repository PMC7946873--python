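"""Technical-validation assays for the curated dataset.

Four assays provide evidence that the curation and pairing behave sensibly:

- distribution moments (excess kurtosis, Fisher-Pearson skewness) of the
  curated readings per measurement method;
- fingerstick vs laboratory-analyzer agreement: the first fingerstick of
  each ICU stay is paired with the temporally closest lab result, and
  Bland-Altman statistics are computed per time-gap (Delta-theta) bin,
  with a LOWESS smooth of the difference against the pair mean;
- comparison of pairing scenarios: the first short-acting bolus per stay is
  paired under the full rule set at 90 min (A), at 60 min (B), and with no
  rules at all (C: nearest preceding reading, unbounded, no floor); paired
  Wilcoxon signed-rank tests per Delta-theta bin quantify how much the
  rules change the glucose value attributed to the dose.

Delta glucose is oriented fingerstick minus lab in the agreement assay, and
scenario minus C in the scenario assay. Zero differences are dropped by the
signed-rank test (the classical Wilcoxon convention); bins with no non-zero
differences report p = 1 (no evidence against the null).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import (AgreementConfig, BLOOD, BOLUS_INYECTION, BOLUS_PUSH,
                     FINGERSTICK, SHORT)
from .io_mimic import assign_stays, restrict_events_to_stay
from .pairing import align_single_event, nearest_preceding

AGREEMENT_COLUMNS = [
    "icustay_id", "fingerstick_value", "lab_value", "delta_glucose",
    "delta_theta_minutes", "mean_value",
]


def first_fingerstick_pairs(readings: pd.DataFrame, stays: pd.DataFrame
                            ) -> pd.DataFrame:
    """First fingerstick per ICU stay paired with the closest lab result.

    Stays recording only one method (or no reading at all) contribute no
    pair. The time gap is unsigned: the closest lab draw may precede or
    follow the fingerstick.
    """
    readings = assign_stays(readings, stays)
    readings = readings[readings["icustay_id"].notna()]
    rows = []
    for stay_id, grp in readings.groupby("icustay_id", sort=True):
        fs = grp[grp["source"] == FINGERSTICK]
        lab = grp[grp["source"] == BLOOD]
        if fs.empty or lab.empty:
            continue
        first = fs.sort_values(["effective_time", "row_id"],
                               kind="mergesort").iloc[0]
        gaps = (lab["effective_time"] - first["effective_time"]).abs()
        closest = lab.loc[gaps.sort_values(kind="mergesort").index[0]]
        delta = float(first["value"] - closest["value"])
        rows.append({
            "icustay_id": stay_id,
            "fingerstick_value": float(first["value"]),
            "lab_value": float(closest["value"]),
            "delta_glucose": delta,
            "delta_theta_minutes": float(gaps.min()
                                         / pd.Timedelta(minutes=1)),
            "mean_value": (float(first["value"])
                           + float(closest["value"])) / 2.0,
        })
    return pd.DataFrame(rows, columns=AGREEMENT_COLUMNS)


def _signed_rank_p(delta: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p, zeros dropped; p=1 when degenerate."""
    nz = delta[delta != 0]
    if len(nz) == 0:
        return 1.0
    return float(stats.wilcoxon(nz, zero_method="wilcox",
                                alternative="two-sided").pvalue)


def _bin_labels(edges: Sequence[float]) -> Tuple[np.ndarray, list]:
    edges = list(edges) + [np.inf]
    labels = [f"[{int(a) if float(a).is_integer() else a}, "
              f"{'inf' if np.isinf(b) else int(b) if float(b).is_integer() else b})"
              for a, b in zip(edges[:-1], edges[1:])]
    return np.asarray(edges, dtype=float), labels


def bland_altman(pairs: pd.DataFrame,
                 bin_edges: Sequence[float] = (0, 30, 60, 90, 120),
                 k: float = 1.96) -> pd.DataFrame:
    """Bland-Altman statistics of fingerstick-lab agreement per Δθ bin.

    For each time-gap bin: n, bias (mean Δ), SD, limits of agreement
    bias ± k·SD, median/Q1/Q3 of Δ, and the signed-rank p-value against a
    zero median difference.
    """
    edges, labels = _bin_labels(bin_edges)
    out = []
    which = np.digitize(pairs["delta_theta_minutes"], edges[1:-1], right=False)
    for b, label in enumerate(labels):
        d = pairs.loc[which == b, "delta_glucose"].to_numpy(dtype=float)
        if len(d) == 0:
            out.append({"bin": label, "n": 0, "bias": np.nan, "sd": np.nan,
                        "loa_low": np.nan, "loa_high": np.nan,
                        "median": np.nan, "q1": np.nan, "q3": np.nan,
                        "p_value": np.nan})
            continue
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
        out.append({
            "bin": label, "n": len(d), "bias": bias, "sd": sd,
            "loa_low": bias - k * sd, "loa_high": bias + k * sd,
            "median": float(np.median(d)),
            "q1": float(np.percentile(d, 25)),
            "q3": float(np.percentile(d, 75)),
            "p_value": _signed_rank_p(d),
        })
    return pd.DataFrame(out)


def lowess_delta_curve(pairs: pd.DataFrame, frac: float = 0.3) -> pd.DataFrame:
    """Smoothed Δ glucose as a function of the pair mean.

    The smoothing contract of the Bland-Altman plots: any standard local
    regression qualifies; statsmodels' LOWESS is used.
    """
    sm = lowess(pairs["delta_glucose"].to_numpy(dtype=float),
                pairs["mean_value"].to_numpy(dtype=float), frac=frac,
                return_sorted=True)
    return pd.DataFrame({"mean_value": sm[:, 0], "delta_smooth": sm[:, 1]})


def distribution_summary(readings: pd.DataFrame) -> pd.DataFrame:
    """Moments of the curated glucose distribution per method and combined.

    Skewness is the Fisher-Pearson coefficient; kurtosis is excess kurtosis
    (normal = 0). Degenerate (zero-variance) samples report skewness 0 and
    undefined kurtosis.
    """

    def _row(name: str, v: np.ndarray) -> dict:
        v = np.asarray(v, dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        degenerate = len(v) < 2 or sd == 0.0
        return {
            "group": name, "n": len(v),
            "mean": float(np.mean(v)) if len(v) else np.nan,
            "sd": sd,
            "median": float(np.median(v)) if len(v) else np.nan,
            "excess_kurtosis": (np.nan if degenerate
                                else float(stats.kurtosis(v, fisher=True))),
            "skewness": 0.0 if degenerate else float(stats.skew(v)),
            "min": float(np.min(v)) if len(v) else np.nan,
            "max": float(np.max(v)) if len(v) else np.nan,
        }

    rows = []
    for source in (BLOOD, FINGERSTICK):
        rows.append(_row(source,
                         readings.loc[readings["source"] == source, "value"]
                         .to_numpy()))
    rows.append(_row("COMBINED", readings["value"].to_numpy()))
    return pd.DataFrame(rows)


@dataclass
class ScenarioComparison:
    """Outcome of the A/B/C pairing-scenario assay."""

    per_stay: pd.DataFrame       # one row per stay with a first short bolus
    paired_counts: dict          # scenario -> number of paired first boluses
    tables: dict                 # "A_vs_C"/"B_vs_C" -> per-bin DataFrame
    n_stays: int
    n_excluded: dict             # scenario -> stays excluded from the test

    def to_dict(self) -> dict:
        return {
            "n_stays": self.n_stays,
            "paired_counts": dict(self.paired_counts),
            "n_excluded": dict(self.n_excluded),
            "tables": {k: v.to_dict(orient="records")
                       for k, v in self.tables.items()},
        }


def _scenario_table(per_stay: pd.DataFrame, scen: str,
                    edges: np.ndarray, labels: list) -> pd.DataFrame:
    both = per_stay[per_stay[f"glc_{scen}"].notna()
                    & per_stay["glc_c"].notna()].copy()
    both["delta"] = both[f"glc_{scen}"] - both["glc_c"]
    which = np.digitize(both["theta_c"], edges[1:-1], right=False)
    rows = []
    for b, label in enumerate(labels):
        d = both.loc[which == b, "delta"].to_numpy(dtype=float)
        rows.append({
            "bin": label, "n": len(d),
            "median": float(np.median(d)) if len(d) else np.nan,
            "q1": float(np.percentile(d, 25)) if len(d) else np.nan,
            "q3": float(np.percentile(d, 75)) if len(d) else np.nan,
            "mean": float(np.mean(d)) if len(d) else np.nan,
            "sd": float(np.std(d, ddof=1)) if len(d) > 1 else np.nan,
            "n_zero": int((d == 0).sum()),
            "p_value": _signed_rank_p(d) if len(d) else np.nan,
        })
    return pd.DataFrame(rows)


def compare_scenarios(insulin_events: pd.DataFrame, readings: pd.DataFrame,
                      stays: pd.DataFrame,
                      config: Optional[AgreementConfig] = None
                      ) -> ScenarioComparison:
    """Pair the first short-acting bolus of each stay under scenarios A/B/C.

    A and B apply the alignment rules at 90- and 60-minute windows; C takes
    the nearest preceding reading with no window and no floor. Differences
    (scenario minus C) are binned by Δθ, the gap between the bolus and the
    scenario-C reading, and tested with a paired two-sided signed-rank test.
    Stays where a scenario pairs nothing are excluded from that scenario's
    test and counted in ``n_excluded``.
    """
    config = config or AgreementConfig()
    readings = assign_stays(readings, stays)
    readings = readings[readings["icustay_id"].notna()]
    events = restrict_events_to_stay(insulin_events, stays)
    boluses = events[events["acting_type"].eq(SHORT)
                     & events["event_kind"].isin([BOLUS_INYECTION,
                                                  BOLUS_PUSH])]
    first = (boluses.sort_values(["start_time", "row_id"], kind="mergesort")
             .groupby("icustay_id", sort=True).head(1))

    readings_by_stay = dict(tuple(readings.groupby("icustay_id")))
    rows = []
    for _, ev in first.iterrows():
        grp = readings_by_stay.get(ev["icustay_id"])
        if grp is None:
            grp = readings.iloc[0:0]
        t = ev["start_time"]
        a = align_single_event(grp, t, config.scenario_window_a, 90.0)
        b = align_single_event(grp, t, config.scenario_window_b, 90.0)
        c = nearest_preceding(grp, t)
        rows.append({
            "icustay_id": ev["icustay_id"], "start_time": t,
            "glc_a": a["value"] if a else np.nan,
            "glc_b": b["value"] if b else np.nan,
            "glc_c": c["value"] if c else np.nan,
            "theta_c": c["gap_minutes"] if c else np.nan,
            "rule_a": a["rule"] if a else None,
        })
    per_stay = pd.DataFrame(rows)
    edges, labels = _bin_labels(config.theta_bin_edges)
    if per_stay.empty:
        per_stay = pd.DataFrame(columns=["icustay_id", "start_time", "glc_a",
                                         "glc_b", "glc_c", "theta_c",
                                         "rule_a"])
    counts = {s: int(per_stay[f"glc_{s}"].notna().sum())
              for s in ("a", "b", "c")}
    excluded = {s: int((per_stay[f"glc_{s}"].isna()
                        & per_stay["glc_c"].notna()).sum())
                for s in ("a", "b")}
    tables = {
        "A_vs_C": _scenario_table(per_stay, "a", edges, labels),
        "B_vs_C": _scenario_table(per_stay, "b", edges, labels),
    }
    return ScenarioComparison(per_stay=per_stay, paired_counts=counts,
                              tables=tables, n_stays=len(per_stay),
                              n_excluded=excluded)
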
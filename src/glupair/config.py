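"""Configuration for the curation/pairing pipeline.

Item-ID maps default to the ten glucose and six insulin item IDs charted in
MIMIC-III MetaVision ICUs, but are plain configuration so the pipeline runs
unchanged on any table that reuses the same schema (in particular the bundled
synthetic-EHR generator).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator

# Glucose source codes (GLCSOURCE): bedside glucometer vs central laboratory.
FINGERSTICK = "FINGERSTICK"
BLOOD = "BLOOD"

# Origin table of a glucose reading.
CHART = "CHART"
LAB = "LAB"

# Insulin acting types (INSULINTYPE).
SHORT = "SHORT"
INTERMEDIATE = "INTERMEDIATE"
LONG = "LONG"

# Insulin event kinds (EVENT).
BOLUS_INYECTION = "BOLUS_INYECTION"  # subcutaneous bolus (spelling as published)
BOLUS_PUSH = "BOLUS_PUSH"            # intravenous push
INFUSION = "INFUSION"                # continuous intravenous infusion

#: itemid -> analytical technique, for glucose rows found in CHARTEVENTS.
CHART_GLUCOSE_ITEMS: Dict[int, str] = {
    807: FINGERSTICK,     # Fingerstick Glucose
    811: FINGERSTICK,     # Glucose (70-105)
    1529: FINGERSTICK,    # Glucose
    3744: FINGERSTICK,    # Blood Glucose
    3745: BLOOD,          # Blood Glucose (laboratory analyzer)
    225664: FINGERSTICK,  # Glucose finger stick
    220621: BLOOD,        # Glucose (serum)
    226537: FINGERSTICK,  # Glucose (whole blood)
}

#: itemid -> analytical technique, for glucose rows found in LABEVENTS.
LAB_GLUCOSE_ITEMS: Dict[int, str] = {
    50809: BLOOD,  # Glucose - Chemistry - Blood
    50931: BLOOD,  # Glucose - Blood Gas - Blood
}

#: itemid -> acting type, for insulin rows in INPUTEVENTS_MV.
INSULIN_ITEMS: Dict[int, str] = {
    223258: SHORT,         # Insulin Regular
    223262: SHORT,         # Insulin Humalog
    223260: LONG,          # Insulin Glargine
    223259: INTERMEDIATE,  # Insulin NPH
    223257: INTERMEDIATE,  # Insulin 70/30
    223261: INTERMEDIATE,  # Insulin Humalog 75/25
}

#: MetaVision ORDERCATEGORYDESCRIPTION -> event kind.
DEFAULT_EVENT_KIND_MAP: Dict[str, str] = {
    "Continuous IV": INFUSION,
    "Drug Push": BOLUS_PUSH,
    "Bolus": BOLUS_INYECTION,
}


class CurationConfig(BaseModel):
    """Thresholds and maps for criteria A-K."""

    model_config = {"frozen": True}

    chart_glucose_items: Dict[int, str] = Field(
        default_factory=lambda: dict(CHART_GLUCOSE_ITEMS))
    lab_glucose_items: Dict[int, str] = Field(
        default_factory=lambda: dict(LAB_GLUCOSE_ITEMS))
    insulin_items: Dict[int, str] = Field(
        default_factory=lambda: dict(INSULIN_ITEMS))
    event_kind_column: str = "ORDERCATEGORYDESCRIPTION"
    event_kind_map: Dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_EVENT_KIND_MAP))
    #: glucose values at or above this limit are outside the lab analyzer's
    #: accurate range and dropped (criterion F)
    blood_limit: float = 1000.0
    #: fingerstick values at or above this limit are ceiling-coded and dropped
    fingerstick_limit: float = 500.0
    #: short-acting bolus doses must be strictly below this cap (criterion J)
    bolus_cap: float = 18.0
    #: infusion rates must be at or below this cap (criterion I)
    infusion_cap: float = 29.8
    #: if True, recompute the caps as this percentile of the observed doses
    recompute_caps: bool = False
    cap_percentile: float = 99.0

    @field_validator("blood_limit", "fingerstick_limit", "bolus_cap",
                     "infusion_cap")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("limits must be positive")
        return v

    @property
    def glucose_sources(self) -> Dict[int, str]:
        """Combined itemid -> source map across both origin tables."""
        return {**self.chart_glucose_items, **self.lab_glucose_items}


class PairingParams(BaseModel):
    """Parameters of alignment rules 1-5.

    window_minutes
        Maximum gap between a glucose reading and the insulin event it is
        paired with (rules 1-3); inclusive at the boundary.
    glucose_floor
        Readings below this value (mg/dL) are never paired (rule 5).
    bundle_gap_minutes
        A short-acting bolus and a short-acting infusion event whose start
        times fall within this gap are treated as one bolus+infusion bundle
        (rule 4).
    """

    model_config = {"frozen": True}

    window_minutes: float = 90.0
    glucose_floor: float = 90.0
    bundle_gap_minutes: float = 15.0

    @field_validator("window_minutes", "bundle_gap_minutes")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("durations must be positive")
        return v

    @field_validator("glucose_floor")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("glucose_floor must be >= 0")
        return v


class AgreementConfig(BaseModel):
    """Parameters of the validation assays."""

    model_config = {"frozen": True}

    #: Δθ bin edges in minutes; a trailing open bin is added automatically
    theta_bin_edges: Tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    #: limits-of-agreement multiplier (1.96 = conventional 95% limits)
    loa_k: float = 1.96
    alpha: float = 0.05
    scenario_window_a: float = 90.0
    scenario_window_b: float = 60.0


class PipelineConfig(BaseModel):
    """Top-level configuration bundling all stages."""

    model_config = {"frozen": True}

    curation: CurationConfig = Field(default_factory=CurationConfig)
    pairing: PairingParams = Field(default_factory=PairingParams)
    agreement: AgreementConfig = Field(default_factory=AgreementConfig)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Missing sections fall back to defaults, so a config file only needs the
    keys it overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def default_config() -> PipelineConfig:
    return PipelineConfig()
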
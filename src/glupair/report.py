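"""Per-criterion audit trail of the curation pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional


@dataclass
class CurationStage:
    """Row accounting for one inclusion criterion."""

    label: str
    description: str
    rows_in: int
    rows_removed: int

    @property
    def rows_out(self) -> int:
        return self.rows_in - self.rows_removed


@dataclass
class CurationReport:
    """Ordered record of what each criterion removed.

    Stages must compose: the output row count of stage *k* is the input row
    count of stage *k+1*. :meth:`verify` raises if the chain is broken, which
    guards against criteria silently double-counting or resurrecting rows.
    """

    stages: List[CurationStage] = field(default_factory=list)
    patients_in: int = 0
    patients_out: int = 0
    extras: Dict[str, float] = field(default_factory=dict)

    def add(self, label: str, description: str, rows_in: int,
            rows_removed: int) -> CurationStage:
        stage = CurationStage(label, description, rows_in, rows_removed)
        self.stages.append(stage)
        return stage

    def stage(self, label: str) -> CurationStage:
        for s in self.stages:
            if s.label == label:
                return s
        raise KeyError(label)

    def verify(self) -> None:
        for s in self.stages:
            if s.rows_removed < 0 or s.rows_removed > s.rows_in:
                raise ValueError(
                    f"stage {s.label}: removed {s.rows_removed} of {s.rows_in}")
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.rows_out != nxt.rows_in:
                raise ValueError(
                    f"stage chain broken between {prev.label} and {nxt.label}: "
                    f"{prev.rows_out} != {nxt.rows_in}")

    @property
    def rows_in(self) -> int:
        return self.stages[0].rows_in if self.stages else 0

    @property
    def rows_out(self) -> int:
        return self.stages[-1].rows_out if self.stages else 0

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "label": s.label,
                    "description": s.description,
                    "rows_in": s.rows_in,
                    "rows_removed": s.rows_removed,
                    "rows_out": s.rows_out,
                }
                for s in self.stages
            ],
            "patients_in": self.patients_in,
            "patients_out": self.patients_out,
            "extras": dict(self.extras),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
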
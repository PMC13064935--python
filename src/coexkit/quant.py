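"""Small closed-form quantifications: relative qPCR expression (delta-delta
CT) and ellipsoid xenograft tumor volume."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import math

import pandas as pd

__all__ = ["CtRecord", "TumorMeasure", "ddct_fold_change", "ellipsoid_volume"]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: target and reference (housekeeping) threshold cycles."""

    sample: str
    target_ct: float
    reference_ct: float
    condition: str  # "treatment" or "control"

    def __post_init__(self) -> None:
        for v in (self.target_ct, self.reference_ct):
            if not math.isfinite(v):
                raise ValueError(f"CT values must be finite (sample {self.sample!r})")
        if self.condition not in {"treatment", "control"}:
            raise ValueError(f"condition must be treatment/control, got {self.condition!r}")


@dataclass(frozen=True)
class TumorMeasure:
    """Caliper length/width of a subcutaneous xenograft, in mm."""

    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("tumor dimensions must be positive")


def ddct_fold_change(records: Iterable[CtRecord]) -> pd.DataFrame:
    """Relative expression by the delta-delta CT method.

    Per sample, dCT = target CT - reference CT; ddCT = dCT minus the
    mean dCT of the control group; fold change = 2^(-ddCT). Averaging
    controls first makes the control-group geometric mean fold equal 1.
    """
    records = list(records)
    controls = [r for r in records if r.condition == "control"]
    if not controls:
        raise ValueError("at least one control record is required")
    control_mean_dct = sum(r.target_ct - r.reference_ct for r in controls) / len(controls)
    rows = []
    for r in records:
        dct = r.target_ct - r.reference_ct
        ddct = dct - control_mean_dct
        rows.append({"sample": r.sample, "condition": r.condition, "delta_ct": dct,
                     "delta_delta_ct": ddct, "fold_change": 2.0 ** (-ddct)})
    return pd.DataFrame(rows)


def ellipsoid_volume(measure: TumorMeasure) -> float:
    """Tumor volume by the xenograft ellipsoid convention: L * W^2 / 2 (mm^3)."""
    return measure.length_mm * measure.width_mm**2 / 2.0
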
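"""Diagnostic threshold classification.

Applies the study's clinical cut-offs:

* vitamin D (25(OH)D, ng/mL): < 20 deficient, 20-29 insufficient,
  >= 30 sufficient (US Endocrine Society criteria);
* PTH (pg/mL): normal range 4.4-58.6 inclusive;
* hepatic iron overload: MRI LIC >= 3 mg/g dry weight;
* pancreatic iron overload: global pancreas T2* < 26 ms (26.0 is normal);
* myocardial iron overload: global heart T2* <= 20 ms (normal is strictly
  > 20 ms, so exactly 20.0 ms is overloaded).

One source occasionally writes vitamin D units as ng/dL; the criteria are
stated in ng/mL and this package uses ng/mL throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import math

import pandas as pd
import yaml

__all__ = [
    "Thresholds",
    "StatusFlags",
    "vitd_category",
    "iron_flags",
    "pth_status",
    "classify_cohort",
]

VitDCategory = Literal["deficient", "insufficient", "sufficient"]
PthStatus = Literal["low", "normal", "high"]


@dataclass(frozen=True)
class Thresholds:
    """All diagnostic cut-offs, serializable to/from YAML bit-exactly."""

    vitd_deficient_below: float = 20.0      # ng/mL
    vitd_sufficient_at: float = 30.0        # ng/mL
    pth_low_below: float = 4.4              # pg/mL
    pth_high_above: float = 58.6            # pg/mL
    lic_overload_at: float = 3.0            # mg/g dw
    pancreas_normal_at: float = 26.0        # ms (>= is normal)
    heart_normal_above: float = 20.0        # ms (> is normal)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Thresholds":
        return cls(**yaml.safe_load(text))


@dataclass(frozen=True)
class StatusFlags:
    vitd_category: VitDCategory
    hepatic_overload: bool
    pancreatic_overload: bool
    myocardial_overload: bool
    pth_status: PthStatus


def _check_nonneg(name: str, value: float) -> float:
    v = float(value)
    if math.isnan(v) or math.isinf(v):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if v < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return v


def vitd_category(vitamin_d_ng_ml: float, thresholds: Thresholds = Thresholds()) -> VitDCategory:
    """Vitamin D status: < 20 deficient, [20, 30) insufficient, >= 30 sufficient."""
    v = _check_nonneg("vitamin_d", vitamin_d_ng_ml)
    if v < thresholds.vitd_deficient_below:
        return "deficient"
    if v < thresholds.vitd_sufficient_at:
        return "insufficient"
    return "sufficient"


def pth_status(pth_pg_ml: float, thresholds: Thresholds = Thresholds()) -> PthStatus:
    """PTH status against the inclusive normal range 4.4-58.6 pg/mL."""
    v = _check_nonneg("pth", pth_pg_ml)
    if v < thresholds.pth_low_below:
        return "low"
    if v > thresholds.pth_high_above:
        return "high"
    return "normal"


def iron_flags(lic_mg_g: float, pancreas_t2star_ms: float, heart_t2star_ms: float,
               thresholds: Thresholds = Thresholds()) -> dict:
    """Organ iron-overload flags.

    Hepatic: LIC >= 3 mg/g dw.  Pancreatic: T2* < 26 ms (exactly 26 is
    normal).  Myocardial: T2* <= 20 ms (exactly 20 is overloaded, since
    normal is strictly above 20 ms).
    """
    lic = _check_nonneg("lic", lic_mg_g)
    panc = _check_nonneg("pancreas_t2star", pancreas_t2star_ms)
    heart = _check_nonneg("heart_t2star", heart_t2star_ms)
    return {
        "hepatic_overload": lic >= thresholds.lic_overload_at,
        "pancreatic_overload": panc < thresholds.pancreas_normal_at,
        "myocardial_overload": heart <= thresholds.heart_normal_above,
    }


def classify_patient(vitamin_d: float, pth: float, lic: float,
                     pancreas_t2star: float, heart_t2star: float,
                     thresholds: Thresholds = Thresholds()) -> StatusFlags:
    flags = iron_flags(lic, pancreas_t2star, heart_t2star, thresholds)
    return StatusFlags(
        vitd_category=vitd_category(vitamin_d, thresholds),
        pth_status=pth_status(pth, thresholds),
        **flags,
    )


def classify_cohort(cohort: pd.DataFrame,
                    thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Append category/flag columns to a cohort table.

    Requires columns ``vitamin_d``, ``pth``, ``lic``, ``pancreas_t2star``,
    ``heart_t2star``; returns a copy with ``vitd_category``, ``pth_status``
    and the three organ-overload boolean columns appended.
    """
    required = ["vitamin_d", "pth", "lic", "pancreas_t2star", "heart_t2star"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    out = cohort.copy()
    out["vitd_category"] = [vitd_category(v, thresholds) for v in out["vitamin_d"]]
    out["pth_status"] = [pth_status(v, thresholds) for v in out["pth"]]
    flag_rows = [
        iron_flags(l, p, h, thresholds)
        for l, p, h in zip(out["lic"], out["pancreas_t2star"], out["heart_t2star"])
    ]
    for key in ("hepatic_overload", "pancreatic_overload", "myocardial_overload"):
        out[key] = [r[key] for r in flag_rows]
    return out
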
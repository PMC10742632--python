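"""Biventricular volumes, ejection fraction, LV mass and BSA indexing.

Volumes follow Simpson's disc-summation rule on contiguous short-axis
slices: each slice contributes area x (thickness + gap), with no geometric
shape assumption.  Ejection fraction is (EDV - ESV) x 100 / EDV; LV mass is
the myocardial shell volume times the specific weight of myocardium,
1.05 g/cm^3.  Volume and mass indices divide by body surface area (Du Bois
by default, Mosteller selectable).

Papillary muscles are a contract on the *inputs*: endocardial areas are
expected to exclude them from the blood pool, and the epicardial-endocardial
shell then counts them in the mass, matching clinical post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VentricularStudy",
    "FunctionMetrics",
    "simpson_volume",
    "ejection_fraction",
    "lv_mass",
    "body_surface_area",
    "index_to_bsa",
    "analyze_study",
    "MYOCARDIUM_DENSITY_G_PER_ML",
]

MYOCARDIUM_DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class VentricularStudy:
    """Per-slice LV areas (cm^2) at end-diastole/end-systole plus anthropometrics."""

    ed_endo_areas: tuple[float, ...]
    es_endo_areas: tuple[float, ...]
    ed_epi_areas: tuple[float, ...]
    slice_thickness_cm: float = 0.8
    gap_cm: float = 0.0
    height_cm: float | None = None
    weight_kg: float | None = None


@dataclass(frozen=True)
class FunctionMetrics:
    edv_ml: float
    esv_ml: float
    ef_percent: float
    mass_g: float
    bsa_m2: float | None = None
    edvi_ml_m2: float | None = None
    mass_index_g_m2: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def simpson_volume(slice_areas: Sequence[float], thickness_cm: float = 0.8,
                   gap_cm: float = 0.0) -> float:
    """Disc-summation volume in mL: sum of area_i * (thickness + gap)."""
    areas = np.asarray(slice_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("slice area list is empty")
    if np.any(areas < 0) or not np.all(np.isfinite(areas)):
        raise ValueError("slice areas must be finite and non-negative")
    if thickness_cm <= 0:
        raise ValueError("slice thickness must be positive")
    if gap_cm < 0:
        raise ValueError("gap must be non-negative")
    return float(areas.sum() * (thickness_cm + gap_cm))


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction in percent: (EDV - ESV) * 100 / EDV."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    if esv_ml < 0 or esv_ml > edv_ml:
        raise ValueError("ESV must lie in [0, EDV]")
    # clamp: rounding can land a hair above 100 when ESV is 0
    return min(100.0, max(0.0, (edv_ml - esv_ml) * 100.0 / edv_ml))


def lv_mass(epi_volume_ml: float, endo_volume_ml: float) -> float:
    """LV mass in grams: myocardial shell volume times 1.05 g/cm^3."""
    if epi_volume_ml < endo_volume_ml:
        raise ValueError("epicardial volume must be >= endocardial volume")
    return (epi_volume_ml - endo_volume_ml) * MYOCARDIUM_DENSITY_G_PER_ML


def body_surface_area(height_cm: float, weight_kg: float,
                      formula: Literal["dubois", "mosteller"] = "dubois") -> float:
    """Body surface area in m^2 (Du Bois default, Mosteller selectable)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula: {formula!r}")


def index_to_bsa(value: float, height_cm: float, weight_kg: float,
                 formula: Literal["dubois", "mosteller"] = "dubois") -> float:
    """Divide a volume (mL) or mass (g) by BSA, giving mL/m^2 or g/m^2."""
    return value / body_surface_area(height_cm, weight_kg, formula)


def analyze_study(study: VentricularStudy,
                  bsa_formula: Literal["dubois", "mosteller"] = "dubois") -> FunctionMetrics:
    """Full function panel (EDV, ESV, EF, mass, BSA indices) for one ventricle."""
    edv = simpson_volume(study.ed_endo_areas, study.slice_thickness_cm, study.gap_cm)
    esv = simpson_volume(study.es_endo_areas, study.slice_thickness_cm, study.gap_cm)
    epi_v = simpson_volume(study.ed_epi_areas, study.slice_thickness_cm, study.gap_cm)
    ef = ejection_fraction(edv, esv)
    mass = lv_mass(epi_v, edv)
    bsa = edvi = mass_i = None
    if study.height_cm is not None and study.weight_kg is not None:
        bsa = body_surface_area(study.height_cm, study.weight_kg, bsa_formula)
        edvi = edv / bsa
        mass_i = mass / bsa
    return FunctionMetrics(edv_ml=edv, esv_ml=esv, ef_percent=ef, mass_g=mass,
                           bsa_m2=bsa, edvi_ml_m2=edvi, mass_index_g_m2=mass_i)
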
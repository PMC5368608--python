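"""Aggregation arithmetic: global strain, gradient parameters, LV volumetrics.

Global strain per direction is the arithmetic mean of the basal, mid and
apical level peaks; layer-specific summaries average the same way.  The two
gradient parameters are differences of strain magnitudes:

* G_endo-epi = |Ecc_endo| - |Ecc_epi|  (transmural circumferential gradient)
* G_base-apex = |Ell_basal| - |Ell_apical|  (longitudinal gradient)

both positive when endocardial / basal shortening dominates.  LV volumes
use slice summation (method of disks): volume = sum(area x (thickness +
gap)); mass = myocardial wall volume at end-diastole x 1.05 g/mL; LVEF =
(EDV - ESV) / EDV; body surface area by Mosteller (Du Bois selectable),
indexed values = raw / BSA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

LAYERS = ("endo", "mid", "epi")
LEVELS = ("basal", "mid", "apical")
DIRECTIONS = ("Err", "Ecc", "Ell")

#: Myocardial tissue density, g/mL.
MYOCARDIAL_DENSITY = 1.05


def aggregate_regions(basal: float, mid: float, apical: float) -> float:
    """Mean of the three level values (the global / summary strain rule).

    Missing values are an error: no silent imputation.
    """
    vals = (basal, mid, apical)
    if any(v is None or not np.isfinite(v) for v in vals):
        missing = [n for n, v in zip(LEVELS, vals) if v is None or not np.isfinite(v)]
        raise ValueError(f"missing level value(s): {', '.join(missing)}")
    return float(np.mean(vals))


def gradient_endo_epi(ecc_endo: float, ecc_epi: float) -> float:
    """Transmural circumferential gradient |Ecc_endo| - |Ecc_epi| (%)."""
    return float(abs(ecc_endo) - abs(ecc_epi))


def gradient_base_apex(ell_basal: float, ell_apical: float) -> float:
    """Longitudinal gradient |Ell_basal| - |Ell_apical| (%)."""
    return float(abs(ell_basal) - abs(ell_apical))


@dataclass
class StrainRecord:
    """One subject's peak systolic strain profile (%).

    Layer values (endo/mid/epi) come from the short-axis views for Err/Ecc
    and the four-chamber view for Ell; level values (basal/mid/apical) from
    the three short-axis levels (Err/Ecc) and the long-axis thirds (Ell).
    Globals and gradients are derived, never free.
    """

    subject: str = ""
    sex: str = ""  # "F" or "M"
    age: float = np.nan

    Err_endo: float = np.nan
    Err_mid: float = np.nan
    Err_epi: float = np.nan
    Ecc_endo: float = np.nan
    Ecc_mid: float = np.nan
    Ecc_epi: float = np.nan
    Ell_endo: float = np.nan
    Ell_mid: float = np.nan
    Ell_epi: float = np.nan

    Err_basal: float = np.nan
    Err_midlv: float = np.nan
    Err_apical: float = np.nan
    Ecc_basal: float = np.nan
    Ecc_midlv: float = np.nan
    Ecc_apical: float = np.nan
    Ell_basal: float = np.nan
    Ell_midlv: float = np.nan
    Ell_apical: float = np.nan

    Err_global: float = field(init=False, default=np.nan)
    Ecc_global: float = field(init=False, default=np.nan)
    Ell_global: float = field(init=False, default=np.nan)
    G_endo_epi: float = field(init=False, default=np.nan)
    G_base_apex: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        self.refresh_derived()

    def refresh_derived(self) -> None:
        """Recompute globals and gradients from the stored layer/level peaks."""
        for d in DIRECTIONS:
            levels = [getattr(self, f"{d}_basal"), getattr(self, f"{d}_midlv"),
                      getattr(self, f"{d}_apical")]
            if all(np.isfinite(levels)):
                setattr(self, f"{d}_global", aggregate_regions(*levels))
        if np.isfinite(self.Ecc_endo) and np.isfinite(self.Ecc_epi):
            self.G_endo_epi = gradient_endo_epi(self.Ecc_endo, self.Ecc_epi)
        if np.isfinite(self.Ell_basal) and np.isfinite(self.Ell_apical):
            self.G_base_apex = gradient_base_apex(self.Ell_basal, self.Ell_apical)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def records_to_frame(records: list[StrainRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2), Mosteller: sqrt(height x weight / 3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2), Du Bois: 0.007184 h^0.725 w^0.425."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


@dataclass(frozen=True)
class VolumetricsRecord:
    """LV volumes, mass and ejection fraction of one subject."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    lvef_pct: float
    mass_g: float
    bsa_m2: float
    edvi_ml_m2: float
    esvi_ml_m2: float
    massi_g_m2: float
    height_cm: float
    weight_kg: float


def lv_volumetrics(
    endo_areas_ed_mm2: np.ndarray,
    endo_areas_es_mm2: np.ndarray,
    epi_areas_ed_mm2: np.ndarray,
    slice_thickness_mm: float,
    slice_gap_mm: float,
    height_cm: float,
    weight_kg: float,
    density_g_ml: float = MYOCARDIAL_DENSITY,
    bsa_formula: str = "mosteller",
) -> VolumetricsRecord:
    """Slice-summation volumetrics from per-slice contour areas.

    Areas are in mm^2, one entry per contiguous short-axis slice; each slice
    contributes area x (thickness + gap).  Papillary muscles are taken as
    included in the blood pool (contours used as drawn, no trabecular
    correction).  An ESV exceeding EDV is physiologically implausible and
    raises a warning but is still computed.
    """
    endo_ed = np.asarray(endo_areas_ed_mm2, dtype=float)
    endo_es = np.asarray(endo_areas_es_mm2, dtype=float)
    epi_ed = np.asarray(epi_areas_ed_mm2, dtype=float)
    if endo_ed.size < 1 or endo_es.size < 1 or epi_ed.size != endo_ed.size:
        raise ValueError("need >= 1 slice and matching ED endo/epi area lists")
    if slice_thickness_mm <= 0 or slice_gap_mm < 0:
        raise ValueError("slice thickness must be positive and gap non-negative")
    if np.any(endo_ed < 0) or np.any(endo_es < 0) or np.any(epi_ed < endo_ed):
        raise ValueError("areas must be non-negative with epi >= endo per slice")

    step = slice_thickness_mm + slice_gap_mm
    edv = float(endo_ed.sum() * step) / 1000.0  # mm^3 -> mL
    esv = float(endo_es.sum() * step) / 1000.0
    if esv > edv:
        warnings.warn(
            f"ESV ({esv:.1f} mL) exceeds EDV ({edv:.1f} mL): physiologically implausible",
            stacklevel=2,
        )
    sv = edv - esv
    lvef = sv / edv * 100.0 if edv > 0 else float("nan")
    wall_ml = float((epi_ed - endo_ed).sum() * step) / 1000.0
    mass = wall_ml * density_g_ml

    bsa_fn = {"mosteller": bsa_mosteller, "dubois": bsa_dubois}.get(bsa_formula)
    if bsa_fn is None:
        raise ValueError(f"unknown BSA formula {bsa_formula!r}")
    bsa = bsa_fn(height_cm, weight_kg)

    return VolumetricsRecord(
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        lvef_pct=lvef,
        mass_g=mass,
        bsa_m2=bsa,
        edvi_ml_m2=edv / bsa,
        esvi_ml_m2=esv / bsa,
        massi_g_m2=mass / bsa,
        height_cm=height_cm,
        weight_kg=weight_kg,
    )
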
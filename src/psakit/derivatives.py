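"""PSA derivatives, anthropometric intermediates, and tumor-volume conversion.

The derivatives quantify how much PSA a man's serum carries relative to his
prostate size and body size:

* **PSAD** (PSA density) = serum PSA / prostate weight (ng/mL per gram);
* **PSAM** (PSA mass)    = serum PSA x plasma volume (reported in micrograms
  on the convention described below) — the total circulating PSA, which is
  insensitive to hemodilution in larger men;
* **PSAMD** (PSA mass density) = PSAM / prostate weight, adjusting for gland
  size and body size at once.

Plasma volume is estimated as 1.67 x body surface area, and body surface
area by the convention ``0.007184 * weight_kg**0.425 * height**0.72`` with
height **in meters** (mode ``"meters"``, the default).  The classic Du Bois
formula takes height in centimeters with exponent 0.725; that convention
(mode ``"dubois-cm"``) yields PSAM values roughly 27x larger, on which the
published PSAMD cutoffs (e.g. 0.012 ug/g) do not apply.  Use it only when
recomputing cutoffs from scratch on your own data.

Tumor volume is reconstructed from histologic 1-mm^2 grid counts as
``mm2 * 3 (section thickness, mm) * 1.12 (fixation shrinkage)``, reported in
cm^3; a volume >= 0.5 cm^3 defines *significant* disease.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import PatientRecord

#: Section thickness in mm used for the grid-count to volume conversion.
SECTION_THICKNESS_MM = 3.0
#: Formalin-fixation shrinkage correction factor.
SHRINKAGE_FACTOR = 1.12
#: Tumor volume (cm^3) at or above which disease is called significant.
SIGNIFICANT_TV_CM3 = 0.5
#: Plasma volume = PLASMA_VOLUME_FACTOR x body surface area.
PLASMA_VOLUME_FACTOR = 1.67


class BmiCategory(enum.Enum):
    UNDERWEIGHT = "UNDERWEIGHT"
    NORMAL = "NORMAL"
    OVERWEIGHT = "OVERWEIGHT"
    OBESE = "OBESE"


@dataclass
class DerivedMeasures:
    """All derivatives for one record; BMI-dependent fields are ``None`` when
    height or weight is missing."""

    psad: float
    significant: Optional[bool]
    tumor_volume: Optional[float] = None
    bmi: Optional[float] = None
    bmi_category: Optional[BmiCategory] = None
    bsa: Optional[float] = None
    plasma_volume: Optional[float] = None
    psam: Optional[float] = None
    psamd: Optional[float] = None


def compute_bmi(weight: float, height: float) -> tuple[float, BmiCategory]:
    """Body mass index (kg/m^2) and WHO category.

    Categories: underweight < 18.5, normal [18.5, 25), overweight [25, 30),
    obese >= 30 (boundaries 25 and 30 belong to the higher category).
    """
    if weight <= 0 or height <= 0:
        raise ValueError(f"weight and height must be positive, got {weight}, {height}")
    bmi = weight / height**2
    return bmi, bmi_category(bmi)


def bmi_category(bmi: float) -> BmiCategory:
    if bmi < 18.5:
        return BmiCategory.UNDERWEIGHT
    if bmi < 25:
        return BmiCategory.NORMAL
    if bmi < 30:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


def compute_bsa(weight, height, mode: str = "meters"):
    """Body surface area.

    mode ``"meters"``: ``0.007184 * weight**0.425 * height_m**0.72`` with
    height in meters — the convention on which the published PSAM/PSAMD
    scale rests.  mode ``"dubois-cm"``: classic Du Bois,
    ``0.007184 * weight**0.425 * height_cm**0.725`` (height converted to cm).
    Accepts scalars or arrays.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    if mode == "meters":
        out = 0.007184 * weight**0.425 * height**0.72
    elif mode == "dubois-cm":
        out = 0.007184 * weight**0.425 * (height * 100.0) ** 0.725
    else:
        raise ValueError(f"unknown BSA mode {mode!r}; use 'meters' or 'dubois-cm'")
    return float(out) if out.ndim == 0 else out


def compute_plasma_volume(bsa):
    """Plasma volume = 1.67 x body surface area (same unit convention as bsa)."""
    bsa = np.asarray(bsa, dtype=float)
    if np.any(bsa <= 0):
        raise ValueError("bsa must be positive")
    out = PLASMA_VOLUME_FACTOR * bsa
    return float(out) if out.ndim == 0 else out


def compute_psa_mass(psa, plasma_volume):
    """PSAM = serum PSA x plasma volume (micrograms on the default convention)."""
    psa = np.asarray(psa, dtype=float)
    if np.any(psa < 0):
        raise ValueError("psa must be non-negative")
    out = psa * np.asarray(plasma_volume, dtype=float)
    return float(out) if out.ndim == 0 else out


def compute_psad(psa, prostate_weight):
    """PSAD = serum PSA / prostate weight without seminal vesicles (ng/mL/g)."""
    psa = np.asarray(psa, dtype=float)
    pw = np.asarray(prostate_weight, dtype=float)
    if np.any(pw <= 0):
        raise ValueError("prostate_weight must be positive")
    if np.any(psa < 0):
        raise ValueError("psa must be non-negative")
    out = psa / pw
    return float(out) if out.ndim == 0 else out


def compute_psamd(psam, prostate_weight):
    """PSAMD = PSAM / prostate weight without seminal vesicles (ug/g)."""
    psam = np.asarray(psam, dtype=float)
    pw = np.asarray(prostate_weight, dtype=float)
    if np.any(pw <= 0):
        raise ValueError("prostate_weight must be positive")
    if np.any(psam < 0):
        raise ValueError("psam must be non-negative")
    out = psam / pw
    return float(out) if out.ndim == 0 else out


def compute_tumor_volume(
    grid_mm2,
    thickness_mm: float = SECTION_THICKNESS_MM,
    shrinkage: float = SHRINKAGE_FACTOR,
):
    """Tumor volume in cm^3 from the summed 1-mm^2 grid count.

    ``grid_mm2 * thickness_mm * shrinkage`` gives mm^3, divided by 1000 for
    cm^3.  With the default constants, 149 mm^2 is the smallest integer count
    crossing the 0.5 cm^3 significance threshold.
    """
    grid = np.asarray(grid_mm2, dtype=float)
    if np.any(grid < 0):
        raise ValueError("grid_mm2 must be non-negative")
    out = grid * thickness_mm * shrinkage / 1000.0
    return float(out) if out.ndim == 0 else out


def classify_significant(tumor_volume, threshold: float = SIGNIFICANT_TV_CM3):
    """True when tumor volume >= threshold (0.5 cm^3 itself is significant)."""
    tv = np.asarray(tumor_volume, dtype=float)
    if np.any(tv < 0):
        raise ValueError("tumor_volume must be non-negative")
    out = tv >= threshold
    return bool(out) if out.ndim == 0 else out


def derive_all(record: PatientRecord, bsa_mode: str = "meters") -> DerivedMeasures:
    """Compute every derivative for one record.

    Tumor volume comes from ``record.tumor_volume`` when present, otherwise
    from the grid count; if neither is present the significance flag is
    ``None``.  BMI/BSA/PSAM/PSAMD are ``None`` when height or weight is
    missing (such records are excluded from BMI-dependent analyses).
    """
    record.validate()
    psad = compute_psad(record.psa, record.prostate_weight)
    if record.tumor_volume is not None:
        tv = record.tumor_volume
    elif record.tumor_grid_mm2 is not None:
        tv = compute_tumor_volume(record.tumor_grid_mm2)
    else:
        tv = None
    significant = classify_significant(tv) if tv is not None else None
    out = DerivedMeasures(psad=psad, significant=significant, tumor_volume=tv)
    if record.has_body_size:
        out.bmi, out.bmi_category = compute_bmi(record.weight, record.height)
        out.bsa = compute_bsa(record.weight, record.height, mode=bsa_mode)
        out.plasma_volume = compute_plasma_volume(out.bsa)
        out.psam = compute_psa_mass(record.psa, out.plasma_volume)
        out.psamd = compute_psamd(out.psam, record.prostate_weight)
    return out


def add_derivatives(df, bsa_mode: str = "meters", tv_threshold: float = SIGNIFICANT_TV_CM3):
    """Append derivative columns to a cohort DataFrame (see ``Cohort.to_frame``).

    Adds: ``bmi``, ``bmi_category``, ``bsa``, ``plasma_volume``, ``psam``,
    ``psamd``, ``psad``, ``tumor_volume`` (filled from grid counts where the
    direct measurement is absent) and boolean ``significant``.
    """
    import pandas as pd

    df = df.copy()
    pw = df["prostate_weight_g"].to_numpy(float)
    psa = df["psa_ng_ml"].to_numpy(float)
    df["psad"] = compute_psad(psa, pw)

    tv = df.get("tumor_volume_cm3", pd.Series(np.nan, index=df.index)).to_numpy(float).copy()
    grid = df.get("tumor_grid_mm2", pd.Series(np.nan, index=df.index)).to_numpy(float)
    fill = np.isnan(tv) & ~np.isnan(grid)
    tv[fill] = compute_tumor_volume(grid[fill])
    df["tumor_volume"] = tv
    sig = pd.array(tv >= tv_threshold, dtype="boolean")
    sig[np.isnan(tv)] = pd.NA
    df["significant"] = sig

    height = df["height_m"].to_numpy(float)
    weight = df["weight_kg"].to_numpy(float)
    has_body = ~np.isnan(height) & ~np.isnan(weight)
    bmi = np.full(len(df), np.nan)
    bsa = np.full(len(df), np.nan)
    bmi[has_body] = weight[has_body] / height[has_body] ** 2
    bsa[has_body] = compute_bsa(weight[has_body], height[has_body], mode=bsa_mode)
    df["bmi"] = bmi
    df["bmi_category"] = [bmi_category(b).value if not np.isnan(b) else None for b in bmi]
    df["bsa"] = bsa
    df["plasma_volume"] = PLASMA_VOLUME_FACTOR * bsa
    df["psam"] = psa * df["plasma_volume"].to_numpy(float)
    df["psamd"] = df["psam"].to_numpy(float) / pw
    return df
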
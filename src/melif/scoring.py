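"""Liver-function scores from registered pre/post-contrast T1 maps.

The chain is: voxel-wise T1 reduction rate -> whole-liver aggregation ->
patient-specific normalization -> the final MELIF score, alongside the
laboratory MELD score used as clinical reference.

Whole-liver aggregation supports two conventions:

``mean_pct``
    Arithmetic mean of the voxel reduction rates, in percent — the
    quantity reported as "rrT1_liver (%)" in cohort summaries.

``integrated``
    Sum of fractional voxel reduction rates after resampling onto a fixed
    *standard scoring grid* (default 3.6 mm isotropic).  The sum then
    scales with functional liver volume rather than acquisition
    resolution; it is the quantity entering the MELIF formula and places
    MELIF on its conventional 20-80 scale for typical adult livers.  The
    grid spacing is configurable; the default is a documented
    reconstruction, not a universally standardized value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import GeometryError, ValidationError
from .image import Geometry, LiverMask, RRMap, T1Map, resample_array

__all__ = [
    "MELIF_C",
    "STANDARD_GRID_MM",
    "PatientRecord",
    "ScoreResult",
    "rr_map",
    "rrt1_liver",
    "patient_factor",
    "melif",
    "meld",
    "meld_group",
    "score_patient",
]

#: Scale constant of the MELIF formula.
MELIF_C = 0.694

#: Default isotropic spacing (mm) of the standard scoring grid.
STANDARD_GRID_MM = 3.6

MELD_GROUPS = ("normal", "impaired", "severe")


@dataclass
class PatientRecord:
    """Anthropometrics and laboratory values for one patient."""

    id: str
    sex: str
    age_years: float
    height_m: float
    weight_kg: float
    bilirubin_mg_dl: float
    inr: float
    creatinine_mg_dl: float
    dialysis: bool
    liver_volume_ml: float

    def __post_init__(self) -> None:
        for name in ("height_m", "weight_kg", "liver_volume_ml",
                     "bilirubin_mg_dl", "inr", "creatinine_mg_dl"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        self.dialysis = bool(self.dialysis)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScoreResult:
    """All per-patient score outputs plus voxel-exclusion accounting."""

    rrt1_mean_pct: float
    rrt1_integrated: float
    f_p: float
    melif: float
    meld: int
    meld_group: str
    n_voxels_used: int
    n_voxels_excluded: int
    n_voxels_clipped: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def rr_map(t1_pre: T1Map, t1_post_reg: T1Map, mask: LiverMask) -> RRMap:
    """Voxel-wise T1 reduction rate (%) on the pre-contrast grid.

    ``rr = (T1pre - T1postReg) / T1pre * 100`` per masked voxel.  Voxels
    with invalid or nonpositive T1pre, or invalid registered T1post, are
    excluded (NaN, invalid).  Negative rates are retained — they flag
    paradoxical enhancement — and values are clipped to [-100, 100].
    """
    if not t1_pre.geometry.matches(t1_post_reg.geometry):
        raise GeometryError("pre and registered post maps are on different grids")
    if not t1_pre.geometry.matches(mask.geometry):
        raise GeometryError("mask is not on the pre-contrast grid")
    if mask.n_voxels == 0:
        raise ValidationError("empty liver mask")

    ok = mask.data & t1_pre.valid & t1_post_reg.valid & (t1_pre.data > 0)
    rr = np.full(t1_pre.geometry.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr[ok] = (t1_pre.data[ok] - t1_post_reg.data[ok]) / t1_pre.data[ok] * 100.0
    clipped = ok & ((rr < -100.0) | (rr > 100.0))
    rr = np.clip(rr, -100.0, 100.0)
    out = RRMap(rr, t1_pre.geometry, ok)
    out.n_clipped = int(clipped.sum())  # clip-event accounting
    return out


def _standard_geometry(mask: LiverMask, grid_mm: float) -> Geometry:
    """Axis-aligned isotropic grid covering the mask bounding box + margin."""
    idx = np.argwhere(mask.data)
    lo_w = mask.geometry.voxel_to_world(idx.min(axis=0) - 1.0)
    hi_w = mask.geometry.voxel_to_world(idx.max(axis=0) + 1.0)
    lo = np.minimum(lo_w, hi_w) - grid_mm
    hi = np.maximum(lo_w, hi_w) + grid_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / grid_mm)) + 1 for i in range(3))
    aff = np.diag([grid_mm, grid_mm, grid_mm, 1.0])
    aff[:3, 3] = lo
    return Geometry(shape, aff)


def rrt1_liver(
    rr: RRMap,
    mask: LiverMask,
    convention: str = "mean_pct",
    grid_mm: float = STANDARD_GRID_MM,
) -> float:
    """Aggregate the voxel reduction-rate map over the liver.

    ``mean_pct`` averages rr (%) over valid masked voxels.  ``integrated``
    resamples rr/100 onto the standard scoring grid and sums over the
    resampled mask — a dimensionless, volume-weighted functional total.
    """
    if convention not in ("mean_pct", "integrated"):
        raise ValidationError(f"unknown convention {convention!r}")
    if not rr.geometry.matches(mask.geometry):
        raise GeometryError("rr map and mask are on different grids")

    ok = mask.data & rr.valid
    if not ok.any():
        raise ValidationError("no valid voxels inside the mask")

    if convention == "mean_pct":
        return float(rr.data[ok].mean())

    tgt = _standard_geometry(mask, grid_mm)
    frac = np.where(ok, rr.data / 100.0, 0.0)
    frac_std = resample_array(frac, rr.geometry, tgt, order=1, cval=0.0)
    # Riemann sum on the fixed grid: resolution of the source map cancels
    return float(np.sum(frac_std))


def patient_factor(height_m: float, weight_kg: float, liver_volume_ml: float) -> float:
    """Patient-specific factor ``height^0.6 / (weight^0.3 * volume^0.6)``.

    Units are fixed by convention as meters, kilograms and milliliters.
    """
    if height_m <= 0 or weight_kg <= 0 or liver_volume_ml <= 0:
        raise ValidationError("height, weight and liver volume must be positive")
    return height_m**0.6 / (weight_kg**0.3 * liver_volume_ml**0.6)


def melif(f_p: float, rrt1_integrated: float, c: float = MELIF_C) -> float:
    """Final score: ``c * f_p * rrT1_liver`` (integrated convention).

    No clamping is applied: the conventional 20-80 band is a cohort-level
    property, not a per-patient constraint.
    """
    if not (math.isfinite(f_p) and math.isfinite(rrt1_integrated) and math.isfinite(c)):
        raise ValidationError("melif inputs must be finite")
    return c * f_p * rrt1_integrated


def meld(
    bilirubin_mg_dl: float,
    inr: float,
    creatinine_mg_dl: float,
    dialysis: bool = False,
) -> int:
    """UNOS-style MELD score.

    Labs below 1.0 are clamped to 1.0; creatinine is capped at 4.0 (and
    set to 4.0 under dialysis); the log-linear score is rounded to the
    nearest integer and floored at 6.
    """
    if bilirubin_mg_dl <= 0 or inr <= 0 or creatinine_mg_dl <= 0:
        raise ValidationError("laboratory values must be positive")
    bili = max(bilirubin_mg_dl, 1.0)
    inr_c = max(inr, 1.0)
    creat = 4.0 if dialysis else min(max(creatinine_mg_dl, 1.0), 4.0)
    raw = 10.0 * (
        0.957 * math.log(creat) + 0.378 * math.log(bili) + 1.120 * math.log(inr_c) + 0.643
    )
    return max(6, int(round(raw)))


def meld_group(score: int) -> str:
    """Three-group stratification: <=10 normal, 11-18 impaired, >18 severe."""
    if score <= 10:
        return "normal"
    if score <= 18:
        return "impaired"
    return "severe"


def score_patient(
    t1_pre: T1Map,
    t1_post_reg: T1Map,
    mask: LiverMask,
    patient: PatientRecord,
    grid_mm: float = STANDARD_GRID_MM,
    c: float = MELIF_C,
) -> ScoreResult:
    """Compute every per-patient score from registered maps and a record."""
    rr = rr_map(t1_pre, t1_post_reg, mask)
    used = int((mask.data & rr.valid).sum())
    excluded = mask.n_voxels - used
    mean_pct = rrt1_liver(rr, mask, "mean_pct")
    integrated = rrt1_liver(rr, mask, "integrated", grid_mm=grid_mm)
    f_p = patient_factor(patient.height_m, patient.weight_kg, patient.liver_volume_ml)
    m = meld(
        patient.bilirubin_mg_dl, patient.inr, patient.creatinine_mg_dl, patient.dialysis
    )
    return ScoreResult(
        rrt1_mean_pct=mean_pct,
        rrt1_integrated=integrated,
        f_p=f_p,
        melif=melif(f_p, integrated, c=c),
        meld=m,
        meld_group=meld_group(m),
        n_voxels_used=used,
        n_voxels_excluded=excluded,
        n_voxels_clipped=getattr(rr, "n_clipped", 0),
    )
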
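"""Orchestration: configuration, provenance, and the per-patient / cohort
pipeline runs tying simulation, fitting, segmentation, registration,
scoring and cohort statistics together."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .cohortstats import cohort_report
from .errors import MelifError, ValidationError
from .image import B1Map, T1Map, VFASeries
from .register import apply_deformation, register
from .scoring import (
    MELIF_C,
    STANDARD_GRID_MM,
    PatientRecord,
    ScoreResult,
    score_patient,
)
from .segmentation import load_mask, mask_volume_ml
from .t1map import fit_t1_vfa, resample_to

__all__ = ["RunConfig", "Provenance", "run_patient", "run_cohort", "load_config"]

logger = logging.getLogger(__name__)


class RegistrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["none", "rigid", "rigid+bspline"] = "rigid+bspline"
    metric: Literal["mi", "mse", "ncc"] = "mi"
    seed: int = 0


class T1FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    flip_angles_deg: list[float] = [2.0, 15.0]
    tr_ms: float = 5.0
    b1_path: Optional[str] = None


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # either fitted T1 maps ...
    t1_pre_path: Optional[str] = None
    t1_post_path: Optional[str] = None
    # ... or raw VFA series
    vfa_pre_path: Optional[str] = None
    vfa_post_path: Optional[str] = None

    mask_path: Optional[str] = None
    patient_csv: Optional[str] = None
    patient_id: Optional[str] = None
    manifest_path: Optional[str] = None  # cohort mode

    out_dir: str = "melif_out"
    convention: Literal["mean_pct", "integrated"] = "integrated"
    grid_mm: float = STANDARD_GRID_MM
    melif_c: float = MELIF_C
    liver_volume_from_mask: bool = True
    registration: RegistrationConfig = RegistrationConfig()
    t1fit: T1FitConfig = T1FitConfig()
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("grid_mm")
    @classmethod
    def _positive_grid(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("grid_mm must be positive")
        return v


class Provenance:
    """Run metadata: version, config hash, input checksums, timings."""

    def __init__(self, config: RunConfig) -> None:
        self.software_version = __version__
        # out_dir and log level do not affect results, so they stay out of
        # the hash: identical inputs must yield identical score reports
        cfg = config.model_dump(exclude={"out_dir", "log_level"})
        cfg_json = json.dumps(cfg, sort_keys=True)
        self.config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()
        self.input_checksums: dict[str, str] = {}
        self.output_checksums: dict[str, str] = {}
        self.timings_s: dict[str, float] = {}
        self.exclusions: dict[str, int] = {}

    @staticmethod
    def _sha256(path: str | Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    def add_input(self, path: str | Path) -> None:
        self.input_checksums[str(path)] = self._sha256(path)

    def add_output(self, path: str | Path) -> None:
        self.output_checksums[str(path)] = self._sha256(path)

    def to_dict(self) -> dict:
        return {
            "software_version": self.software_version,
            "config_hash": self.config_hash,
            "input_checksums": self.input_checksums,
            "output_checksums": self.output_checksums,
            "timings_s": self.timings_s,
            "exclusions": self.exclusions,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration with strict validation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


class _Timer:
    def __init__(self, prov: Provenance, stage: str) -> None:
        self.prov, self.stage = prov, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.prov.timings_s[self.stage] = time.perf_counter() - self.t0
        return False


def _load_patient(config: RunConfig, liver_volume_ml: float | None) -> PatientRecord:
    if config.patient_csv is None:
        raise ValidationError("patient_csv is required")
    df = pd.read_csv(config.patient_csv)
    if config.patient_id is not None:
        df = df[df["id"].astype(str) == str(config.patient_id)]
    if len(df) != 1:
        raise ValidationError(
            "patient_csv must resolve to exactly one row (use patient_id)"
        )
    row = df.iloc[0]
    return PatientRecord(
        id=str(row["id"]),
        sex=str(row.get("sex", "")),
        age_years=float(row.get("age", row.get("age_years", 0.0)) or 0.0),
        height_m=float(row["height_m"]),
        weight_kg=float(row["weight_kg"]),
        bilirubin_mg_dl=float(row["bilirubin_mg_dl"]),
        inr=float(row["inr"]),
        creatinine_mg_dl=float(row["creatinine_mg_dl"]),
        dialysis=bool(int(row.get("dialysis", 0))),
        liver_volume_ml=(
            liver_volume_ml
            if (liver_volume_ml is not None and config.liver_volume_from_mask)
            else float(row["liver_volume_ml"])
        ),
    )


def _obtain_t1(config: RunConfig, phase: str, prov: Provenance) -> T1Map:
    map_path = getattr(config, f"t1_{phase}_path")
    vfa_path = getattr(config, f"vfa_{phase}_path")
    if map_path is not None:
        prov.add_input(map_path)
        return T1Map.load(map_path)
    if vfa_path is None:
        raise ValidationError(f"neither t1_{phase}_path nor vfa_{phase}_path given")
    prov.add_input(vfa_path)
    series = VFASeries.load(vfa_path)
    series = VFASeries(
        series.volumes, config.t1fit.flip_angles_deg, config.t1fit.tr_ms, series.geometry
    )
    b1 = None
    if config.t1fit.b1_path is not None:
        prov.add_input(config.t1fit.b1_path)
        b1 = resample_to(B1Map.load(config.t1fit.b1_path), series.geometry)
    t1, _ = fit_t1_vfa(series, b1)
    return t1


def run_patient(config: RunConfig) -> tuple[ScoreResult, Provenance]:
    """Run the full per-patient pipeline and write the score report.

    Stages: T1 ingestion or VFA fitting, mask loading, registration of the
    post map onto the pre map, reduction-rate and score computation.
    Outputs (score JSON, rr-map NIfTI, provenance JSON) land in
    ``config.out_dir``; partial outputs are removed on failure.
    """
    prov = Provenance(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with _Timer(prov, "t1_ingest"):
            t1_pre = _obtain_t1(config, "pre", prov)
            t1_post = _obtain_t1(config, "post", prov)

        with _Timer(prov, "mask"):
            if config.mask_path is None:
                raise ValidationError("mask_path is required")
            prov.add_input(config.mask_path)
            mask = load_mask(config.mask_path, expected=t1_pre.geometry)
            vol_ml = mask_volume_ml(mask)

        with _Timer(prov, "register"):
            if config.registration.mode == "none":
                if not t1_post.geometry.matches(t1_pre.geometry):
                    t1_post_reg = resample_to(t1_post, t1_pre.geometry)
                else:
                    t1_post_reg = t1_post
            else:
                field, diag = register(
                    t1_pre,
                    t1_post,
                    mode=config.registration.mode,
                    metric=config.registration.metric,
                    seed=config.registration.seed,
                )
                t1_post_reg = apply_deformation(t1_post, field)
                prov.exclusions["post_voxels_out_of_field"] = int(
                    (~t1_post_reg.valid).sum() - (~t1_post.valid).sum()
                )

        with _Timer(prov, "score"):
            patient = _load_patient(config, vol_ml)
            prov.add_input(config.patient_csv)
            result = score_patient(
                t1_pre, t1_post_reg, mask, patient,
                grid_mm=config.grid_mm, c=config.melif_c,
            )
            prov.exclusions["masked_voxels_excluded"] = result.n_voxels_excluded

        rr_path = out / f"{patient.id}_rr.nii.gz"
        from .scoring import rr_map as _rr

        _rr(t1_pre, t1_post_reg, mask).save(rr_path)
        written.append(rr_path)

        score_path = out / f"{patient.id}_score.json"
        payload = {
            "patient": patient.to_dict(),
            "scores": result.to_dict(),
            "provenance_ref": f"{patient.id}_provenance.json",
            "grid_mm": config.grid_mm,
            "convention": config.convention,
            "software_version": __version__,
            "config_hash": prov.config_hash,
            "inputs": sorted(prov.input_checksums),
        }
        with open(score_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        written.append(score_path)

        for p in written:
            prov.add_output(p)
        prov_path = out / f"{patient.id}_provenance.json"
        with open(prov_path, "w") as fh:
            json.dump(prov.to_dict(), fh, indent=2, sort_keys=True)
        return result, prov
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run every patient of a cohort manifest and build the report bundle.

    Individual patient failures are logged and excluded; the run only
    fails if no patient succeeds.
    """
    if config.manifest_path is None:
        raise ValidationError("manifest_path is required for cohort runs")
    with open(config.manifest_path) as fh:
        manifest = json.load(fh)
    patients = manifest.get("patients", [])
    if not patients:
        raise ValidationError("manifest lists no patients")

    rows = []
    failures = 0
    for entry in patients:
        pconf = config.model_copy(
            update={
                "t1_pre_path": entry.get("t1_pre"),
                "t1_post_path": entry.get("t1_post"),
                "vfa_pre_path": entry.get("vfa_pre"),
                "vfa_post_path": entry.get("vfa_post"),
                "mask_path": entry["mask"],
                "patient_csv": manifest["cohort_csv"],
                "patient_id": entry["id"],
                "manifest_path": None,
                "out_dir": str(Path(config.out_dir) / "patients"),
            }
        )
        try:
            result, _ = run_patient(pconf)
        except (MelifError, OSError) as exc:
            failures += 1
            logger.warning("patient %s failed: %s", entry["id"], exc)
            continue
        rows.append(
            {
                "id": entry["id"],
                "meld": result.meld,
                "meld_group": result.meld_group,
                "melif": result.melif,
                "rrt1_mean_pct": result.rrt1_mean_pct,
                "rrt1_integrated": result.rrt1_integrated,
                "f_p": result.f_p,
            }
        )
    if not rows:
        raise MelifError(f"all {failures} patients failed")
    if failures:
        logger.warning("%d of %d patients excluded", failures, len(patients))

    table = pd.DataFrame(rows)
    demo = pd.read_csv(manifest["cohort_csv"])
    table = table.merge(demo.drop(columns=["dialysis"], errors="ignore"), on="id", how="left")
    report = cohort_report(table, out_dir=Path(config.out_dir) / "report")
    table.to_csv(Path(config.out_dir) / "cohort_table.csv", index=False)
    return table, report
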
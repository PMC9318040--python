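"""Synthetic liver phantoms: patients, geometries, paired pre/post-contrast
T1 maps with regional uptake, inter-phase deformation, and raw VFA series.

The forward model is deliberately simple and analytically invertible:
post-contrast T1 is ``t1_pre * (1 - uptake)``, so the voxel-wise T1
reduction rate equals the uptake fraction times 100 exactly, giving every
downstream stage an exact ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GeometryError, ValidationError
from .image import DeformationField, Geometry, LiverMask, T1Map, VFASeries, Volume, B1Map
from .scoring import PatientRecord, meld, meld_group

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_patient",
    "make_ground_truth",
    "synthesize_vfa",
    "make_cohort",
    "DEFAULT_GROUP_UPTAKE",
]

#: Group-level mean fractional uptake, calibrated so that cohort rrT1
#: percentages approximate the published per-group means (54/43/31%).
DEFAULT_GROUP_UPTAKE = {"normal": 0.54, "impaired": 0.43, "severe": 0.31}
DEFAULT_GROUP_UPTAKE_SD = {"normal": 0.10, "impaired": 0.11, "severe": 0.12}

# Log-normal lab centers per MELD group (bilirubin mg/dL, INR, creatinine
# mg/dL); chosen so rejection sampling lands in each group's MELD band
# quickly.  Clinical plausibility only — no published distributions exist.
_LAB_CENTERS = {
    "normal": (0.8, 1.05, 0.9),
    "impaired": (2.2, 1.45, 1.25),
    "severe": (5.5, 2.1, 1.9),
}
_LAB_SPREADS = {
    "normal": (0.35, 0.05, 0.20),
    "impaired": (0.45, 0.12, 0.30),
    "severe": (0.45, 0.18, 0.40),
}
_LIVER_VOLUME = {"normal": (1560.0, 330.0), "impaired": (1450.0, 360.0), "severe": (1150.0, 280.0)}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (3.5, 3.5, 3.5)
    field_strength_T: float = 3.0
    t1_liver_baseline_ms: float = 800.0
    t1_background_ms: float = 350.0
    uptake_mean: float = 0.5
    uptake_sd: float = 0.05
    uptake_texture_scale_mm: float = 20.0
    deformation_amplitude_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValidationError("voxel spacings must be positive")
        if not (0.0 <= self.uptake_mean < 1.0):
            raise ValidationError("uptake_mean must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )

    @property
    def geometry(self) -> Geometry:
        aff = np.diag(list(self.voxel_spacing_mm) + [1.0])
        return Geometry(self.grid_shape, aff)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Noise-free truth for one phantom patient."""

    t1_pre: T1Map
    t1_post: T1Map
    uptake_field: np.ndarray
    deformation: DeformationField | None
    mask: LiverMask
    patient: PatientRecord


def make_patient(group: str, seed: int) -> PatientRecord:
    """Sample a patient whose computed MELD falls in the requested group.

    Anthropometrics follow the published cohort (height 1.7 +- 0.08 m,
    weight 83 +- 16 kg, age 62 +- 11 y, 79% male); labs are log-normal
    around group-specific centers, rejection-sampled into the MELD band.
    """
    if group not in _LAB_CENTERS:
        raise ValidationError(f"unknown MELD group {group!r}")
    rng = np.random.default_rng(seed)

    height = float(np.clip(rng.normal(1.70, 0.08), 1.45, 2.05))
    weight = float(np.clip(rng.normal(83.0, 16.0), 45.0, 160.0))
    age = float(np.clip(rng.normal(62.0, 11.0), 18.0, 95.0))
    sex = "M" if rng.random() < 0.79 else "F"
    vol_mu, vol_sd = _LIVER_VOLUME[group]
    # upper clip keeps the largest livers voxelizable on the default grids
    volume = float(np.clip(rng.normal(vol_mu, vol_sd), 700.0, 2200.0))

    centers, spreads = _LAB_CENTERS[group], _LAB_SPREADS[group]
    for _ in range(1000):
        bili, inr, creat = (
            float(np.exp(rng.normal(np.log(mu), sd)))
            for mu, sd in zip(centers, spreads)
        )
        if meld_group(meld(bili, inr, creat, False)) == group:
            return PatientRecord(
                id=f"{group[:3]}-{seed:06d}",
                sex=sex,
                age_years=age,
                height_m=height,
                weight_kg=weight,
                bilirubin_mg_dl=bili,
                inr=inr,
                creatinine_mg_dl=creat,
                dialysis=False,
                liver_volume_ml=volume,
            )
    raise ValidationError(
        f"could not sample labs reaching MELD group {group!r} in 1000 attempts"
    )


def _correlated_field(
    shape: tuple[int, ...], spacing: np.ndarray, scale_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with given correlation length."""
    noise = rng.standard_normal(shape)
    sigma_vox = np.maximum(scale_mm / spacing, 0.5)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _liver_indicator(geometry: Geometry, scale: float) -> np.ndarray:
    """Union-of-ellipsoids liver silhouette at a global size scale (mm units)."""
    center = geometry.voxel_to_world((np.asarray(geometry.shape) - 1) / 2.0)
    grid = geometry.world_grid() - center
    # main right lobe + smaller left lobe, semi-axes in mm at scale=1
    lobes = [
        (np.array([6.0, 0.0, 0.0]), np.array([64.0, 56.0, 48.0])),
        (np.array([-40.0, 14.0, 6.0]), np.array([34.0, 28.0, 23.0])),
    ]
    inside = np.zeros(geometry.shape, dtype=bool)
    for offset, axes in lobes:
        d = (grid - offset * scale) / (axes * scale)
        inside |= (d**2).sum(axis=-1) <= 1.0
    return inside


def _fit_liver_mask(geometry: Geometry, target_ml: float) -> np.ndarray:
    """Bisect the global scale so the voxelized volume is within 2% of target."""
    voxvol = geometry.voxel_volume_mm3
    lo, hi = 0.2, 2.5
    if _liver_indicator(geometry, hi).sum() * voxvol / 1000.0 < target_ml:
        raise GeometryError("liver volume not realizable on this grid")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        vol = _liver_indicator(geometry, mid).sum() * voxvol / 1000.0
        if abs(vol - target_ml) / target_ml <= 0.02:
            break
        if vol < target_ml:
            lo = mid
        else:
            hi = mid
    mask = _liver_indicator(geometry, 0.5 * (lo + hi))
    vol = mask.sum() * voxvol / 1000.0
    if abs(vol - target_ml) / target_ml > 0.02:
        raise GeometryError(
            f"could not voxelize a {target_ml:.0f} mL liver within 2% on this grid"
        )
    # keep shape fully inside the grid with a one-voxel margin
    edge = np.zeros(geometry.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        edge[tuple(sl)] = True
        sl[ax] = -1
        edge[tuple(sl)] = True
    if (mask & edge).any():
        raise GeometryError("liver touches the grid boundary; enlarge the grid")
    return mask


def _sample_displacement(
    geometry: Geometry, amplitude_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement (mm), max magnitude == amplitude.

    Built from coarse control-point perturbations upsampled by cubic
    interpolation; amplitude is kept below half the control spacing, so the
    warp stays diffeomorphic.
    """
    shape = geometry.shape
    ctrl_shape = tuple(max(4, s // 16) for s in shape)
    ctrl = rng.standard_normal(ctrl_shape + (3,))
    vary = np.stack(
        [
            ndimage.zoom(ctrl[..., d], np.array(shape) / np.array(ctrl_shape), order=3)
            for d in range(3)
        ],
        axis=-1,
    )
    mag = np.linalg.norm(vary, axis=-1).max()
    if mag > 0:
        vary *= 0.25 * amplitude_mm / mag
    # bulk quasi-respiratory shift plus a varying elastic component; the
    # triangle inequality keeps the total magnitude <= amplitude
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    disp = vary + 0.75 * amplitude_mm * direction
    excess = np.linalg.norm(disp, axis=-1).max()
    if excess > amplitude_mm:
        disp *= amplitude_mm / excess
    return disp


def _invert_displacement(disp: np.ndarray, geometry: Geometry, n_iter: int = 8) -> np.ndarray:
    """Fixed-point inverse of a small smooth displacement field (mm)."""
    inv_lin = np.linalg.inv(geometry.affine[:3, :3])
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in geometry.shape], indexing="ij"), axis=-1)
    inv = -disp
    for _ in range(n_iter):
        coords = idx + inv @ inv_lin.T  # voxel coords of x + inv(x)
        sampled = np.stack(
            [
                ndimage.map_coordinates(
                    disp[..., d], np.moveaxis(coords, -1, 0), order=1, mode="nearest"
                )
                for d in range(3)
            ],
            axis=-1,
        )
        inv = -sampled
    return inv


def _warp(data: np.ndarray, disp_mm: np.ndarray, geometry: Geometry, order: int = 1) -> np.ndarray:
    """Sample ``data`` at ``x + disp(x)`` (world mm), on its own grid."""
    inv_lin = np.linalg.inv(geometry.affine[:3, :3])
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in geometry.shape], indexing="ij"), axis=-1)
    coords = idx + disp_mm @ inv_lin.T
    return ndimage.map_coordinates(
        data, np.moveaxis(coords, -1, 0), order=order, mode="nearest"
    )


def make_ground_truth(spec: PhantomSpec, patient: PatientRecord) -> GroundTruth:
    """Build the noise-free truth volumes for one patient.

    The stored deformation maps the post grid onto the pre grid: applying
    it to ``t1_post`` approximately recovers the undeformed reduced map.
    """
    geometry = spec.geometry
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing_mm)

    mask = _fit_liver_mask(geometry, patient.liver_volume_ml)

    # native T1 with mild correlated texture (vessels/inhomogeneity stand-in)
    tex_liver = _correlated_field(geometry.shape, spacing, spec.uptake_texture_scale_mm, rng)
    tex_bg = _correlated_field(geometry.shape, spacing, spec.uptake_texture_scale_mm, rng)
    t1_pre = np.where(
        mask,
        spec.t1_liver_baseline_ms * (1.0 + 0.08 * tex_liver),
        spec.t1_background_ms * (1.0 + 0.05 * tex_bg),
    )
    t1_pre = np.clip(t1_pre, 50.0, 4500.0)

    uptake = np.zeros(geometry.shape)
    if spec.uptake_mean > 0:
        fluct = _correlated_field(geometry.shape, spacing, spec.uptake_texture_scale_mm, rng)
        u = np.clip(spec.uptake_mean + spec.uptake_sd * fluct, 0.0, 0.95)
        uptake[mask] = u[mask]

    reduced = t1_pre * (1.0 - uptake)

    deformation = None
    t1_post = reduced
    if spec.deformation_amplitude_mm > 0:
        disp = _sample_displacement(geometry, spec.deformation_amplitude_mm, rng)
        inv = _invert_displacement(disp, geometry)
        t1_post = _warp(reduced, inv, geometry, order=3)
        deformation = DeformationField(disp, geometry)

    return GroundTruth(
        t1_pre=T1Map(t1_pre, geometry),
        t1_post=T1Map(t1_post, geometry),
        uptake_field=uptake,
        deformation=deformation,
        mask=LiverMask(mask, geometry),
        patient=patient,
    )


def synthesize_vfa(
    t1_truth: T1Map,
    m0: Volume | np.ndarray | float,
    flip_angles_deg: list[float],
    tr_ms: float,
    b1: B1Map | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VFASeries:
    """Forward-simulate an SPGR magnitude series from a T1 map.

    Per voxel and angle: ``S = M0 sin(a_eff) (1-E1)/(1 - E1 cos(a_eff))``
    with ``E1 = exp(-TR/T1)`` and ``a_eff = b1 * a``.  ``noise_sd`` is the
    Rician noise parameter in the same (arbitrary) units as ``m0``.
    """
    angles = [float(a) for a in flip_angles_deg]
    if len(set(angles)) < 2:
        raise ConfigurationError("need at least 2 distinct flip angles")
    if tr_ms <= 0:
        raise ConfigurationError("tr_ms must be positive")

    geometry = t1_truth.geometry
    t1 = np.where(t1_truth.valid & (t1_truth.data > 0), t1_truth.data, np.inf)
    if isinstance(m0, Volume):
        m0_arr = m0.data
    else:
        m0_arr = np.broadcast_to(np.asarray(m0, dtype=float), geometry.shape)
    b1_arr = b1.data if b1 is not None else np.ones(geometry.shape)

    e1 = np.exp(-tr_ms / t1)
    rng = np.random.default_rng(seed)
    vols = np.empty((len(angles),) + geometry.shape)
    for i, a in enumerate(angles):
        a_eff = np.deg2rad(a) * b1_arr
        s = m0_arr * np.sin(a_eff) * (1.0 - e1) / (1.0 - e1 * np.cos(a_eff))
        if noise_sd > 0:
            s = np.sqrt(
                (s + rng.normal(0.0, noise_sd, s.shape)) ** 2
                + rng.normal(0.0, noise_sd, s.shape) ** 2
            )
        vols[i] = np.abs(s)
    return VFASeries(vols, tuple(angles), tr_ms, geometry)


def make_cohort(
    n_per_group: dict[str, int],
    spec: PhantomSpec,
    out_dir: str | Path,
    seed: int = 0,
    mode: str = "t1maps",
    group_uptake: dict[str, float] | None = None,
    vfa_angles_deg: tuple[float, ...] = (2.0, 15.0),
    vfa_tr_ms: float = 5.0,
    write_volumes: bool = True,
) -> dict:
    """Generate a whole phantom cohort on disk and return its manifest.

    Writes, per patient, a subdirectory with NIfTI volumes (T1 maps or raw
    VFA series per ``mode``) plus the mask, a ``cohort.csv`` of patient
    records, and a ``manifest.json``.  Group uptake means default to the
    calibrated severity ordering.
    """
    if mode not in ("t1maps", "vfa"):
        raise ConfigurationError(f"unknown cohort mode {mode!r}")
    if any(n < 0 for n in n_per_group.values()):
        raise ValidationError("group counts must be nonnegative")
    uptake_means = dict(DEFAULT_GROUP_UPTAKE, **(group_uptake or {}))

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    entries: list[dict] = []
    for group in ("normal", "impaired", "severe"):
        for i in range(int(n_per_group.get(group, 0))):
            pseed = int(rng.integers(0, 2**31 - 1))
            patient = make_patient(group, pseed)
            patient.id = f"{group[:3]}-{len(rows):04d}"
            u_mean = float(
                np.clip(
                    rng.normal(uptake_means[group], DEFAULT_GROUP_UPTAKE_SD[group]),
                    0.05,
                    0.90,
                )
            )
            pspec = PhantomSpec(
                **{**spec.to_dict(), "uptake_mean": u_mean, "seed": pseed}
            )
            truth = make_ground_truth(pspec, patient)
            entry = {
                "id": patient.id,
                "group": group,
                "seed": pseed,
                "uptake_mean": u_mean,
                "mean_uptake_in_mask": float(truth.uptake_field[truth.mask.data].mean()),
            }
            if write_volumes:
                pdir = out / patient.id
                pdir.mkdir(exist_ok=True)
                truth.mask.save(pdir / "mask.nii.gz")
                noise_rng = np.random.default_rng(pseed + 1)
                if mode == "t1maps":
                    _save_t1(truth.t1_pre, pdir / "t1_pre.nii.gz", spec.noise_sd, noise_rng)
                    _save_t1(truth.t1_post, pdir / "t1_post.nii.gz", spec.noise_sd, noise_rng)
                    entry["t1_pre"] = str(pdir / "t1_pre.nii.gz")
                    entry["t1_post"] = str(pdir / "t1_post.nii.gz")
                else:
                    scale = 1000.0
                    for phase, t1m in (("pre", truth.t1_pre), ("post", truth.t1_post)):
                        series = synthesize_vfa(
                            t1m, scale, list(vfa_angles_deg), vfa_tr_ms,
                            noise_sd=spec.noise_sd * scale, seed=pseed + (2 if phase == "pre" else 3),
                        )
                        series.save(pdir / f"vfa_{phase}.nii.gz")
                        entry[f"vfa_{phase}"] = str(pdir / f"vfa_{phase}.nii.gz")
                entry["mask"] = str(pdir / "mask.nii.gz")
                if truth.deformation is not None:
                    truth.deformation.save(pdir / "deformation.nii.gz")
                    entry["deformation"] = str(pdir / "deformation.nii.gz")
            rows.append(
                {
                    "id": patient.id,
                    "sex": patient.sex,
                    "age": round(patient.age_years, 1),
                    "height_m": round(patient.height_m, 3),
                    "weight_kg": round(patient.weight_kg, 1),
                    "bilirubin_mg_dl": round(patient.bilirubin_mg_dl, 3),
                    "inr": round(patient.inr, 3),
                    "creatinine_mg_dl": round(patient.creatinine_mg_dl, 3),
                    "dialysis": int(patient.dialysis),
                    "liver_volume_ml": round(patient.liver_volume_ml, 1),
                }
            )
            entries.append(entry)

    csv_path = out / "cohort.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=[
                "id", "sex", "age", "height_m", "weight_kg", "bilirubin_mg_dl",
                "inr", "creatinine_mg_dl", "dialysis", "liver_volume_ml",
            ],
        )
        writer.writeheader()
        writer.writerows(rows)

    manifest = {
        "seed": seed,
        "mode": mode,
        "spec": spec.to_dict(),
        "cohort_csv": str(csv_path),
        "patients": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _save_t1(t1m: T1Map, path: Path, noise_sd: float, rng: np.random.Generator) -> None:
    if noise_sd > 0:
        data = t1m.data * (1.0 + rng.normal(0.0, noise_sd, t1m.data.shape))
        T1Map(np.clip(data, 1.0, 5000.0), t1m.geometry, t1m.valid).save(path)
    else:
        t1m.save(path)
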
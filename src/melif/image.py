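"""Core image containers: geometry, scalar volumes, masks, vector fields.

All volumes are 3-D arrays indexed ``[i, j, k]`` (0-based voxel indices);
world coordinates (mm) are obtained through a NIfTI-style 4x4 affine.
Invalid voxels of quantitative maps are stored as NaN on disk and as an
explicit boolean ``valid`` array in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError

__all__ = [
    "Geometry",
    "Volume",
    "T1Map",
    "B1Map",
    "LiverMask",
    "RRMap",
    "DeformationField",
    "VFASeries",
    "resample_array",
]


@dataclass(frozen=True)
class Geometry:
    """Voxel grid: shape plus a 4x4 voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise GeometryError(f"expected a 3-D grid, got shape {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def matches(self, other: "Geometry", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    @staticmethod
    def isotropic(shape: Sequence[int], spacing_mm: float | Sequence[float]) -> "Geometry":
        sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
        aff = np.diag([sp[0], sp[1], sp[2], 1.0])
        return Geometry(tuple(int(s) for s in shape), aff)


def resample_array(
    data: np.ndarray,
    src: Geometry,
    tgt: Geometry,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``data`` from geometry ``src`` onto geometry ``tgt``."""
    m = np.linalg.inv(src.affine) @ tgt.affine
    return ndimage.affine_transform(
        np.asarray(data, dtype=float),
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=tgt.shape,
        order=order,
        cval=cval,
        mode="constant",
    )


@dataclass
class Volume:
    """Plain scalar volume."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise GeometryError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.geometry.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.dataobj, dtype=float))
        return cls(data, Geometry(data.shape, np.asarray(img.affine)))


@dataclass
class _MaskedMap:
    """Scalar map with an explicit fit/validity mask (NaN sentinel on disk)."""

    data: np.ndarray
    geometry: Geometry
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise GeometryError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.data)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise GeometryError("valid-mask shape mismatch")

    def save(self, path: str | Path) -> None:
        out = np.where(self.valid, self.data, np.nan)
        nib.save(nib.Nifti1Image(out.astype(np.float64), self.geometry.affine), str(path))

    @classmethod
    def load(cls, path: str | Path):
        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.dataobj, dtype=float))
        return cls(data, Geometry(data.shape, np.asarray(img.affine)))


@dataclass
class T1Map(_MaskedMap):
    """Voxel-wise T1 relaxation times in milliseconds."""


@dataclass
class RRMap(_MaskedMap):
    """Voxel-wise T1 reduction rate in percent, on the pre-contrast grid."""


@dataclass
class B1Map:
    """Relative flip-angle scale (dimensionless, ~1.0)."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise GeometryError("B1 data/geometry shape mismatch")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() <= 0 or finite.max() > 2.0):
            raise ValueError("relative B1 values must lie in (0, 2]")

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.geometry.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "B1Map":
        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.dataobj, dtype=float))
        return cls(data, Geometry(data.shape, np.asarray(img.affine)))


@dataclass
class LiverMask:
    """Binary liver mask."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.shape != self.geometry.shape:
            raise GeometryError("mask data/geometry shape mismatch")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def save(self, path: str | Path) -> None:
        nib.save(
            nib.Nifti1Image(self.data.astype(np.uint8), self.geometry.affine), str(path)
        )

    @classmethod
    def load(cls, path: str | Path) -> "LiverMask":
        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.dataobj))
        return cls(data, Geometry(data.shape, np.asarray(img.affine)))


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm) on the fixed grid, shape (*shape, 3)."""

    disp: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.shape != self.geometry.shape + (3,):
            raise GeometryError(
                f"displacement shape {self.disp.shape} != {self.geometry.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.disp, axis=-1)

    def save(self, path: str | Path) -> None:
        nib.save(
            nib.Nifti1Image(self.disp.astype(np.float64), self.geometry.affine), str(path)
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        img = nib.load(str(path))
        disp = np.asarray(img.dataobj, dtype=float)
        return cls(disp, Geometry(disp.shape[:3], np.asarray(img.affine)))


@dataclass
class VFASeries:
    """Co-registered SPGR magnitude volumes, one per nominal flip angle."""

    volumes: np.ndarray  # (n_angles, *shape)
    flip_angles_deg: tuple[float, ...]
    tr_ms: float
    geometry: Geometry = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.flip_angles_deg = tuple(float(a) for a in self.flip_angles_deg)
        if self.volumes.ndim != 4 or self.volumes.shape[0] != len(self.flip_angles_deg):
            raise GeometryError("volumes must be (n_angles, nx, ny, nz)")
        if len(set(self.flip_angles_deg)) < 2:
            raise ValueError("need >= 2 distinct flip angles")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.geometry is None:
            self.geometry = Geometry.isotropic(self.volumes.shape[1:], 1.0)
        if self.volumes.shape[1:] != self.geometry.shape:
            raise GeometryError("series volumes do not match geometry")

    def save(self, path: str | Path) -> None:
        """Save as a 4-D NIfTI (last axis = flip angle); angles/TR in the header
        description field."""
        img = nib.Nifti1Image(
            np.moveaxis(self.volumes, 0, -1).astype(np.float64), self.geometry.affine
        )
        desc = f"fa={','.join(str(a) for a in self.flip_angles_deg)};tr={self.tr_ms}"
        img.header["descrip"] = desc.encode()[:79]
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VFASeries":
        img = nib.load(str(path))
        desc = bytes(img.header["descrip"]).decode(errors="ignore").rstrip("\x00")
        fields = dict(part.split("=") for part in desc.split(";") if "=" in part)
        angles = tuple(float(a) for a in fields["fa"].split(","))
        tr = float(fields["tr"])
        data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        return cls(data, angles, tr, Geometry(data.shape[1:], np.asarray(img.affine)))
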
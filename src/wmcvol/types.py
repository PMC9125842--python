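"""Core volumetric containers: scalar images, binary masks, per-subject volumes.

All segmentation operates in voxel space (0-based indices); the affine is
carried along for NIfTI round-trips and world-coordinate reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "BinaryMask", "LesionVolumes", "check_aligned"]


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class VolumeImage:
    """A 3D scalar grid (FLAIR-like intensities) with voxel spacing in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        return VolumeImage(values, self.voxel_size, self.affine)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), zooms, np.asarray(img.affine))


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned to a parent image."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def count(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.voxel_size, self.affine)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        check_aligned(self, other)
        return self.with_values(self.values & other.values)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        check_aligned(self, other)
        return self.with_values(self.values | other.values)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        check_aligned(self, other)
        return self.with_values(self.values & ~other.values)

    def __invert__(self) -> "BinaryMask":
        return self.with_values(~self.values)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.uint8), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj) > 0, zooms, np.asarray(img.affine))


def check_aligned(*grids: VolumeImage | BinaryMask) -> None:
    """Raise if any pair of grids differs in shape, spacing or affine."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ValueError(f"misaligned grids: shape {g.shape} != {ref.shape}")
        if not np.allclose(g.voxel_size, ref.voxel_size):
            raise ValueError(
                f"misaligned grids: voxel_size {g.voxel_size} != {ref.voxel_size}"
            )
        if not np.allclose(g.affine, ref.affine):
            raise ValueError("misaligned grids: affines differ")


@dataclass
class LesionVolumes:
    """Compartment volumes in ml for one subject.

    Total WMC is by construction the sum of the periventricular (PVH) and
    deep (DWMH) compartments: deep volume is what remains of total WMC after
    the periventricular part is taken out.
    """

    total_wmc_ml: float
    pvh_ml: float
    dwmh_ml: float
    ventricles_ml: float

    def __post_init__(self) -> None:
        for name in ("total_wmc_ml", "pvh_ml", "dwmh_ml", "ventricles_ml"):
            v = float(getattr(self, name))
            setattr(self, name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if abs(self.total_wmc_ml - (self.pvh_ml + self.dwmh_ml)) > 1e-9:
            raise ValueError(
                "total_wmc_ml must equal pvh_ml + dwmh_ml "
                f"({self.total_wmc_ml} != {self.pvh_ml} + {self.dwmh_ml})"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "total_wmc_ml": self.total_wmc_ml,
            "pvh_ml": self.pvh_ml,
            "dwmh_ml": self.dwmh_ml,
            "ventricles_ml": self.ventricles_ml,
        }
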
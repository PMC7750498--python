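"""Core image containers: SUV volumes, binary region masks, histology slice sets.

All grids are plain numpy arrays on an isotropic voxel lattice. World
coordinates are anchored at voxel centers: the center of voxel ``k`` along an
axis sits at ``k * voxel_size_mm`` (0-based indices). Axis order is (x, y, z);
axis 2 is the cranio-caudal (slice) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["SUVVolume", "RegionMask", "HistoSliceSet", "GridInfo"]

#: Region roles a mask may carry.
ROLES = ("prostate", "specimen", "histo_gtv", "pet_gtv", "truth_tumor")


@dataclass(frozen=True)
class GridInfo:
    """Shape + spacing descriptor for a voxel lattice."""

    shape: tuple[int, int, int]
    voxel_size_mm: float

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def z_mm(self, k: int) -> float:
        """World Z coordinate (mm) of the center of slice ``k``."""
        return k * self.voxel_size_mm


@dataclass
class SUVVolume:
    """3-D grid of standardized uptake values (body-weight normalized, unitless).

    SUV is non-negative by definition; NaN/inf values are rejected.
    """

    grid: np.ndarray
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("SUV grid must be 3-D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("SUV grid contains non-finite values")
        if np.any(self.grid < 0):
            raise ValueError("SUV values must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")

    @property
    def info(self) -> GridInfo:
        return GridInfo(self.grid.shape, self.voxel_size_mm)


@dataclass
class RegionMask:
    """Binary region on a voxel lattice with a semantic role.

    Roles: ``prostate`` (whole gland), ``specimen`` (portion covered by
    histology step sections), ``histo_gtv`` (histology tumor reference),
    ``pet_gtv`` (PET-derived contour), ``truth_tumor`` (phantom ground truth).
    """

    grid: np.ndarray
    voxel_size_mm: float = 2.0
    role: str = "pet_gtv"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("region mask must be 3-D")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    @property
    def info(self) -> GridInfo:
        return GridInfo(self.grid.shape, self.voxel_size_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.info.voxel_volume_ml

    def with_grid(self, grid: np.ndarray, role: str | None = None) -> "RegionMask":
        return RegionMask(grid, self.voxel_size_mm, role or self.role)

    def issubset(self, other: "RegionMask") -> bool:
        _check_aligned(self, other)
        return bool(np.all(~self.grid | other.grid))


@dataclass
class HistoSliceSet:
    """Sparse per-slice 2-D tumor contours at fixed physical slice spacing.

    Each entry is ``(z_mm, mask2d)`` where ``z_mm`` is the physical position of
    the section plane and ``mask2d`` a binary in-plane mask. Slice positions
    must be strictly increasing and, when more than one slice is present,
    consecutively ``slice_step_mm`` apart (whole-mount step sections are cut at
    a fixed step).
    """

    slices: list[tuple[float, np.ndarray]]
    slice_step_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.slice_step_mm <= 0:
            raise ValueError("slice_step_mm must be > 0")
        cleaned: list[tuple[float, np.ndarray]] = []
        shape = None
        for z, m in self.slices:
            m = np.asarray(m).astype(bool)
            if m.ndim != 2:
                raise ValueError("histo slice masks must be 2-D")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("all histo slice masks must share an in-plane shape")
            cleaned.append((float(z), m))
        self.slices = cleaned
        zs = [z for z, _ in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("histo slice z positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def z_positions_mm(self) -> list[float]:
        return [z for z, _ in self.slices]

    def validate_spacing(self, tol_mm: float) -> None:
        """Require consecutive slices to sit one nominal step apart (± tol)."""
        zs = self.z_positions_mm
        for a, b in zip(zs, zs[1:]):
            if abs((b - a) - self.slice_step_mm) > tol_mm:
                raise ValueError(
                    f"slices at z={a} and z={b} mm are {b - a:.2f} mm apart; "
                    f"expected {self.slice_step_mm} mm (tolerance {tol_mm} mm)"
                )


def _check_aligned(*objs: SUVVolume | RegionMask) -> None:
    """Raise if grids differ in shape or spacing."""
    first = objs[0]
    for o in objs[1:]:
        if o.grid.shape != first.grid.shape:
            raise ValueError(
                f"grid shape mismatch: {o.grid.shape} vs {first.grid.shape}"
            )
        if not np.isclose(o.voxel_size_mm, first.voxel_size_mm):
            raise ValueError(
                f"voxel size mismatch: {o.voxel_size_mm} vs {first.voxel_size_mm}"
            )
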
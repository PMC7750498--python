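"""3-D histology reference construction from sparse whole-mount slices.

Whole-mount step sections are cut every 4 mm; each section's tumor contour is
expanded 2 mm in both Z directions to form a slab, and the union of slabs is
the 3-D histology reference volume (GTV-Histo). Slabs are half-open,
``[z - step/2, z + step/2)``, so consecutively stepped sections tile the Z
axis with neither gaps nor double assignment. No in-plane interpolation is
performed between sections.
"""

from __future__ import annotations

import numpy as np

from .grids import GridInfo, HistoSliceSet, RegionMask, _check_aligned

__all__ = ["build_histo_model", "trim_to_region", "volume_ml"]


def build_histo_model(slices: HistoSliceSet, target_grid: GridInfo) -> RegionMask:
    """Expand per-slice contours into Z slabs and union them on a 3-D grid.

    Each slice at physical position ``z`` fills every voxel layer whose
    center lies in the half-open slab ``[z - h, z + h)`` with
    ``h = slice_step_mm / 2``. Voxel-layer centers sit at
    ``k * voxel_size_mm`` (0-based ``k``).

    Raises if a slice plane falls outside the grid's Z range, if the in-plane
    shape does not match the grid, or if slices are mis-spaced so that slabs
    would overlap.
    """
    if len(slices) == 0:
        raise ValueError("histo slice set is empty")
    nz = target_grid.shape[2]
    dz = target_grid.voxel_size_mm
    half = slices.slice_step_mm / 2.0
    step_ratio = slices.slice_step_mm / dz
    if abs(step_ratio - round(step_ratio)) > 1e-9:
        raise ValueError(
            f"grid Z spacing {dz} mm must divide the slice step "
            f"{slices.slice_step_mm} mm"
        )
    # Mis-spaced slices would assign one layer twice; reject them up front.
    slices.validate_spacing(tol_mm=dz / 2.0)

    out = np.zeros(target_grid.shape, dtype=bool)
    assigned = np.zeros(nz, dtype=bool)
    for z, mask2d in slices.slices:
        if mask2d.shape != target_grid.shape[:2]:
            raise ValueError(
                f"slice at z={z} mm has in-plane shape {mask2d.shape}, "
                f"expected {target_grid.shape[:2]}"
            )
        if not (-half <= z < (nz - 1) * dz + half):
            raise ValueError(
                f"slice plane at z={z} mm lies outside the grid Z range "
                f"[0, {(nz - 1) * dz}] mm"
            )
        # Layers k with z - half <= k*dz < z + half.
        k_lo = int(np.ceil((z - half) / dz - 1e-9))
        k_hi = int(np.ceil((z + half) / dz - 1e-9))  # exclusive
        k_lo, k_hi = max(k_lo, 0), min(k_hi, nz)
        for k in range(k_lo, k_hi):
            if assigned[k]:
                raise ValueError(
                    f"slab of slice at z={z} mm overlaps a previously "
                    f"assigned layer (k={k})"
                )
            assigned[k] = True
            out[:, :, k] |= mask2d
    return RegionMask(out, target_grid.voxel_size_mm, "histo_gtv")


def trim_to_region(mask: RegionMask, region: RegionMask) -> RegionMask:
    """Voxelwise intersection of ``mask`` with ``region``; role is kept.

    This is the study's trimming rule: contours are restricted to the
    prostatic gland and, for histology-referenced analyses, to the part of
    the gland covered by the examined specimen.
    """
    _check_aligned(mask, region)
    return mask.with_grid(mask.grid & region.grid)


def volume_ml(mask: RegionMask) -> float:
    """Mask volume in ml: voxel count times voxel volume."""
    return mask.volume_ml
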
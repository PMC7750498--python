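"""NIfTI persistence for phantom datasets, masks and SUV volumes.

Grids are written as NIfTI-1 with a diagonal affine carrying the isotropic
voxel size; masks as uint8, SUV as float64 (lossless round trip). A JSON
sidecar stores the generating spec, the realized geometry and the histology
slice positions so a dataset can be reloaded in full.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import HistoSliceSet, RegionMask, SUVVolume
from .phantom import LesionGeometry, PhantomDataset, PhantomSpec

__all__ = [
    "write_mask",
    "read_mask",
    "write_suv",
    "read_suv",
    "save_dataset",
    "load_dataset",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def _voxel_size(img: nib.Nifti1Image) -> float:
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"expected isotropic voxels, got zooms {zooms}")
    return float(zooms[0])


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(mask.voxel_size_mm))
    nib.save(img, path)
    return path


def read_mask(path: str | Path, role: str = "pet_gtv") -> RegionMask:
    img = nib.load(str(path))
    return RegionMask(np.asarray(img.dataobj) > 0, _voxel_size(img), role)


def write_suv(suv: SUVVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(suv.grid.astype(np.float64), _affine(suv.voxel_size_mm))
    nib.save(img, path)
    return path


def read_suv(path: str | Path) -> SUVVolume:
    img = nib.load(str(path))
    return SUVVolume(np.asarray(img.dataobj, dtype=np.float64), _voxel_size(img))


def save_dataset(ds: PhantomDataset, outdir: str | Path) -> Path:
    """Write one phantom dataset as NIfTI files plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_suv(ds.suv, outdir / "suv.nii.gz")
    write_mask(ds.prostate, outdir / "prostate.nii.gz")
    write_mask(ds.specimen, outdir / "specimen.nii.gz")
    write_mask(ds.truth_tumor, outdir / "truth.nii.gz")

    vox = ds.suv.voxel_size_mm
    stack = np.stack([m for _, m in ds.histo_slices.slices], axis=2)
    nib.save(
        nib.Nifti1Image(stack.astype(np.uint8), _affine(vox)),
        outdir / "histo_slices.nii.gz",
    )
    sidecar = {
        "spec": dataclasses.asdict(ds.spec_used),
        "histo_z_mm": ds.histo_slices.z_positions_mm,
        "histo_slice_step_mm": ds.histo_slices.slice_step_mm,
        "gland_center_mm": list(ds.gland_center_mm),
        "gland_semi_axes_mm": list(ds.gland_semi_axes_mm),
        "lesions": [dataclasses.asdict(l) for l in ds.lesions],
    }
    (outdir / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def load_dataset(outdir: str | Path) -> PhantomDataset:
    """Reload a dataset written by :func:`save_dataset`."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "sidecar.json").read_text())
    raw = dict(sidecar["spec"])
    raw["grid_shape"] = tuple(raw["grid_shape"])
    raw["lesion_volumes_ml"] = tuple(raw["lesion_volumes_ml"])
    raw["lesion_suvmax"] = tuple(raw["lesion_suvmax"])
    spec = PhantomSpec(**raw)

    suv = read_suv(outdir / "suv.nii.gz")
    stack_img = nib.load(str(outdir / "histo_slices.nii.gz"))
    stack = np.asarray(stack_img.dataobj) > 0
    slices = [
        (z, stack[:, :, i]) for i, z in enumerate(sidecar["histo_z_mm"])
    ]
    return PhantomDataset(
        suv=suv,
        prostate=read_mask(outdir / "prostate.nii.gz", "prostate"),
        specimen=read_mask(outdir / "specimen.nii.gz", "specimen"),
        truth_tumor=read_mask(outdir / "truth.nii.gz", "truth_tumor"),
        histo_slices=HistoSliceSet(slices, sidecar["histo_slice_step_mm"]),
        spec_used=spec,
        gland_center_mm=tuple(sidecar["gland_center_mm"]),
        gland_semi_axes_mm=tuple(sidecar["gland_semi_axes_mm"]),
        lesions=[
            LesionGeometry(tuple(l["center_mm"]), tuple(l["semi_axes_mm"]), l["suvmax"])
            for l in sidecar["lesions"]
        ],
    )
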
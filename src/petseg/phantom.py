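"""Synthetic prostate PSMA-PET phantom generator.

Emulates one patient of a PET-vs-histopathology validation study: an
ellipsoidal prostate gland with low background tracer uptake, one or more
focal high-uptake lesions, point-spread blur and additive noise, a central
"specimen" slab standing in for the part of the gland covered by whole-mount
step sections, and sparse histology slice contours sampled from the ground
truth at a fixed physical step.

Geometry is analytic (similar concentric ellipsoids), which makes volume
targeting, containment and iso-fraction truth sets exactly computable — the
independent route used to validate the thresholding code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridInfo, HistoSliceSet, RegionMask, SUVVolume

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "LesionGeometry",
    "PlacementError",
    "generate_phantom",
    "sample_cohort_spec",
    "analytic_fraction_mask",
]

#: Gland semi-axis aspect ratio (x : y : z); prostate is wider than tall.
_GLAND_ASPECT = np.array([1.2, 1.0, 0.9])

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2).
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PlacementError(RuntimeError):
    """A lesion could not be placed inside the gland."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient.

    Defaults reproduce the scale of the study cohort the generator emulates:
    2 mm isotropic PET voxels, a gland at the median examined-specimen volume
    (29.1 ml), a single lesion at the median histology tumor volume (3.8 ml)
    with the median intraprostatic SUVmax (39.6), benign-gland background
    uptake of 3.0 SUV, 5 mm reconstruction blur, 0.4 SUV noise, histology
    step sections every 4 mm over the central three quarters of the gland.

    ``lesion_profile``:
      * ``"ramp"`` (default) — uptake falls linearly with the normalized
        ellipsoidal radius from ``lesion_suvmax`` at the lesion center to the
        gland background at the truth boundary, so each fractional-SUVmax
        threshold carves a distinct nested sub-volume.
      * ``"flat"`` — uniform ``lesion_suvmax`` across the lesion; any
        threshold between background and SUVmax recovers the truth mask
        exactly when blur and noise are off.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size_mm: float = 2.0
    prostate_volume_ml: float = 29.1
    n_lesions: int = 1
    lesion_volumes_ml: tuple[float, ...] = (3.8,)
    lesion_suvmax: tuple[float, ...] | float = 39.6
    background_suv_mean: float = 3.0
    blur_fwhm_mm: float = 5.0
    noise_sd_suv: float = 0.4
    specimen_fraction: float = 0.75
    histo_slice_step_mm: float = 4.0
    lesion_profile: str = "ramp"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(
            self, "lesion_volumes_ml", tuple(float(v) for v in self.lesion_volumes_ml)
        )
        suvmax = self.lesion_suvmax
        if np.isscalar(suvmax):
            suvmax = (float(suvmax),) * self.n_lesions
        else:
            suvmax = tuple(float(s) for s in suvmax)
        object.__setattr__(self, "lesion_suvmax", suvmax)
        self.validate()

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.prostate_volume_ml <= 0:
            raise ValueError("prostate_volume_ml must be > 0")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if len(self.lesion_volumes_ml) != self.n_lesions:
            raise ValueError("lesion_volumes_ml must list one volume per lesion")
        if len(self.lesion_suvmax) != self.n_lesions:
            raise ValueError("lesion_suvmax must give one peak per lesion")
        if any(v <= 0 for v in self.lesion_volumes_ml):
            raise ValueError("lesion volumes must be > 0")
        if self.background_suv_mean <= 0:
            raise ValueError("background_suv_mean must be > 0")
        if any(s <= self.background_suv_mean for s in self.lesion_suvmax):
            raise ValueError("lesion_suvmax must exceed background_suv_mean")
        if self.blur_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise ValueError("blur_fwhm_mm and noise_sd_suv must be >= 0")
        if not 0 < self.specimen_fraction <= 1:
            raise ValueError("specimen_fraction must be in (0, 1]")
        step_ratio = self.histo_slice_step_mm / self.voxel_size_mm
        if abs(step_ratio - round(step_ratio)) > 1e-9 or round(step_ratio) < 1:
            raise ValueError(
                "histo_slice_step_mm must be a positive integer multiple of voxel_size_mm"
            )
        if self.lesion_profile not in ("ramp", "flat"):
            raise ValueError("lesion_profile must be 'ramp' or 'flat'")

    @property
    def info(self) -> GridInfo:
        return GridInfo(self.grid_shape, self.voxel_size_mm)


@dataclass(frozen=True)
class LesionGeometry:
    """Realized analytic geometry of one placed lesion (all lengths in mm)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    suvmax: float


@dataclass
class PhantomDataset:
    """One synthetic patient: images, masks, histology slices and provenance."""

    suv: SUVVolume
    prostate: RegionMask
    specimen: RegionMask
    truth_tumor: RegionMask
    histo_slices: HistoSliceSet
    spec_used: PhantomSpec
    gland_center_mm: tuple[float, float, float]
    gland_semi_axes_mm: tuple[float, float, float]
    lesions: list[LesionGeometry] = field(default_factory=list)


def _ellipsoid_radius(
    info: GridInfo,
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel center (1.0 = surface)."""
    axes = [
        (np.arange(n) * info.voxel_size_mm - c) / a
        for n, c, a in zip(info.shape, center_mm, semi_axes_mm)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(x**2 + y**2 + z**2)


def _calibrated_ellipsoid(
    info: GridInfo,
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    target_voxels: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize an ellipsoid, rescaling its axes so the voxel count matches.

    Bisects a global scale multiplier (voxel count is monotone in scale) and
    returns ``(mask, realized_semi_axes_mm)`` for the best multiplier found.
    """
    r = _ellipsoid_radius(info, center_mm, semi_axes_mm)
    lo, hi = 0.7, 1.3
    if np.count_nonzero(r <= hi) < target_voxels:
        raise ValueError(
            f"grid too small for an ellipsoid of {target_voxels} voxels "
            f"at center {tuple(center_mm)}"
        )
    best_m, best_err = 1.0, None
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        count = int(np.count_nonzero(r <= mid))
        err = abs(count - target_voxels)
        if best_err is None or err < best_err:
            best_m, best_err = mid, err
        if count < target_voxels:
            lo = mid
        elif count > target_voxels:
            hi = mid
        else:
            break
    mask = r <= best_m
    realized = np.asarray(semi_axes_mm, dtype=float) * best_m
    return mask, realized


def _aspect_semi_axes(volume_ml: float, aspect: np.ndarray) -> np.ndarray:
    """Semi-axes (mm) of an ellipsoid of the given volume and aspect ratio."""
    volume_mm3 = volume_ml * 1000.0
    t = (volume_mm3 / (4.0 / 3.0 * math.pi * float(np.prod(aspect)))) ** (1.0 / 3.0)
    return aspect * t


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate one synthetic patient dataset from ``spec``.

    The gland and every lesion are similar concentric-frame ellipsoids whose
    voxelizations are rescaled to hit their target volumes (within a voxel
    shell). Noiseless activity is background uptake on the gland with the
    lesion profile superimposed; the SUV image adds Gaussian blur and
    zero-mean noise clipped at 0. Identical seeds give identical datasets.
    """
    spec.validate()
    info = spec.info
    rng = np.random.default_rng(spec.seed)
    vox_ml = info.voxel_volume_ml

    # Gland: ellipsoid centered on the grid, snapped to a voxel center.
    center_idx = [int(n // 2) for n in info.shape]
    gland_center = np.array([k * info.voxel_size_mm for k in center_idx])
    gland_axes0 = _aspect_semi_axes(spec.prostate_volume_ml, _GLAND_ASPECT)
    gland_target = int(round(spec.prostate_volume_ml / vox_ml))
    half_extent = np.array(info.shape) * info.voxel_size_mm / 2.0
    if np.any(gland_axes0 * 1.05 >= half_extent):
        raise ValueError(
            f"grid {info.shape} too small for a {spec.prostate_volume_ml} ml gland"
        )
    gland_mask, gland_axes = _calibrated_ellipsoid(
        info, gland_center, gland_axes0, gland_target
    )

    # Lesions: similar ellipsoids placed in gland-normalized coordinates.
    # A lesion of scale s centered at normalized radius <= 1 - s is contained
    # in the gland; scales and centers also give an exact disjointness test.
    margin = info.voxel_size_mm / float(gland_axes.min())
    scales = []
    for i, vol_ml in enumerate(spec.lesion_volumes_ml):
        s = (vol_ml / spec.prostate_volume_ml) ** (1.0 / 3.0)
        if 1.0 - s - margin < 0:
            raise PlacementError(
                f"lesion {i} ({vol_ml} ml) is too large to fit inside the "
                f"{spec.prostate_volume_ml} ml gland"
            )
        if int(round(vol_ml / vox_ml)) < 1:
            raise ValueError(f"lesion {i} smaller than one voxel ({vol_ml} ml)")
        scales.append(s)

    # Whole configurations are retried: an index lesion drawn too close to
    # the gland center can make every satellite position infeasible, which
    # no amount of satellite re-sampling fixes.
    placed: list[LesionGeometry] = []
    failed_lesion = 0
    for _restart in range(60):
        placed = []
        placed_norm: list[tuple[np.ndarray, float]] = []
        truth = np.zeros(info.shape, dtype=bool)
        failed_lesion = None
        for i, (vol_ml, s) in enumerate(zip(spec.lesion_volumes_ml, scales)):
            max_r = 1.0 - s - margin
            target = int(round(vol_ml / vox_ml))
            lesion = None
            for _attempt in range(80):
                if not placed_norm:
                    # Uniform in the allowed ball (cube-root radius density).
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    radius = max_r * rng.uniform() ** (1.0 / 3.0)
                else:
                    # Propose on the far side of the gland from the first
                    # lesion (with jitter); the explicit containment and
                    # disjointness checks below remain the arbiter, this only
                    # concentrates proposals where they can succeed.
                    c0, s0 = placed_norm[0]
                    d0 = float(np.linalg.norm(c0))
                    away = -c0 / d0 if d0 > 1e-9 else rng.normal(size=3)
                    direction = away + 0.3 * rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    r_lo = min(max(0.0, s + s0 + margin - d0), max_r)
                    radius = rng.uniform(r_lo, max_r)
                center = gland_center + direction * radius * gland_axes
                center = np.round(center / info.voxel_size_mm) * info.voxel_size_mm
                c_norm = (center - gland_center) / gland_axes
                if np.linalg.norm(c_norm) > max_r + 1e-9:
                    continue
                if any(
                    np.linalg.norm(c_norm - other) <= s + s_other + margin
                    for other, s_other in placed_norm
                ):
                    continue
                mask, axes = _calibrated_ellipsoid(info, center, s * gland_axes, target)
                if not np.all(~mask | gland_mask):
                    continue  # calibration pushed past the gland surface
                lesion = LesionGeometry(tuple(center), tuple(axes), spec.lesion_suvmax[i])
                placed_norm.append((c_norm, s))
                truth |= mask
                break
            if lesion is None:
                failed_lesion = i
                break
            placed.append(lesion)
        if failed_lesion is None:
            break
    else:
        raise PlacementError(
            f"failed to place lesion {failed_lesion} "
            f"({spec.lesion_volumes_ml[failed_lesion]} ml) after 60 "
            f"configuration restarts"
        )

    # Noiseless activity: background on gland, lesion profile superimposed.
    activity = np.where(gland_mask, spec.background_suv_mean, 0.0)
    bg = spec.background_suv_mean
    for lesion in placed:
        r = _ellipsoid_radius(info, lesion.center_mm, lesion.semi_axes_mm)
        inside = r <= 1.0
        if spec.lesion_profile == "ramp":
            value = bg + (lesion.suvmax - bg) * (1.0 - r)
        else:
            value = np.full(info.shape, lesion.suvmax)
        activity = np.where(inside, np.maximum(activity, value), activity)

    suv_grid = activity
    if spec.blur_fwhm_mm > 0:
        sigma_vox = spec.blur_fwhm_mm / _FWHM_TO_SIGMA / info.voxel_size_mm
        suv_grid = gaussian_filter(suv_grid, sigma_vox, mode="constant", cval=0.0)
    if spec.noise_sd_suv > 0:
        suv_grid = suv_grid + rng.normal(0.0, spec.noise_sd_suv, size=info.shape)
    suv_grid = np.clip(suv_grid, 0.0, None)

    # Specimen: central contiguous Z-slab covering specimen_fraction of the
    # gland's Z extent (whole-mount step sections cover a central block).
    z_any = np.flatnonzero(gland_mask.any(axis=(0, 1)))
    g0, g1 = int(z_any[0]), int(z_any[-1])
    nz = g1 - g0 + 1
    n_spec = max(1, int(round(spec.specimen_fraction * nz)))
    z0 = g0 + (nz - n_spec) // 2
    z1 = z0 + n_spec - 1
    specimen = np.zeros(info.shape, dtype=bool)
    specimen[:, :, z0 : z1 + 1] = gland_mask[:, :, z0 : z1 + 1]

    # Histology slices: planes every histo_slice_step_mm, centered in the
    # specimen slab, sampling the truth mask at the nearest voxel layer.
    step_vox = int(round(spec.histo_slice_step_mm / info.voxel_size_mm))
    n_planes = (n_spec - 1) // step_vox + 1
    offset = (n_spec - 1 - (n_planes - 1) * step_vox) // 2
    plane_idx = [z0 + offset + j * step_vox for j in range(n_planes)]
    slices = [
        (info.z_mm(k), truth[:, :, k].copy()) for k in plane_idx
    ]
    histo = HistoSliceSet(slices, slice_step_mm=spec.histo_slice_step_mm)

    vox = info.voxel_size_mm
    return PhantomDataset(
        suv=SUVVolume(suv_grid, vox),
        prostate=RegionMask(gland_mask, vox, "prostate"),
        specimen=RegionMask(specimen, vox, "specimen"),
        truth_tumor=RegionMask(truth, vox, "truth_tumor"),
        histo_slices=histo,
        spec_used=spec,
        gland_center_mm=tuple(gland_center),
        gland_semi_axes_mm=tuple(gland_axes),
        lesions=placed,
    )


def analytic_fraction_mask(dataset: PhantomDataset, fraction: float) -> RegionMask:
    """Exact iso-fraction truth set of the noiseless phantom, from geometry.

    For a threshold ``T = fraction * SUVmax`` the set ``{SUV >= T}`` of the
    noiseless, blur-free phantom is analytically known: the whole gland when
    ``T`` does not exceed the background, otherwise (for ramp lesions) the
    nested sub-ellipsoid of normalized radius
    ``r_f = 1 - (T - bg) / (suvmax - bg)`` of each lesion whose peak reaches
    ``T``. This is the independent geometric route against which the image
    thresholding code is validated.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    spec = dataset.spec_used
    info = spec.info
    bg = spec.background_suv_mean
    suvmax = max(l.suvmax for l in dataset.lesions)
    threshold = fraction * suvmax
    if threshold <= bg:
        return dataset.prostate.with_grid(dataset.prostate.grid.copy(), "pet_gtv")
    out = np.zeros(info.shape, dtype=bool)
    for lesion in dataset.lesions:
        if lesion.suvmax < threshold:
            continue
        r = _ellipsoid_radius(info, lesion.center_mm, lesion.semi_axes_mm)
        if spec.lesion_profile == "flat":
            out |= r <= 1.0
        else:
            r_f = 1.0 - (threshold - bg) / (lesion.suvmax - bg)
            out |= r <= r_f
    return RegionMask(out, info.voxel_size_mm, "pet_gtv")


def sample_cohort_spec(
    n_patients: int,
    seed: int,
    grid_shape: tuple[int, int, int] = (48, 48, 32),
    lesion_profile: str = "ramp",
) -> list[PhantomSpec]:
    """Draw per-patient phantom specs with the cohort's statistical structure.

    Per patient: peak lesion SUVmax uniform in [11.6, 59.8]; the index-lesion
    volume log-uniform in [0.6, 9.9] ml; gland volume uniform in
    [20.4, 41.8] ml (the examined-specimen scale); 1-3 lesions with
    probabilities 0.6/0.3/0.1, satellite lesions log-uniform in [0.3, 1.5] ml
    with peaks at 40-90% of the index peak (floored above background).
    Deterministic under ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for _ in range(n_patients):
        suvmax = rng.uniform(11.6, 59.8)
        index_vol = math.exp(rng.uniform(math.log(0.6), math.log(9.9)))
        prostate_vol = rng.uniform(20.4, 41.8)
        n_lesions = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        volumes = [index_vol]
        peaks = [suvmax]
        # Satellites are kept only when the gland can geometrically hold them.
        # Containment and disjointness are enforced in gland-normalized
        # coordinates: two lesions of scales s1, s2 need
        # s1 + s2 <= 1 - 1.5*margin to co-exist at all, and random placement
        # needs extra slack to succeed within the attempt budget; infeasible
        # draws fall back to fewer lesions rather than fail placement.
        s_index = (index_vol / prostate_vol) ** (1.0 / 3.0)
        margin = 2.0 / float(_aspect_semi_axes(prostate_vol, _GLAND_ASPECT).min())
        for _j in range(n_lesions - 1):
            sat_vol = math.exp(rng.uniform(math.log(0.3), math.log(1.5)))
            sat_peak = max(suvmax * rng.uniform(0.4, 0.9), 3.0 * 2.0)
            s_sat = (sat_vol / prostate_vol) ** (1.0 / 3.0)
            s_prev = max(
                ((v / prostate_vol) ** (1.0 / 3.0) for v in volumes[1:]),
                default=0.0,
            )
            pair_ok = s_index + s_sat <= 1.0 - 1.5 * margin - 0.08
            trio_ok = s_prev == 0.0 or s_index + 2.0 * max(s_sat, s_prev) <= 1.0 - 2.0 * margin - 0.08
            if not (pair_ok and trio_ok):
                continue
            volumes.append(sat_vol)
            peaks.append(sat_peak)
        n_lesions = len(volumes)
        specs.append(
            PhantomSpec(
                grid_shape=grid_shape,
                prostate_volume_ml=prostate_vol,
                n_lesions=n_lesions,
                lesion_volumes_ml=tuple(volumes),
                lesion_suvmax=tuple(peaks),
                lesion_profile=lesion_profile,
                seed=int(rng.integers(2**31)),
            )
        )
    return specs
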
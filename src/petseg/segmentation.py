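"""PET-based tumor contouring by fractional-SUVmax thresholding.

Two approaches are implemented:

* fixed fractional thresholds — the contour is every gland voxel whose SUV
  reaches a stated fraction (20-50% in the study) of the intraprostatic
  SUVmax; and
* individual scaling — the absolute SUV threshold is searched so that the
  resulting contour volume matches the available histology volume, which is
  how per-patient manual rescaling of the display window is operationalized
  as a reproducible computation.

Thresholding is deliberately plain: inclusive ``>=``, no smoothing, no
connected-component selection, so multifocal uptake yields multifocal
contours. Results are restricted to the gland by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import RegionMask, SUVVolume, _check_aligned

__all__ = [
    "ThresholdResult",
    "IndividualScalingResult",
    "intraprostatic_suvmax",
    "threshold_segment",
    "volume_matched_threshold",
]


@dataclass(frozen=True)
class ThresholdResult:
    """A fractional-SUVmax contour and the threshold that produced it."""

    fraction: float
    suv_threshold: float
    gtv: RegionMask
    suvmax_used: float


@dataclass(frozen=True)
class IndividualScalingResult:
    """A volume-matched contour: the threshold whose volume best fits histology.

    ``flagged`` is True when the requested target exceeded what any threshold
    can reach (the whole gland), in which case the search floor is returned.
    """

    suv_upper: float
    percent_of_suvmax: float
    gtv: RegionMask
    target_volume_ml: float
    achieved_volume_ml: float
    flagged: bool = False


def intraprostatic_suvmax(suv: SUVVolume, prostate: RegionMask) -> float:
    """Maximum SUV over the prostate voxels (uptake outside is ignored)."""
    _check_aligned(suv, prostate)
    if prostate.voxel_count == 0:
        raise ValueError("prostate mask is empty")
    return float(suv.grid[prostate.grid].max())


def threshold_segment(
    suv: SUVVolume, prostate: RegionMask, fraction: float
) -> ThresholdResult:
    """Contour the gland voxels with SUV >= fraction * intraprostatic SUVmax."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    suvmax = intraprostatic_suvmax(suv, prostate)
    threshold = fraction * suvmax
    gtv = prostate.grid & (suv.grid >= threshold)
    return ThresholdResult(
        fraction=float(fraction),
        suv_threshold=float(threshold),
        gtv=RegionMask(gtv, suv.voxel_size_mm, "pet_gtv"),
        suvmax_used=suvmax,
    )


def volume_matched_threshold(
    suv: SUVVolume,
    prostate: RegionMask,
    target_volume_ml: float,
    resolution: float = 0.1,
) -> IndividualScalingResult:
    """Find the absolute SUV threshold whose contour volume best matches a target.

    Scans thresholds ``T`` on a grid of step ``resolution`` over
    ``(0, SUVmax]``; the contour volume ``|{SUV >= T} ∩ gland|`` is
    non-increasing in ``T``. Returns the ``T`` minimizing the absolute volume
    error, breaking ties toward the larger ``T`` (the more specific contour).
    A target no threshold can reach (above the whole-gland volume) returns
    the search floor with ``flagged=True``.
    """
    if target_volume_ml <= 0:
        raise ValueError("target_volume_ml must be > 0")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    suvmax = intraprostatic_suvmax(suv, prostate)
    vox_ml = prostate.info.voxel_volume_ml
    n_steps = max(1, int(np.floor(suvmax / resolution + 1e-9)))
    # Rounding keeps grid points at clean multiples of the resolution
    # (cumulative float drift would otherwise miss exact SUV plateau edges).
    thresholds = np.round(np.arange(1, n_steps + 1) * resolution, 9)

    values = np.sort(suv.grid[prostate.grid])
    counts = values.size - np.searchsorted(values, thresholds, side="left")
    volumes = counts * vox_ml
    errors = np.abs(volumes - target_volume_ml)
    # Prefer the largest threshold among (float-tolerant) ties: the more
    # specific contour when two step volumes are equally close.
    best = int(np.flatnonzero(errors <= errors.min() + 1e-9)[-1])

    flagged = target_volume_ml > values.size * vox_ml
    if flagged:
        best = 0  # search floor: the most inclusive threshold available
    t_best = float(thresholds[best])
    gtv = prostate.grid & (suv.grid >= t_best)
    return IndividualScalingResult(
        suv_upper=t_best,
        percent_of_suvmax=100.0 * t_best / suvmax,
        gtv=RegionMask(gtv, suv.voxel_size_mm, "pet_gtv"),
        target_volume_ml=float(target_volume_ml),
        achieved_volume_ml=float(volumes[best]),
        flagged=flagged,
    )
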
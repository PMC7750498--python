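"""Validation of a PET contour against the histology reference.

Sensitivity and specificity are scored at the slice-quadrant level: on every
axial slice the examined prostate is split into four quadrants by two
axis-aligned lines through the in-slice prostate centroid, and each quadrant
is called positive by the reference (histology) and by the test contour if it
contains at least one respective voxel. This deliberately coarse unit absorbs
small coregistration mismatch that would dominate a voxel-level comparison.

Voxel-level agreement (Dice), coverage of the histology volume and volume
proportions complement the quadrant scores. Metrics with an undefined
denominator are reported as ``nan`` (not available), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import RegionMask, _check_aligned

__all__ = [
    "QuadrantConfusion",
    "quadrant_partition",
    "quadrant_confusion",
    "sens_spec",
    "dice",
    "coverage",
    "proportion",
]


@dataclass(frozen=True)
class QuadrantConfusion:
    """TP/FP/TN/FN counts over slice-quadrants; 4 quadrants per scored slice."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_slices: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_slices) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn != 4 * self.n_slices:
            raise ValueError("quadrant counts must total 4 per scored slice")

    def __add__(self, other: "QuadrantConfusion") -> "QuadrantConfusion":
        return QuadrantConfusion(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.n_slices + other.n_slices,
        )


def quadrant_partition(prostate_slice: np.ndarray) -> np.ndarray:
    """Label the slice's prostate voxels 1-4 by centroid-anchored quadrants.

    Two axis-aligned lines through the prostate-voxel centroid split the
    slice into anterior/posterior x left/right quadrants; a voxel exactly on
    a dividing line goes to the lower-index side. Returns an int array of the
    slice's shape with 0 outside the prostate.
    """
    mask = np.asarray(prostate_slice).astype(bool)
    if mask.ndim != 2:
        raise ValueError("prostate slice must be 2-D")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("prostate slice is empty")
    r_c, c_c = rows.mean(), cols.mean()
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[rows, cols] = 1 + 2 * (rows > r_c) + (cols > c_c)
    return labels


def quadrant_confusion(
    gtv: RegionMask,
    histo: RegionMask,
    prostate: RegionMask,
    eval_region: RegionMask,
) -> QuadrantConfusion:
    """Score each examined slice's quadrants against the histology reference.

    For every axial slice with at least one ``prostate ∩ eval_region`` voxel,
    those voxels are partitioned into quadrants; a quadrant is
    reference-positive if it holds >= 1 histology voxel and test-positive if
    it holds >= 1 contour voxel. Slices without examined prostate (outside
    the specimen) are skipped entirely — unexamined tissue must not inflate
    specificity. Quadrants left empty by the centroid split count as true
    negatives, keeping 4 quadrants per scored slice.
    """
    _check_aligned(gtv, histo, prostate, eval_region)
    scope = prostate.grid & eval_region.grid
    tp = fp = tn = fn = n_slices = 0
    for k in range(scope.shape[2]):
        sl = scope[:, :, k]
        if not sl.any():
            continue
        labels = quadrant_partition(sl)
        n_slices += 1
        g = gtv.grid[:, :, k]
        h = histo.grid[:, :, k]
        for q in (1, 2, 3, 4):
            in_q = labels == q
            ref_pos = bool((h & in_q).any())
            test_pos = bool((g & in_q).any())
            if ref_pos and test_pos:
                tp += 1
            elif test_pos:
                fp += 1
            elif ref_pos:
                fn += 1
            else:
                tn += 1
    return QuadrantConfusion(tp, fp, tn, fn, n_slices)


def sens_spec(conf: QuadrantConfusion) -> tuple[float, float]:
    """Sensitivity and specificity in percent from quadrant counts.

    An undefined metric (no reference-positive quadrants for sensitivity, no
    reference-negative ones for specificity) is returned as ``nan``.
    """
    sens = 100.0 * conf.tp / (conf.tp + conf.fn) if conf.tp + conf.fn > 0 else float("nan")
    spec = 100.0 * conf.tn / (conf.tn + conf.fp) if conf.tn + conf.fp > 0 else float("nan")
    return sens, spec


def dice(a: RegionMask, b: RegionMask) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a|+|b|); ``nan`` if both empty."""
    _check_aligned(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return float("nan")
    inter = int((a.grid & b.grid).sum())
    return 2.0 * inter / (na + nb)


def coverage(gtv: RegionMask, histo: RegionMask) -> float:
    """Percent of the histology reference volume covered by the contour."""
    _check_aligned(gtv, histo)
    n_h = histo.voxel_count
    if n_h == 0:
        raise ValueError("histology reference mask is empty")
    inter = int((gtv.grid & histo.grid).sum())
    return 100.0 * inter / n_h


def proportion(gtv: RegionMask, region: RegionMask) -> float:
    """Contour volume inside ``region`` as a percent of the region volume."""
    _check_aligned(gtv, region)
    n_r = region.voxel_count
    if n_r == 0:
        raise ValueError("region mask is empty")
    inter = int((gtv.grid & region.grid).sum())
    return 100.0 * inter / n_r
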
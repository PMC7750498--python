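"""Quadrant analysis, Dice, coverage and proportion metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petseg import (
    QuadrantConfusion,
    RegionMask,
    coverage,
    dice,
    proportion,
    quadrant_confusion,
    quadrant_partition,
    sens_spec,
)


def _mask3d(grid, role="pet_gtv"):
    return RegionMask(np.asarray(grid, dtype=bool), 2.0, role)


class TestQuadrantPartition:
    def test_symmetric_block_splits_evenly(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:5, 1:5] = True
        labels = quadrant_partition(m)
        counts = [int((labels == q).sum()) for q in (1, 2, 3, 4)]
        assert counts == [4, 4, 4, 4]

    def test_single_voxel_goes_to_one_quadrant(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        labels = quadrant_partition(m)
        assert sorted(int((labels == q).sum()) for q in (1, 2, 3, 4)) == [0, 0, 0, 1]
        # the voxel sits on both centroid lines -> lower-index side -> quadrant 1
        assert labels[2, 3] == 1

    def test_l_shape_matches_bruteforce_centroid_split(self):
        m = np.zeros((6, 6), dtype=bool)
        m[0:4, 0] = True
        m[3, 0:4] = True
        m[0, 1:5] = True
        labels = quadrant_partition(m)
        rows, cols = np.nonzero(m)
        r_c, c_c = rows.mean(), cols.mean()
        for r, c in zip(rows, cols):
            expected = 1 + 2 * (r > r_c) + (c > c_c)
            assert labels[r, c] == expected
        assert (labels[~m] == 0).all()

    def test_empty_slice_raises(self):
        with pytest.raises(ValueError, match="empty"):
            quadrant_partition(np.zeros((4, 4), dtype=bool))


class TestQuadrantConfusion:
    def _single_slice(self, histo_q, gtv_q):
        """6x6x1 world with a centered 4x4 prostate; fill named quadrants."""
        prostate = np.zeros((6, 6, 1), dtype=bool)
        prostate[1:5, 1:5, 0] = True
        labels = quadrant_partition(prostate[:, :, 0])
        histo = np.zeros_like(prostate)
        gtv = np.zeros_like(prostate)
        for q in histo_q:
            histo[:, :, 0] |= labels == q
        for q in gtv_q:
            gtv[:, :, 0] |= labels == q
        ev = np.ones_like(prostate)
        return (
            _mask3d(gtv),
            _mask3d(histo, "histo_gtv"),
            _mask3d(prostate, "prostate"),
            _mask3d(ev, "specimen"),
        )

    def test_partial_agreement_counts(self):
        """Histology in quadrant 1, contour in 1 and 2: TP=1 FP=1 TN=2 FN=0."""
        conf = quadrant_confusion(*self._single_slice({1}, {1, 2}))
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (1, 1, 2, 0)
        assert conf.n_slices == 1

    def test_identical_contours_have_no_errors(self):
        conf = quadrant_confusion(*self._single_slice({1, 3}, {1, 3}))
        assert conf.fp == 0 and conf.fn == 0

    def test_empty_contour_yields_only_misses(self):
        conf = quadrant_confusion(*self._single_slice({2, 4}, set()))
        assert (conf.tp, conf.fp, conf.fn) == (0, 0, 2)

    def test_slices_outside_eval_region_skipped(self):
        gtv, histo, prostate, ev = self._single_slice({1}, {1})
        ev.grid[:] = False
        conf = quadrant_confusion(gtv, histo, prostate, ev)
        assert conf.n_slices == 0
        assert conf.tp + conf.fp + conf.tn + conf.fn == 0

    def test_counts_total_four_per_slice_invariant(self):
        with pytest.raises(ValueError):
            QuadrantConfusion(tp=1, fp=0, tn=0, fn=0, n_slices=1)

    def test_matches_bruteforce_on_random_fixtures(self):
        """Vectorized scoring equals a per-voxel brute-force loop."""
        from conftest import random_fixture

        for seed in range(25):
            _, prostate, gtv, histo, ev = random_fixture(seed)
            conf = quadrant_confusion(gtv, histo, prostate, ev)
            expected = _bruteforce_confusion(
                gtv.grid, histo.grid, prostate.grid, ev.grid
            )
            assert (conf.tp, conf.fp, conf.tn, conf.fn, conf.n_slices) == expected


def _bruteforce_confusion(gtv, histo, prostate, ev):
    """Independent oracle: explicit loops over slices, voxels and quadrants."""
    tp = fp = tn = fn = n_slices = 0
    nx, ny, nz = prostate.shape
    for k in range(nz):
        pts = [
            (i, j)
            for i in range(nx)
            for j in range(ny)
            if prostate[i, j, k] and ev[i, j, k]
        ]
        if not pts:
            continue
        n_slices += 1
        rc = sum(p[0] for p in pts) / len(pts)
        cc = sum(p[1] for p in pts) / len(pts)
        for q in (1, 2, 3, 4):
            ref = test = False
            for i, j in pts:
                label = 1 + 2 * (i > rc) + (j > cc)
                if label == q:
                    ref = ref or histo[i, j, k]
                    test = test or gtv[i, j, k]
            if ref and test:
                tp += 1
            elif test:
                fp += 1
            elif ref:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn, n_slices


class TestSensSpec:
    def test_arithmetic(self):
        sens, spec = sens_spec(QuadrantConfusion(1, 1, 2, 0, 1))
        assert sens == pytest.approx(100.0)
        assert spec == pytest.approx(200.0 / 3.0)

    def test_perfect_agreement(self):
        assert sens_spec(QuadrantConfusion(2, 0, 2, 0, 1)) == (100.0, 100.0)

    def test_all_missed_gives_zero_sensitivity(self):
        sens, _ = sens_spec(QuadrantConfusion(0, 0, 2, 2, 1))
        assert sens == 0.0

    def test_undefined_denominators_are_nan(self):
        sens, spec = sens_spec(QuadrantConfusion(0, 0, 0, 4, 1))
        assert math.isnan(spec) and sens == 0.0
        sens, spec = sens_spec(QuadrantConfusion(0, 0, 4, 0, 1))
        assert math.isnan(sens) and spec == 100.0


class TestOverlapMetrics:
    def _pair(self, na, nb, ninter, shape=(4, 4, 8)):
        a = np.zeros(shape, dtype=bool)
        b = np.zeros(shape, dtype=bool)
        a.flat[:na] = True
        b.flat[na - ninter : na - ninter + nb] = True
        return _mask3d(a), _mask3d(b, "histo_gtv")

    def test_dice_identity_and_disjoint(self):
        a, b = self._pair(10, 10, 0)
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_dice_direct_count(self):
        a, b = self._pair(4, 6, 2)
        assert dice(a, b) == pytest.approx(0.4)

    def test_dice_both_empty_is_nan(self):
        a, b = self._pair(0, 0, 0)
        assert math.isnan(dice(a, b))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_dice_symmetry_and_equality_property(self, bits_a, bits_b):
        shape = (4, 5, 1)
        a = _mask3d(np.array([bool(bits_a >> i & 1) for i in range(20)]).reshape(shape))
        b = _mask3d(np.array([bool(bits_b >> i & 1) for i in range(20)]).reshape(shape))
        if a.voxel_count + b.voxel_count == 0:
            return
        d_ab, d_ba = dice(a, b), dice(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        assert (d_ab == 1.0) == np.array_equal(a.grid, b.grid)

    def test_coverage(self):
        gtv, histo = self._pair(6, 4, 4)
        assert coverage(gtv, histo) == 100.0
        gtv2, histo2 = self._pair(5, 5, 0)
        assert coverage(gtv2, histo2) == 0.0
        gtv3, histo3 = self._pair(60, 100, 60)
        assert coverage(gtv3, histo3) == pytest.approx(60.0)

    def test_coverage_empty_reference_raises(self):
        gtv, histo = self._pair(5, 0, 0)
        with pytest.raises(ValueError):
            coverage(gtv, histo)

    def test_proportion(self):
        gtv, region = self._pair(20, 20, 20)
        assert proportion(gtv, region) == 100.0
        empty, region2 = self._pair(0, 10, 0)
        assert proportion(empty, region2) == 0.0

    def test_proportion_table_scale(self):
        """400 of 3638 specimen voxels (29.1 ml at 2 mm) is 11% of the specimen."""
        shape = (20, 20, 16)
        gtv, region = self._pair(400, 3638, 400, shape=shape)
        assert proportion(gtv, region) == pytest.approx(11.0, abs=0.05)

    def test_proportion_empty_region_raises(self):
        gtv, region = self._pair(5, 0, 0)
        with pytest.raises(ValueError):
            proportion(gtv, region)
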
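"""Cohort-level nonparametric statistics.

Metrics are summarized as median (IQR). Normality is screened with
Shapiro-Wilk; the comparison across contouring approaches uses the Friedman
test (repeated measures over patients) followed by pairwise uncorrected
Dunn tests on the Friedman mean ranks, both at a significance level of 0.05
with a strict ``p < alpha`` flag. No multiplicity correction is applied to
the pairwise tests, matching the study's analysis.

The Friedman statistic is computed here (midranks, standard tie correction);
scipy's implementation is used only as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestReport",
    "PairwiseResult",
    "median_iqr",
    "friedman",
    "dunn_uncorrected",
    "shapiro_gate",
]


@dataclass(frozen=True)
class PairwiseResult:
    """One uncorrected Dunn comparison between two approaches."""

    approach_i: int
    approach_j: int
    z: float
    p: float
    significant: bool


@dataclass(frozen=True)
class TestReport:
    """Friedman omnibus result plus pairwise Dunn comparisons."""

    friedman_statistic: float
    friedman_p: float
    pairwise: tuple[PairwiseResult, ...]
    alpha: float = 0.05
    mean_ranks: tuple[float, ...] = ()


def median_iqr(values) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles (linear interpolation between order
    statistics, numpy's default quantile convention)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr needs at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _block_ranks(block_matrix: np.ndarray) -> np.ndarray:
    """Within-block (row-wise) midranks of an n x k matrix."""
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("block matrix must be 2-D (patients x approaches)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 approaches")
    if not np.all(np.isfinite(m)):
        raise ValueError(
            "block matrix has missing/non-finite cells; Friedman requires "
            "complete blocks — restrict to complete cases upstream"
        )
    return np.apply_along_axis(sps.rankdata, 1, m)


def friedman(block_matrix) -> tuple[float, float]:
    """Friedman test over an n-patients x k-approaches block matrix.

    Within-block midranks with the standard tie-correction factor; the
    statistic is referred to a chi-squared distribution with k-1 degrees of
    freedom. Returns ``(statistic, p)``. All-tied data yield (0.0, 1.0).
    """
    m = np.asarray(block_matrix, dtype=float)
    ranks = _block_ranks(m)
    n, k = m.shape
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    # Tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1)) over within-block
    # tie groups.
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0  # every block fully tied: no evidence of any effect
    stat /= correction
    p = float(sps.chi2.sf(stat, k - 1))
    return float(stat), p


def dunn_uncorrected(block_matrix, alpha: float = 0.05) -> TestReport:
    """Pairwise post-hoc comparisons on Friedman mean ranks, uncorrected.

    For approaches i < j the statistic is
    ``z = (meanrank_i - meanrank_j) / sqrt(k (k+1) / (6 n))`` with a
    two-sided normal p-value. No multiplicity correction is applied; each
    pair is flagged significant iff ``p < alpha`` (strict).
    """
    m = np.asarray(block_matrix, dtype=float)
    ranks = _block_ranks(m)
    n, k = m.shape
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    stat, p_omnibus = friedman(m)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
            pairs.append(PairwiseResult(i, j, float(z), p, p < alpha))
    return TestReport(
        friedman_statistic=stat,
        friedman_p=p_omnibus,
        pairwise=tuple(pairs),
        alpha=alpha,
        mean_ranks=tuple(float(r) for r in mean_ranks),
    )


def shapiro_gate(values, alpha: float = 0.05) -> tuple[float | None, bool]:
    """Shapiro-Wilk normality screen: ``(p_value, non_normal_flag)``.

    ``p < alpha`` flags the sample non-normal, routing the pipeline to the
    nonparametric tests. Fewer than 3 values or a constant sample has no
    defined statistic and returns ``(None, False)``.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3 or np.ptp(arr) == 0:
        return None, False
    p = float(sps.shapiro(arr).pvalue)
    return p, p < alpha
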
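"""End-to-end cohort pipeline and study-style reporting.

For each (synthetic) patient the pipeline builds the 3-D histology reference
from the sparse slice contours, produces the fractional-SUVmax contours and
the histology-volume-matched ("individually scaled") contour, trims
everything to the examined specimen where histology is the reference, and
computes volumes, proportions, coverage, and quadrant sensitivity /
specificity. Cohort records are collected into a tidy table from which the
median (IQR) overview table and the Friedman + uncorrected Dunn comparisons
are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import coverage, dice, proportion, quadrant_confusion, sens_spec
from .grids import RegionMask
from .histo import build_histo_model, trim_to_region, volume_ml
from .phantom import PhantomDataset, generate_phantom, sample_cohort_spec
from .segmentation import (
    intraprostatic_suvmax,
    threshold_segment,
    volume_matched_threshold,
)
from .stats import TestReport, dunn_uncorrected, median_iqr, shapiro_gate

__all__ = [
    "CohortTable",
    "CohortResult",
    "HISTO_APPROACH",
    "threshold_approach_name",
    "evaluate_patient",
    "run_cohort",
    "build_table2",
]

HISTO_APPROACH = "GTV-Histo"
INDIVIDUAL_APPROACH = "GTV-Individual"

#: Metric columns of the overview table, in print order.
METRICS = (
    "volume_ml",
    "proportion_specimen_pct",
    "proportion_whole_pct",
    "coverage_pct",
    "sensitivity_pct",
    "specificity_pct",
)


def threshold_approach_name(fraction: float) -> str:
    return f"GTV-SUV{round(fraction * 100):d}%"


@dataclass
class CohortTable:
    """Tidy per-patient, per-approach metric records with cohort helpers."""

    records: pd.DataFrame  # columns: patient, approach, metric, value
    approaches: list[str]
    n_patients: int

    def block_matrix(self, metric: str, approaches: list[str] | None = None) -> np.ndarray:
        """n_patients x k matrix of one metric, complete cases only.

        Patients missing any cell (undefined metric) are dropped, which is
        the complete-block requirement of the Friedman test.
        """
        approaches = approaches or self.approaches
        wide = (
            self.records[self.records["metric"] == metric]
            .pivot(index="patient", columns="approach", values="value")
            .reindex(columns=approaches)
        )
        wide = wide.dropna(axis=0, how="any")
        return wide.to_numpy(dtype=float)

    def metric_values(self, metric: str, approach: str) -> np.ndarray:
        sel = self.records[
            (self.records["metric"] == metric) & (self.records["approach"] == approach)
        ]
        return sel["value"].to_numpy(dtype=float)


@dataclass
class CohortResult:
    """Everything the cohort run produces: records, overview, tests."""

    table: CohortTable
    overview: pd.DataFrame
    reports: dict[str, TestReport]
    report_approaches: dict[str, list[str]]
    shapiro: dict[str, tuple[float | None, bool]]
    datasets: list[PhantomDataset] = field(default_factory=list)


def _metrics_for_gtv(
    gtv: RegionMask,
    histo: RegionMask,
    prostate: RegionMask,
    specimen: RegionMask,
) -> dict[str, float]:
    """Study metric panel for one contour against the histology reference."""
    gtv_spec = trim_to_region(gtv, specimen)
    conf = quadrant_confusion(gtv, histo, prostate, specimen)
    sens, spec_ = sens_spec(conf)
    return {
        "volume_ml": volume_ml(gtv_spec),
        "proportion_specimen_pct": proportion(gtv_spec, specimen),
        "proportion_whole_pct": proportion(gtv, prostate),
        "coverage_pct": coverage(gtv_spec, histo) if histo.voxel_count else float("nan"),
        "sensitivity_pct": sens,
        "specificity_pct": spec_,
        "dsc_vs_histo": dice(gtv_spec, histo),
    }


def evaluate_patient(
    ds: PhantomDataset,
    patient: int | str = 0,
    fractions: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5),
    match_resolution: float = 0.1,
) -> list[dict]:
    """All per-approach metric records for one patient dataset.

    The histology reference is built from the slice contours and trimmed to
    the gland and the examined specimen; every PET contour is evaluated
    against it. The individually scaled contour matches the histology volume
    and is skipped (recorded as missing) when no histology tumor was sampled.
    """
    info = ds.suv.info
    histo3d = build_histo_model(ds.histo_slices, info)
    histo = trim_to_region(trim_to_region(histo3d, ds.prostate), ds.specimen)
    suvmax = intraprostatic_suvmax(ds.suv, ds.prostate)

    records: list[dict] = []

    def emit(approach: str, metrics: dict[str, float]) -> None:
        for name, value in metrics.items():
            records.append(
                {"patient": patient, "approach": approach, "metric": name, "value": value}
            )

    emit(
        HISTO_APPROACH,
        {
            "volume_ml": volume_ml(histo),
            "proportion_specimen_pct": proportion(histo, ds.specimen),
        },
    )
    records.append(
        {"patient": patient, "approach": "patient", "metric": "suvmax", "value": suvmax}
    )
    records.append(
        {
            "patient": patient,
            "approach": "Prostate specimen",
            "metric": "volume_ml",
            "value": volume_ml(ds.specimen),
        }
    )
    records.append(
        {
            "patient": patient,
            "approach": "Prostate whole",
            "metric": "volume_ml",
            "value": volume_ml(ds.prostate),
        }
    )

    for fraction in fractions:
        res = threshold_segment(ds.suv, ds.prostate, fraction)
        emit(threshold_approach_name(fraction), _metrics_for_gtv(res.gtv, histo, ds.prostate, ds.specimen))

    target = volume_ml(histo)
    if target > 0:
        match = volume_matched_threshold(ds.suv, ds.prostate, target, match_resolution)
        metrics = _metrics_for_gtv(match.gtv, histo, ds.prostate, ds.specimen)
        metrics["percent_of_suvmax"] = match.percent_of_suvmax
        metrics["applied_suv_upper"] = match.suv_upper
        emit(INDIVIDUAL_APPROACH, metrics)
    else:
        emit(INDIVIDUAL_APPROACH, {m: float("nan") for m in METRICS})

    return records


def run_cohort(
    n_patients: int = 10,
    seed: int = 0,
    fractions: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5),
    grid_shape: tuple[int, int, int] = (48, 48, 32),
    lesion_profile: str = "ramp",
    keep_datasets: bool = False,
) -> CohortResult:
    """Simulate and analyze a full cohort; the package's end-to-end entry point.

    Generates ``n_patients`` phantoms at the study's scales, evaluates every
    contouring approach on each, and runs the cohort statistics: Shapiro-Wilk
    screens per metric, then Friedman + uncorrected Dunn across approaches
    for volume (including the histology reference) and for sensitivity /
    specificity / coverage (PET approaches only).
    """
    specs = sample_cohort_spec(n_patients, seed, grid_shape, lesion_profile)
    records: list[dict] = []
    datasets: list[PhantomDataset] = []
    for pid, spec in enumerate(specs):
        ds = generate_phantom(spec)
        records.extend(evaluate_patient(ds, patient=pid, fractions=fractions))
        if keep_datasets:
            datasets.append(ds)

    threshold_names = [threshold_approach_name(f) for f in fractions]
    approaches = [HISTO_APPROACH, *threshold_names, INDIVIDUAL_APPROACH]
    table = CohortTable(pd.DataFrame.from_records(records), approaches, n_patients)

    report_approaches = {
        "volume_ml": [HISTO_APPROACH, *threshold_names, INDIVIDUAL_APPROACH],
        "sensitivity_pct": [*threshold_names, INDIVIDUAL_APPROACH],
        "specificity_pct": [*threshold_names, INDIVIDUAL_APPROACH],
        "coverage_pct": [*threshold_names, INDIVIDUAL_APPROACH],
    }
    reports: dict[str, TestReport] = {}
    shapiro: dict[str, tuple[float | None, bool]] = {}
    for metric, names in report_approaches.items():
        block = table.block_matrix(metric, names)
        if block.shape[0] >= 2:
            reports[metric] = dunn_uncorrected(block)
        for name in names:
            shapiro[f"{metric}:{name}"] = shapiro_gate(
                table.metric_values(metric, name)
            )

    overview = build_table2(table)
    return CohortResult(table, overview, reports, report_approaches, shapiro, datasets)


def _fmt(med: float, q1: float, q3: float, decimals: int = 1) -> str:
    return f"{med:.{decimals}f} ({q1:.{decimals}f}–{q3:.{decimals}f})"


def build_table2(cohort: CohortTable) -> pd.DataFrame:
    """Median (IQR) overview of every approach, in the study's print layout.

    Rows: histology reference, each PET approach, then the specimen and
    whole-gland volumes. Cells are ``median (q1–q3)`` strings at one decimal;
    medians and quartiles are computed on unrounded values. A metric that is
    undefined for a row (for example sensitivity of the histology reference)
    is left blank; a metric missing for every patient is marked ``NA``.
    """
    rows = {}
    row_names = [*cohort.approaches, "Prostate specimen", "Prostate whole"]
    for approach in row_names:
        cells = {}
        for metric in METRICS:
            values = cohort.metric_values(metric, approach)
            finite = values[np.isfinite(values)] if values.size else values
            if values.size == 0:
                cells[metric] = ""
            elif finite.size == 0:
                cells[metric] = "NA"
            else:
                cells[metric] = _fmt(*median_iqr(finite))
        rows[approach] = cells
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRICS))
    out.index.name = "approach"
    return out
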
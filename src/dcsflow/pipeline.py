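"""End-to-end in-memory pipeline: simulate -> fit -> longitudinal statistics.

Chains the synthetic cohort generator, the per-curve Nelder-Mead
inversion with repeat averaging, and the rBF/dRBF group statistics, all
without touching disk. The file-based equivalents live in the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohort import CohortSimulation
from .inversion import FitOptions, average_repeats, fit_curve
from .stats import (
    MeasurementRecord,
    compute_delta_rbf,
    compute_rbf,
    elevation_duration,
    group_summary,
    records_to_frame,
    weekly_comparisons,
)

log = logging.getLogger(__name__)

__all__ = ["fit_cohort", "analyze_records", "summary_report", "AnalysisResult"]


def fit_cohort(
    sim: CohortSimulation,
    options: FitOptions = FitOptions(),
    progress_every: int = 0,
) -> list[MeasurementRecord]:
    """Fit every repeat curve of a simulated cohort and average per site-visit."""
    records: list[MeasurementRecord] = []
    for i, (meta, curves) in enumerate(sim.iter_site_visits()):
        estimates = [fit_curve(c, sim.optics, options) for c in curves]
        rec = average_repeats(estimates, meta, drop_outliers=options.drop_outlier_repeats)
        if rec is not None:
            records.append(rec)
        if progress_every and (i + 1) % progress_every == 0:
            log.info("fitted %d site-visits", i + 1)
    return records


@dataclass
class AnalysisResult:
    """Tidy outputs of the longitudinal analysis."""

    rbf: pd.DataFrame                 # per-mouse rBF rows
    delta: pd.DataFrame               # per-mouse dRBF rows (graft positions)
    rbf_summary: pd.DataFrame         # mean/sem/n per (group, week, position, separation)
    delta_summary: pd.DataFrame
    tests: pd.DataFrame = field(repr=False)  # weekly t-test table

    def mean_rbf_series(self, group: str, position: str, separation_mm: float) -> pd.Series:
        """Group-mean rBF indexed by week (weeks >= 1) for one cell."""
        s = self.rbf_summary
        cell = s[(s["group"] == group) & (s["position"] == position)
                 & (s["separation_mm"] == separation_mm) & (s["week"] >= 1)]
        return cell.set_index("week")["mean"].sort_index()


def analyze_records(
    records: list[MeasurementRecord] | pd.DataFrame,
    paired_contralateral: bool = False,
) -> AnalysisResult:
    """rBF, dRBF, group summaries and weekly significance tests from records."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rbf = compute_rbf(df)
    delta = compute_delta_rbf(rbf)
    return AnalysisResult(
        rbf=rbf,
        delta=delta,
        rbf_summary=group_summary(rbf, "rbf"),
        delta_summary=group_summary(delta, "delta_rbf"),
        tests=weekly_comparisons(rbf, delta, paired_contralateral=paired_contralateral),
    )


def summary_report(analysis: AnalysisResult, threshold: float = 1.25) -> dict[str, pd.DataFrame]:
    """Headline tables: elevation durations, weekly peak rBF, significant tests.

    Durations count consecutive weeks from week 1 with group-mean rBF
    strictly above ``threshold``; peaks are the maximum weekly group-mean
    rBF (and its week) over weeks >= 1.
    """
    rows_dur, rows_peak = [], []
    s = analysis.rbf_summary
    cells = s[["group", "position", "separation_mm"]].drop_duplicates()
    for _, c in cells.iterrows():
        series = analysis.mean_rbf_series(c["group"], c["position"], c["separation_mm"])
        if series.empty:
            continue
        rows_dur.append(dict(group=c["group"], position=c["position"],
                             separation_mm=c["separation_mm"],
                             elevation_weeks=elevation_duration(series, threshold)))
        rows_peak.append(dict(group=c["group"], position=c["position"],
                              separation_mm=c["separation_mm"],
                              peak_week=int(series.idxmax()),
                              peak_rbf=float(series.max())))
    return {
        "elevation_durations": pd.DataFrame(rows_dur),
        "peak_rbf": pd.DataFrame(rows_peak),
        "significant_tests": analysis.tests[analysis.tests["significant"]].reset_index(drop=True),
    }
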
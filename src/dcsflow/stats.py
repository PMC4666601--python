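"""Longitudinal relative-blood-flow statistics.

Works on tidy pandas tables of repeat-averaged BFI records. Relative
blood flow normalizes each site's BFI to its own pre-surgery baseline,

    rBF(r, t_i) = BFI(r, t_i) / BFI(r, t_0),

and the per-mouse graft-specific change subtracts the contralateral leg,

    dRBF(t) = rBF_graft(t) - rBF_contralateral(t),

with the contralateral measurement taken at position P7 at the same week
and source-detector separation. Group summaries report mean +/- SEM
(sd with n-1 denominator over the mice in a cell), and weekly
significance is assessed with the two-sided pooled-variance two-sample
Student's t-test at p < 0.05, without multiple-testing correction.
Missing data propagate and are never imputed; per-cell n is recomputed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = [
    "MeasurementRecord",
    "TTestResult",
    "records_to_frame",
    "compute_rbf",
    "compute_delta_rbf",
    "group_summary",
    "student_t_test",
    "elevation_duration",
    "weekly_comparisons",
]

CONTRALATERAL = "P7"
GRAFT_POSITIONS = ("P1", "P2", "P3", "P4", "P5", "P6")
SIGNIFICANCE_LEVEL = 0.05

_SITE = ["mouse", "position", "separation_mm"]
_CELL = ["group", "week", "position", "separation_mm"]


@dataclass(frozen=True)
class MeasurementRecord:
    """Repeat-averaged BFI for one (mouse, week, position, separation)."""

    mouse: str
    group: str
    week: int
    position: str
    separation_mm: float
    bfi: float
    beta: float = float("nan")
    n_used: int = 1
    n_total: int = 1

    def __post_init__(self) -> None:
        if not self.bfi > 0:
            raise ValueError(f"bfi must be positive, got {self.bfi}")


@dataclass(frozen=True)
class TTestResult:
    """Two-sample Student's t-test outcome."""

    t: float
    df: int
    p: float
    significant: bool


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Tidy DataFrame of measurement records; validates per-site uniqueness."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise DataError("no measurement records")
    dup = df.duplicated(subset=["mouse", "week", "position", "separation_mm"])
    if dup.any():
        raise DataError(f"{dup.sum()} duplicate (mouse, week, position, separation) records")
    return df


def compute_rbf(records: pd.DataFrame) -> pd.DataFrame:
    """Relative blood flow per mouse and site: BFI(r, t_i) / BFI(r, t_0).

    Sites without a week-0 baseline are dropped with a log entry (their
    rBF is undefined at every week and is never imputed). A zero or
    negative baseline raises :class:`DataError` naming the record.
    """
    df = records.copy()
    base = df[df["week"] == 0].set_index(_SITE)["bfi"]
    bad = base[base <= 0]
    if not bad.empty:
        site = bad.index[0]
        raise DataError(
            f"non-positive week-0 baseline BFI for mouse={site[0]}, "
            f"position={site[1]}, separation={site[2]} mm"
        )
    keyed = df.set_index(_SITE)
    keyed["baseline_bfi"] = base
    missing = keyed["baseline_bfi"].isna()
    if missing.any():
        lost = keyed[missing].reset_index()[_SITE].drop_duplicates()
        for _, row in lost.iterrows():
            log.warning(
                "no week-0 baseline for mouse=%s position=%s separation=%s mm; "
                "site dropped from rBF",
                row["mouse"], row["position"], row["separation_mm"],
            )
    out = keyed[~missing].reset_index()
    out["rbf"] = out["bfi"] / out["baseline_bfi"]
    return out


def compute_delta_rbf(rbf: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse graft-minus-contralateral rBF difference.

    For each (mouse, week, graft-leg position, separation), subtracts the
    contralateral rBF measured at P7 at the same week and separation.
    Mouse-weeks without a P7 record propagate as missing.
    """
    graft = rbf[rbf["position"].isin(GRAFT_POSITIONS)].copy()
    contra = (
        rbf[rbf["position"] == CONTRALATERAL]
        .set_index(["mouse", "week", "separation_mm"])["rbf"]
        .rename("rbf_contralateral")
    )
    graft = graft.join(contra, on=["mouse", "week", "separation_mm"])
    n_missing = int(graft["rbf_contralateral"].isna().sum())
    if n_missing:
        log.warning("%d graft records without a matching contralateral rBF", n_missing)
    graft = graft.dropna(subset=["rbf_contralateral"])
    graft["delta_rbf"] = graft["rbf"] - graft["rbf_contralateral"]
    return graft


def group_summary(table: pd.DataFrame, value: str = "rbf") -> pd.DataFrame:
    """Mean, SEM and n of ``value`` per (group, week, position, separation).

    SEM is sd/sqrt(n) with the n-1 sd denominator; cells with a single
    mouse report SEM as missing, empty cells are absent rows.
    """
    if value not in table.columns:
        raise ValueError(f"column {value!r} not in table")
    g = table.groupby(_CELL)[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    return out.drop(columns="sd")


def student_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance (classic Student's) two-sample t-test.

    Degenerate zero-variance inputs are resolved explicitly: equal means
    give t=0, p=1; unequal means with zero pooled variance give p=0 with
    a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    df = int(a.size + b.size - 2)
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0, significant=False)
        warnings.warn(
            "zero pooled variance with unequal means; reporting p=0", stacklevel=2
        )
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t=t, df=df, p=0.0, significant=True)
    res = sps.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p, significant=p < SIGNIFICANCE_LEVEL)


def elevation_duration(series: pd.Series | Sequence[float], threshold: float = 1.25) -> int:
    """Consecutive weeks from week 1 with group-mean rBF strictly above threshold.

    ``series`` is indexed by week starting at 1 without gaps (a plain
    sequence is taken as weeks 1, 2, ...). Returns 0 when week 1 is
    already at or below the threshold; the run stops at the first
    non-elevated week even if later weeks are elevated again.
    """
    if isinstance(series, pd.Series):
        weeks = np.asarray(series.index, dtype=int)
        values = series.to_numpy(dtype=float)
    else:
        values = np.asarray(series, dtype=float)
        weeks = np.arange(1, values.size + 1)
    if values.size == 0 or weeks[0] != 1 or np.any(np.diff(weeks) != 1):
        raise DataError("elevation duration needs consecutive weeks starting at week 1")
    duration = 0
    for v in values:
        if np.isnan(v):
            raise DataError("elevation duration undefined with missing weekly means")
        if v > threshold:
            duration += 1
        else:
            break
    return duration


def _cell_values(df: pd.DataFrame, value: str, **keys) -> np.ndarray:
    m = pd.Series(True, index=df.index)
    for k, v in keys.items():
        m &= df[k] == v
    return df.loc[m, value].to_numpy(dtype=float)


def weekly_comparisons(
    rbf: pd.DataFrame,
    delta: pd.DataFrame,
    paired_contralateral: bool = False,
) -> pd.DataFrame:
    """All weekly significance tests, one row per (comparison, week, position, separation).

    Three families are tested for every week >= 1 and separation:

    - ``graft_vs_contralateral``: within each group, rBF at P4 vs P7;
    - ``group_rbf``: autograft vs allograft rBF at each position;
    - ``group_delta_rbf``: autograft vs allograft dRBF at each graft position.

    Cells with fewer than 2 mice on either side are skipped with a log
    entry. ``paired_contralateral`` switches the within-group P4-vs-P7
    test to a paired t-test on per-mouse differences (the unpaired
    two-sample test is the default).
    """
    rows: list[dict] = []
    weeks = sorted(w for w in rbf["week"].unique() if w >= 1)
    seps = sorted(rbf["separation_mm"].unique())
    groups = sorted(rbf["group"].unique())
    positions = [p for p in rbf["position"].unique()]

    def add(kind, group, week, position, sep, a, b, paired=False):
        if min(len(a), len(b)) < 2:
            log.info("skipping %s %s wk%s %s %.1f mm: n<2", kind, group, week, position, sep)
            return
        if paired:
            res = sps.ttest_rel(a, b)
            df = len(a) - 1
            r = TTestResult(float(res.statistic), df, float(res.pvalue),
                            float(res.pvalue) < SIGNIFICANCE_LEVEL)
        else:
            r = student_t_test(a, b)
        rows.append(dict(comparison=kind, group=group, week=week, position=position,
                         separation_mm=sep, t=r.t, df=r.df, p=r.p, significant=r.significant))

    for week in weeks:
        for sep in seps:
            for group in groups:
                sub = rbf[(rbf["week"] == week) & (rbf["separation_mm"] == sep)
                          & (rbf["group"] == group)]
                if paired_contralateral:
                    wide = sub[sub["position"].isin(["P4", CONTRALATERAL])].pivot_table(
                        index="mouse", columns="position", values="rbf"
                    ).dropna()
                    if "P4" in wide and CONTRALATERAL in wide:
                        add("graft_vs_contralateral", group, week, "P4", sep,
                            wide["P4"].to_numpy(), wide[CONTRALATERAL].to_numpy(), paired=True)
                else:
                    add("graft_vs_contralateral", group, week, "P4", sep,
                        _cell_values(sub, "rbf", position="P4"),
                        _cell_values(sub, "rbf", position=CONTRALATERAL))
            for position in positions:
                sub = rbf[(rbf["week"] == week) & (rbf["separation_mm"] == sep)
                          & (rbf["position"] == position)]
                add("group_rbf", "autograft_vs_allograft", week, position, sep,
                    _cell_values(sub, "rbf", group="autograft"),
                    _cell_values(sub, "rbf", group="allograft"))
            for position in GRAFT_POSITIONS:
                sub = delta[(delta["week"] == week) & (delta["separation_mm"] == sep)
                            & (delta["position"] == position)]
                add("group_delta_rbf", "autograft_vs_allograft", week, position, sep,
                    _cell_values(sub, "delta_rbf", group="autograft"),
                    _cell_values(sub, "delta_rbf", group="allograft"))
    columns = ["comparison", "group", "week", "position", "separation_mm",
               "t", "df", "p", "significant"]
    return pd.DataFrame(rows, columns=columns)
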
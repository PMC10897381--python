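"""Missing-data imputation, boxplot outlier handling, minute-to-day aggregation
and cohort summary statistics.

Interior gaps are filled with the mean of the nearest preceding and following
observations (the average of a forward fill and a backward fill); leading and
trailing gaps take the nearest observed value.  Outliers are fenced by the
standard boxplot rule Q1 − 1.5·IQR / Q3 + 1.5·IQR with linear-interpolation
quartiles and winsorized to the nearer fence by default.

``STUDY_COHORT_TOTALS`` holds the published per-participant totals of the
16-adult MOX2-5 cohort (30–48 days of wear each, 539 participant-days in
total); ``cohort_summary`` computed on it reproduces the published cohort
mean/SD/min/max table.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .mox_io import DayRecord, MinuteRecord

__all__ = [
    "STUDY_COHORT_TOTALS",
    "ImputationLog",
    "OutlierResult",
    "CohortSummary",
    "impute_missing",
    "flag_outliers_boxplot",
    "aggregate_daily",
    "cohort_summary",
]

# Published per-participant totals for the 16-adult MOX2-5 cohort.
# Columns: days of data collection, daily records considered, and totals of
# sedentary/VPA/MPA/LPA seconds and steps over the full wear period.
_STUDY_ROWS = [
    # id, days, records, sedentary_s, vpa_s, mpa_s, lpa_s, steps
    ("P1", 43, 43, 3_512_792, 8_510, 52_196, 183_702, 392_512),
    ("P2", 48, 48, 4_261_190, 50_214, 95_730, 200_524, 588_132),
    ("P3", 30, 30, 2_293_208, 24_248, 62_502, 65_494, 273_708),
    ("P4", 31, 31, 3_065_884, 15_156, 23_402, 254_332, 442_365),
    ("P5", 30, 30, 2_402_790, 43_104, 57_606, 123_170, 398_029),
    ("P6", 30, 30, 2_316_338, 51_094, 64_885, 77_141, 305_673),
    ("P7", 39, 39, 3_784_340, 78_908, 53_876, 245_160, 398_296),
    ("P8", 31, 31, 3_028_756, 112, 38_230, 103_480, 252_551),
    ("P9", 32, 32, 2_623_966, 30_722, 72_308, 153_174, 419_063),
    ("P10", 31, 31, 2_395_160, 27_024, 58_846, 120_820, 347_144),
    ("P11", 33, 33, 3_061_236, 15_432, 45_440, 247_896, 436_404),
    ("P12", 31, 31, 590_028, 25_142, 37_680, 151_150, 271_888),
    ("P13", 31, 31, 2_297_915, 10_006, 27_487, 135_314, 269_258),
    ("P14", 30, 30, 1_963_218, 14_891, 39_670, 193_226, 320_134),
    ("P15", 38, 38, 925_614, 256_896, 58_212, 32_272, 411_033),
    ("P16", 31, 31, 664_302, 18_746, 63_638, 187_498, 341_063),
]

STUDY_COHORT_TOTALS = pd.DataFrame(
    _STUDY_ROWS,
    columns=[
        "Participant", "Duration", "Records",
        "TotalSedentary", "TotalVPA", "TotalMPA", "TotalLPA", "TotalSteps",
    ],
).set_index("Participant")


@dataclass
class ImputationLog:
    """Per-fill record: series index and the method used."""

    fills: list[tuple[object, str]] = field(default_factory=list)


@dataclass
class OutlierResult:
    flags: pd.Series          # boolean, True where outside the fences
    lower_fence: float
    upper_fence: float
    treated: pd.Series | None = None  # winsorized/dropped series when requested


@dataclass
class CohortSummary:
    """Per-column mean/SD/min/max over participants plus the record-count sum."""

    stats: pd.DataFrame       # index: column names; columns: mean, sd, min, max
    n_participants: int
    total_records: int
    notes: list[str] = field(default_factory=list)


def impute_missing(series: pd.Series) -> tuple[pd.Series, ImputationLog]:
    """Fill gaps by averaging forward and backward fills.

    An interior missing value becomes the arithmetic mean of the nearest
    preceding and nearest following observed values; a leading or trailing gap
    takes the nearest observed value.  Raises on an all-missing series.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if series.isna().all():
        raise ValueError("all values missing; nothing to impute from")
    fwd = series.ffill()
    bwd = series.bfill()
    log = ImputationLog()
    out = series.copy().astype(float)
    for idx in series.index[series.isna()]:
        f, b = fwd.loc[idx], bwd.loc[idx]
        if pd.isna(f):
            out.loc[idx], method = b, "leading-nearest"
        elif pd.isna(b):
            out.loc[idx], method = f, "trailing-nearest"
        else:
            out.loc[idx], method = (f + b) / 2.0, "interior-mean"
        log.fills.append((idx, method))
    return out, log


def flag_outliers_boxplot(
    series: pd.Series,
    treat: Literal["none", "winsorize", "drop"] = "none",
) -> OutlierResult:
    """Flag values outside the 1.5·IQR boxplot fences.

    Quartiles use linear interpolation.  ``treat="winsorize"`` clips flagged
    values to the nearer fence; ``treat="drop"`` removes them.
    """
    values = series.dropna()
    if len(values) < 4:
        raise ValueError("need at least 4 finite values for boxplot fences")
    q1, q3 = np.percentile(values.astype(float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = (series < lo) | (series > hi)
    flags = flags.fillna(False)
    treated = None
    if treat == "winsorize":
        treated = series.clip(lower=lo, upper=hi)
    elif treat == "drop":
        treated = series[~flags]
    return OutlierResult(flags=flags, lower_fence=float(lo), upper_fence=float(hi), treated=treated)


def aggregate_daily(
    minutes: Sequence[MinuteRecord], participant_id: str
) -> list[DayRecord]:
    """Aggregate minute epochs into per-day totals, grouped by calendar date.

    Second fields, steps and IMA are summed; ``minutes_observed`` counts the
    epochs seen.  The timestamp itself is dropped from the analysis table.
    Days with fewer than 1440 minutes are retained (no wear-time minimum is
    imposed); an empty input yields an empty output.
    """
    by_date: dict[_dt.date, list[MinuteRecord]] = {}
    for r in minutes:
        by_date.setdefault(r.timestamp.date(), []).append(r)
    days = []
    for date in sorted(by_date):
        recs = by_date[date]
        days.append(
            DayRecord(
                participant_id=participant_id,
                date=date,
                sedentary_s=sum(r.sedentary_s for r in recs),
                lpa_s=sum(r.lpa_s for r in recs),
                mpa_s=sum(r.mpa_s for r in recs),
                vpa_s=sum(r.vpa_s for r in recs),
                weight_bearing_s=sum(r.weight_bearing_s for r in recs),
                standing_s=sum(r.standing_s for r in recs),
                steps=sum(r.steps for r in recs),
                ima=sum(r.ima_sum for r in recs),
                minutes_observed=len(recs),
            )
        )
    return days


def cohort_summary(totals: pd.DataFrame, ddof: int = 1) -> CohortSummary:
    """Per-column mean/SD/min/max over per-participant totals.

    ``totals`` is one row per participant (numeric columns only are
    summarized; a ``Records`` column, when present, is additionally summed
    into ``total_records``).  SD uses the sample convention (``ddof=1``) by
    default; for a single participant SD is reported as 0 with a note.
    """
    if len(totals) == 0:
        raise ValueError("empty cohort table")
    numeric = totals.select_dtypes("number")
    notes: list[str] = []
    if len(totals) == 1 and ddof == 1:
        sd = pd.Series(0.0, index=numeric.columns)
        notes.append("single participant: sample SD undefined, reported as 0")
    else:
        sd = numeric.std(ddof=ddof)
    stats = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "sd": sd,
            "min": numeric.min(),
            "max": numeric.max(),
        }
    )
    total_records = int(numeric["Records"].sum()) if "Records" in numeric else int(len(totals))
    return CohortSummary(
        stats=stats,
        n_participants=len(totals),
        total_records=total_records,
        notes=notes,
    )
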
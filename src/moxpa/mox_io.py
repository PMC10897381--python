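"""Reading, validation and writing of MOX2-5 minute-epoch and daily tabular data.

The MOX2-5 activity monitor reports one record per 60-second window: an IMA
(inertial movement analysis) count sum, seconds of weight-bearing, sedentary,
standing and light/moderate/vigorous activity classification, and a step sum.
Within each window the classified seconds obey a conservation identity::

    sedentary + standing + weight_bearing + (LPA + MPA + VPA) = 60 s

``validate_minute_record`` checks this identity together with field ranges;
violations are reported, never silently dropped.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MinuteRecord",
    "DayRecord",
    "ParticipantProfile",
    "ValidationResult",
    "ReadReport",
    "MINUTE_COLUMNS",
    "DAILY_COLUMNS",
    "read_minute_csv",
    "write_minute_csv",
    "validate_minute_record",
    "read_daily_csv",
    "write_daily_csv",
]

#: Column order of a minute-level CSV (device algorithm-value order).
MINUTE_COLUMNS = [
    "Timestamp",
    "UploadStatus",
    "IMA",
    "WeightBearing",
    "Sedentary",
    "Standing",
    "LPA",
    "MPA",
    "VPA",
    "Steps",
]

#: Column order of a daily analysis table (matching the deposited datasets).
DAILY_COLUMNS = ["Sedentary", "LPA", "MPA", "VPA", "Steps"]

#: Seconds-valued fields of a minute record, in conservation-sum order.
_SECOND_FIELDS = ("sedentary_s", "standing_s", "weight_bearing_s", "lpa_s", "mpa_s", "vpa_s")


@dataclass(frozen=True)
class MinuteRecord:
    """One 60-second epoch of MOX2-5 output.

    ``timestamp`` is the start of the window; ``upload_status`` is ``"H"``
    (history) or ``"L"`` (live).  All ``*_s`` fields are seconds within the
    window, ``ima_sum`` and ``steps`` are nonnegative counts.
    """

    timestamp: _dt.datetime
    upload_status: str
    ima_sum: int
    weight_bearing_s: int
    sedentary_s: int
    standing_s: int
    lpa_s: int
    mpa_s: int
    vpa_s: int
    steps: int

    def active_s(self) -> int:
        """Seconds of classified activity (LPA + MPA + VPA)."""
        return self.lpa_s + self.mpa_s + self.vpa_s


@dataclass(frozen=True)
class DayRecord:
    """Per-participant daily aggregate of minute records."""

    participant_id: str
    date: _dt.date
    sedentary_s: int
    lpa_s: int
    mpa_s: int
    vpa_s: int
    weight_bearing_s: int
    standing_s: int
    steps: int
    ima: int
    minutes_observed: int


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics of one study participant."""

    id: str
    age: float | None = None
    sex: str | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    education: str | None = None

    def __post_init__(self) -> None:
        if None not in (self.height_cm, self.weight_kg, self.bmi):
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(implied - self.bmi) > 0.02 * implied:
                raise ValueError(
                    f"BMI {self.bmi} inconsistent with height/weight (implies {implied:.2f})"
                )


@dataclass
class ValidationResult:
    """Verdict of ``validate_minute_record``: ``ok`` iff no violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class ReadReport:
    """Parse outcome of ``read_minute_csv``."""

    n_parsed: int = 0
    n_rejected: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)


def validate_minute_record(r: MinuteRecord, tolerance_s: float = 0.0) -> ValidationResult:
    """Check field ranges and the 60-second conservation identity.

    Returns a :class:`ValidationResult` listing every violated rule; it never
    raises.  ``tolerance_s`` relaxes the conservation check to absorb device
    rounding in real files (fixtures are validated at 0).
    """
    res = ValidationResult()
    for name in _SECOND_FIELDS:
        v = getattr(r, name)
        if not 0 <= v <= 60:
            res.violations.append(f"{name}={v} outside [0, 60]")
    if r.steps < 0:
        res.violations.append(f"steps={r.steps} negative")
    if r.ima_sum < 0:
        res.violations.append(f"ima_sum={r.ima_sum} negative")
    if r.upload_status not in ("H", "L"):
        res.violations.append(f"upload_status={r.upload_status!r} not in {{'H','L'}}")
    total = sum(getattr(r, name) for name in _SECOND_FIELDS)
    if abs(total - 60) > tolerance_s:
        res.violations.append(
            f"conservation violation: second fields sum to {total}, expected 60 "
            f"(deviation {total - 60:+g} s)"
        )
    return res


def _parse_timestamp(raw: str) -> _dt.datetime:
    """Parse a window-start timestamp: unix epoch seconds or ISO-8601."""
    raw = raw.strip()
    if raw.isdigit():
        return _dt.datetime.fromtimestamp(int(raw), tz=_dt.timezone.utc).replace(tzinfo=None)
    return _dt.datetime.fromisoformat(raw)


def _parse_row(row: dict[str, str]) -> MinuteRecord:
    ts = _parse_timestamp(row["Timestamp"])
    status = row["UploadStatus"].strip()
    ints = {}
    for col, attr in zip(MINUTE_COLUMNS[2:],
                         ("ima_sum", "weight_bearing_s", "sedentary_s", "standing_s",
                          "lpa_s", "mpa_s", "vpa_s", "steps")):
        v = int(float(row[col]))
        if v < 0:
            raise ValueError(f"{col}={v} negative")
        ints[attr] = v
    for attr in ("weight_bearing_s", "sedentary_s", "standing_s", "lpa_s", "mpa_s", "vpa_s"):
        if ints[attr] > 60:
            raise ValueError(f"{attr}={ints[attr]} outside [0, 60]")
    return MinuteRecord(timestamp=ts, upload_status=status, **ints)


def read_minute_csv(path: str | Path) -> tuple[list[MinuteRecord], ReadReport]:
    """Read a minute-level CSV, rejecting malformed rows with line numbers.

    Rows failing timestamp parsing or range checks are logged in the returned
    :class:`ReadReport` and excluded; they are never silently coerced.
    Records are returned sorted by timestamp.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in MINUTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    report = ReadReport()
    records: list[MinuteRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line_no = i + 2  # header is line 1
        try:
            records.append(_parse_row(row))
            report.n_parsed += 1
        except (ValueError, KeyError, TypeError) as exc:
            report.n_rejected += 1
            report.rejects.append((line_no, str(exc)))
    records.sort(key=lambda r: r.timestamp)
    return records, report


def write_minute_csv(records: Iterable[MinuteRecord], path: str | Path) -> None:
    """Write minute records in the device column order (RFC-4180 CSV)."""
    rows = [
        {
            "Timestamp": r.timestamp.isoformat(),
            "UploadStatus": r.upload_status,
            "IMA": r.ima_sum,
            "WeightBearing": r.weight_bearing_s,
            "Sedentary": r.sedentary_s,
            "Standing": r.standing_s,
            "LPA": r.lpa_s,
            "MPA": r.mpa_s,
            "VPA": r.vpa_s,
            "Steps": r.steps,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MINUTE_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_daily_csv(path: str | Path) -> pd.DataFrame:
    """Read a daily analysis table (``Sedentary,LPA,MPA,VPA,Steps[,Active]``)."""
    df = pd.read_csv(path)
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    return df


def write_daily_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a daily analysis table, keeping the deposited column layout."""
    cols = [c for c in DAILY_COLUMNS + ["Active"] if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, lineterminator="\n")


def day_records_to_table(days: Sequence[DayRecord]) -> pd.DataFrame:
    """Convert DayRecords to the five-feature analysis table (seconds/day, steps/day)."""
    return pd.DataFrame(
        {
            "Sedentary": [d.sedentary_s for d in days],
            "LPA": [d.lpa_s for d in days],
            "MPA": [d.mpa_s for d in days],
            "VPA": [d.vpa_s for d in days],
            "Steps": [d.steps for d in days],
        }
    )
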
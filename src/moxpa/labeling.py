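"""Intensity banding (IMA counts, cps, METs) and daily activity-level labeling.

The MOX2-5 algorithm maps per-minute IMA counts onto intensity bands with
closed integer intervals (LPA 0–400, MPA 401–800, VPA ≥ 801).  For an
upper-leg placement the cycles-per-second thresholds are half-open
(4.5 < LPA ≤ 11.9, 11.9 < MPA ≤ 26.8, VPA > 26.8 cps); the MET equivalents
are LPA 1.5–3, MPA 3–6 and VPA ≥ 6 METs.

Daily activity levels (0 = Sedentary … 4 = Highly active) follow standard
step-count / weekly-MVPA rules.  Each level is a disjunction of a
steps-and-MVPA clause and a plain steps-band clause, with weekly MVPA
computed as (2·VPA + MPA)·7 from daily minutes (vigorous minutes counted
double, mirroring WHO's weekly 150–300 min moderate-equivalent guidance).
The rules overlap; by default the highest satisfied level wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .mox_io import DayRecord

__all__ = [
    "IntensityThresholds",
    "ActivityLevel",
    "ACTIVITY_LEVEL_NAMES",
    "intensity_from_ima",
    "intensity_from_cps",
    "intensity_from_met",
    "weekly_mvpa_minutes",
    "label_activity_level",
    "label_table",
]

ACTIVITY_LEVEL_NAMES = {
    0: "Sedentary",
    1: "Low active",
    2: "Active",
    3: "Medium active",
    4: "Highly active",
}


@dataclass(frozen=True)
class IntensityThresholds:
    """Cut-points of the three intensity schemes (IMA counts, cps, METs)."""

    ima_lpa_max: int = 400       # LPA: 0 <= IMA <= 400 (closed)
    ima_mpa_max: int = 800       # MPA: 401 <= IMA <= 800; VPA: IMA >= 801
    cps_lpa_min: float = 4.5     # LPA: 4.5 < cps <= 11.9 (upper-leg placement)
    cps_mpa_min: float = 11.9    # MPA: 11.9 < cps <= 26.8
    cps_vpa_min: float = 26.8    # VPA: cps > 26.8
    met_lpa_min: float = 1.5     # LPA: 1.5 <= MET < 3
    met_mpa_min: float = 3.0     # MPA: 3 <= MET < 6
    met_vpa_min: float = 6.0     # VPA: MET >= 6 ("6.0 or more")


@dataclass(frozen=True)
class ActivityLevel:
    """A daily activity-level assignment and the rule disjunct that won."""

    code: int
    rule_fired: str

    @property
    def name(self) -> str:
        return ACTIVITY_LEVEL_NAMES[self.code]


_DEFAULT = IntensityThresholds()


def intensity_from_ima(ima: float, thresholds: IntensityThresholds = _DEFAULT) -> str:
    """Band a per-minute IMA count: LPA 0–400, MPA 401–800, VPA ≥ 801."""
    if ima < 0:
        raise ValueError(f"IMA must be nonnegative, got {ima}")
    if ima <= thresholds.ima_lpa_max:
        return "LPA"
    if ima <= thresholds.ima_mpa_max:
        return "MPA"
    return "VPA"


def intensity_from_cps(
    cps: float,
    placement: str = "upper-leg",
    thresholds: IntensityThresholds = _DEFAULT,
) -> str:
    """Band a cycles-per-second value; only upper-leg thresholds are defined.

    Values at or below 4.5 cps fall below the light-activity cut and are
    returned as ``"below-LPA"``.
    """
    if placement != "upper-leg":
        raise ValueError(f"no published cps thresholds for placement {placement!r}")
    if cps < 0:
        raise ValueError(f"cps must be nonnegative, got {cps}")
    if cps <= thresholds.cps_lpa_min:
        return "below-LPA"
    if cps <= thresholds.cps_mpa_min:
        return "LPA"
    if cps <= thresholds.cps_vpa_min:
        return "MPA"
    return "VPA"


def intensity_from_met(met: float, thresholds: IntensityThresholds = _DEFAULT) -> str:
    """Band a MET value; boundaries go to the upper band (3 → MPA, 6 → VPA)."""
    if met < 0:
        raise ValueError(f"MET must be nonnegative, got {met}")
    if met >= thresholds.met_vpa_min:
        return "VPA"
    if met >= thresholds.met_mpa_min:
        return "MPA"
    if met >= thresholds.met_lpa_min:
        return "LPA"
    return "below-LPA"


def weekly_mvpa_minutes(vpa_min: float, mpa_min: float) -> float:
    """Weekly moderate-equivalent minutes: (2·VPA + MPA) · 7, from daily minutes."""
    return (2.0 * vpa_min + mpa_min) * 7.0


def _fired_disjuncts(steps: float, vpa_min: float, mpa_min: float, lpa_min: float) -> list[tuple[int, str]]:
    """All satisfied (level, disjunct) pairs of the ten labeling clauses."""
    wm = weekly_mvpa_minutes(vpa_min, mpa_min)
    fired: list[tuple[int, str]] = []
    # Level 0 — Sedentary
    if steps < 5000 and wm < 90 and lpa_min >= 0:
        fired.append((0, "steps<5000 & weekly-MVPA<90"))
    if steps < 5000:
        fired.append((0, "steps<5000"))
    # Level 1 — Low active
    if steps > 4999 and 90 <= wm < 210:
        fired.append((1, "steps>4999 & 90<=weekly-MVPA<210"))
    if 4999 < steps < 7500:
        fired.append((1, "4999<steps<7500"))
    # Level 2 — Active
    if steps > 4999 and 210 <= wm < 300:
        fired.append((2, "steps>4999 & 210<=weekly-MVPA<300"))
    if 7499 < steps < 10000:
        fired.append((2, "7499<steps<10000"))
    # Level 3 — Medium active
    if steps > 4999 and 300 <= wm < 360:
        fired.append((3, "steps>4999 & 300<=weekly-MVPA<360"))
    if 9999 < steps < 12500:
        fired.append((3, "9999<steps<12500"))
    # Level 4 — Highly active
    if steps > 4999 and wm >= 360:
        fired.append((4, "steps>4999 & weekly-MVPA>=360"))
    if steps > 12499:
        fired.append((4, "steps>12499"))
    return fired


def label_activity_level(
    day: DayRecord | None = None,
    *,
    steps: float | None = None,
    vpa_min: float | None = None,
    mpa_min: float | None = None,
    lpa_min: float = 0.0,
    policy: Literal["highest", "lowest"] = "highest",
) -> ActivityLevel:
    """Assign the daily activity level (0–4) from steps and MVPA minutes.

    Accepts either a :class:`DayRecord` (seconds are converted to minutes/day
    before the rules apply) or explicit daily ``steps`` / ``vpa_min`` /
    ``mpa_min`` minutes.  Rules overlap; ``policy`` picks among the satisfied
    levels (default: the highest level wins).
    """
    if day is not None:
        steps = day.steps
        vpa_min = day.vpa_s / 60.0
        mpa_min = day.mpa_s / 60.0
        lpa_min = day.lpa_s / 60.0
    if steps is None or vpa_min is None or mpa_min is None:
        raise ValueError("provide a DayRecord or steps, vpa_min and mpa_min")
    if min(steps, vpa_min, mpa_min, lpa_min) < 0:
        raise ValueError("steps and activity minutes must be nonnegative")
    fired = _fired_disjuncts(steps, vpa_min, mpa_min, lpa_min)
    if policy == "highest":
        code, rule = max(fired)
    else:
        code, rule = min(fired)
    return ActivityLevel(code=code, rule_fired=rule)


def label_table(table: pd.DataFrame, policy: Literal["highest", "lowest"] = "highest") -> pd.DataFrame:
    """Append the integer ``Active`` column (0–4) to a daily analysis table.

    Time columns are expected in seconds/day and are converted to minutes
    before the rules apply; ``Steps`` is the daily step count.
    """
    out = table.copy()
    out["Active"] = [
        label_activity_level(
            steps=row.Steps,
            vpa_min=row.VPA / 60.0,
            mpa_min=row.MPA / 60.0,
            lpa_min=row.LPA / 60.0,
            policy=policy,
        ).code
        for row in table.itertuples()
    ]
    return out
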
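"""Construction of long glycemia courses from CGM sessions and scenarios.

A continuous glucose monitor covers only a few six-day windows out of the
~120-day erythrocyte life span, so the glucose history driving the
glycation model has to be extrapolated.  Two schemes are provided:

* WW ("working day / weekend"): all recorded workdays are point-wise
  averaged into one representative workday and likewise for weekend
  days; the two averaged daily profiles are tiled in a 5 + 2 weekly
  pattern over the horizon.
* ID ("individual days"): the recorded days are cycled in chronological
  order, unaveraged, until the horizon is filled.  Both schemes preserve
  mean glucose; ID preserves the recorded between-day variability, which
  the WW averaging suppresses.

Parametric scenario profiles (step, rectangle, ramp, composite daily
patterns) generate the idealized glycemic histories used in simulation
experiments.  All outputs are daily-mean plasma glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import GlucoseProfile

__all__ = [
    "CgmDay",
    "CgmSessionSet",
    "ScenarioSpec",
    "read_cgm_csv",
    "ww_extrapolate",
    "id_extrapolate",
    "scenario_profile",
    "profile_stats",
]

DAY_TYPES = ("workday", "weekend")


@dataclass(frozen=True)
class CgmDay:
    """One recorded day of CGM samples on a fixed intra-day grid."""

    date: pd.Timestamp
    day_type: str
    glucose: np.ndarray  # plasma-aligned mmol/l, one value per grid point

    def __post_init__(self) -> None:
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"day_type must be one of {DAY_TYPES}, got {self.day_type!r}")
        g = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "glucose", g)
        if g.size == 0 or np.any(~np.isfinite(g)) or np.any(g <= 0):
            raise ValueError("CGM day must contain finite positive glucose values")

    @property
    def mean(self) -> float:
        return float(self.glucose.mean())


@dataclass(frozen=True)
class CgmSessionSet:
    """All recorded CGM days for one subject, sharing one intra-day grid."""

    days: tuple[CgmDay, ...]

    def __post_init__(self) -> None:
        if not self.days:
            raise ValueError("session set contains no recorded days")
        n = self.days[0].glucose.size
        if any(d.glucose.size != n for d in self.days):
            raise ValueError("all CGM days must share one intra-day grid")
        object.__setattr__(self, "days", tuple(self.days))

    @property
    def samples_per_day(self) -> int:
        return self.days[0].glucose.size

    def of_type(self, day_type: str) -> list[CgmDay]:
        return [d for d in self.days if d.day_type == day_type]


def read_cgm_csv(path: str | Path, max_gap_hours: float = 2.0) -> CgmSessionSet:
    """Read CGM samples (timestamp, glucose_mmol_l[, day_type]) into days.

    Samples are binned on the grid implied by the median sampling
    interval.  Missing grid points inside a day are filled by linear
    interpolation when the gap does not exceed ``max_gap_hours``;
    otherwise the day is dropped.  Without a day_type column, weekdays
    are labelled from the calendar (Saturday/Sunday -> weekend).
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if df.empty:
        raise ValueError(f"no CGM samples in {path}")
    step = df["timestamp"].sort_values().diff().dropna().median()
    samples_per_day = int(round(pd.Timedelta(days=1) / step))
    days: list[CgmDay] = []
    for date, group in df.groupby(df["timestamp"].dt.normalize()):
        group = group.sort_values("timestamp")
        slot = (
            (group["timestamp"] - date) / pd.Timedelta(days=1) * samples_per_day
        ).round().astype(int).clip(0, samples_per_day - 1)
        grid = np.full(samples_per_day, np.nan)
        grid[slot.to_numpy()] = group["glucose_mmol_l"].to_numpy(dtype=float)
        missing = np.isnan(grid)
        if missing.any():
            max_gap = _longest_run(missing) * (pd.Timedelta(days=1) / samples_per_day)
            if max_gap > pd.Timedelta(hours=max_gap_hours):
                continue  # unusable day
            idx = np.arange(samples_per_day)
            grid[missing] = np.interp(idx[missing], idx[~missing], grid[~missing])
        if "day_type" in group:
            day_type = str(group["day_type"].iloc[0])
        else:
            day_type = "weekend" if date.dayofweek >= 5 else "workday"
        days.append(CgmDay(date, day_type, grid))
    return CgmSessionSet(tuple(days))


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def ww_extrapolate(sessions: CgmSessionSet, horizon_days: int = 120) -> GlucoseProfile:
    """Workday/weekend extrapolation of a CGM record to ``horizon_days``.

    Point-wise averages all workdays into one daily profile and all
    weekend days into another, tiles a Monday-start week (5 workdays
    then 2 weekend days), and reduces to daily means.
    """
    work = sessions.of_type("workday")
    rest = sessions.of_type("weekend")
    if not work or not rest:
        raise ValueError("WW extrapolation needs at least one workday and one weekend day")
    work_mean = float(np.mean([d.glucose for d in work], axis=0).mean())
    rest_mean = float(np.mean([d.glucose for d in rest], axis=0).mean())
    week = np.array([work_mean] * 5 + [rest_mean] * 2)
    reps = int(np.ceil(horizon_days / 7))
    return GlucoseProfile(np.tile(week, reps)[:horizon_days])


def averaged_daily_profiles(sessions: CgmSessionSet) -> dict[str, np.ndarray]:
    """The two point-wise averaged intra-day profiles behind WW."""
    out = {}
    for day_type in DAY_TYPES:
        days = sessions.of_type(day_type)
        if days:
            out[day_type] = np.mean([d.glucose for d in days], axis=0)
    return out


def id_extrapolate(sessions: CgmSessionSet, horizon_days: int = 120) -> GlucoseProfile:
    """Individual-days extrapolation: cycle the recorded days unaveraged.

    Days are repeated in chronological order until the horizon is
    filled; each day keeps its own mean, so the output preserves the
    recorded between-day variability.
    """
    ordered = sorted(sessions.days, key=lambda d: d.date)
    means = np.array([d.mean for d in ordered])
    reps = int(np.ceil(horizon_days / means.size))
    return GlucoseProfile(np.tile(means, reps)[:horizon_days])


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric glycemia scenario.

    kind
        step — ``baseline`` until ``change_day`` (0-based), ``level`` after;
        rectangle — ``level`` for ``duration_days`` then ``baseline``;
        ramp — linear daily interpolation ``baseline`` -> ``level`` over
        ``duration_days``, holding ``level`` afterwards;
        composite — ``base_day`` daily pattern with ``hypo_day`` substituted
        at ``frequency`` (1/period days).
    """

    kind: Literal["step", "rectangle", "ramp", "composite"]
    baseline: float = 5.6
    level: float | None = None
    change_day: int = 0
    duration_days: int = 0
    base_day: Sequence[float] | None = None
    hypo_day: Sequence[float] | None = None
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "rectangle", "ramp", "composite"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.baseline <= 0 or (self.level is not None and self.level <= 0):
            raise ValueError("glucose levels must be > 0")
        if self.duration_days < 0:
            raise ValueError("duration_days must be >= 0")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")


def scenario_profile(spec: ScenarioSpec, horizon_days: int) -> GlucoseProfile:
    """Realize a :class:`ScenarioSpec` as a daily glucose profile."""
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    if spec.kind == "step":
        bg = np.full(horizon_days, float(spec.level))
        bg[: spec.change_day] = spec.baseline
        return GlucoseProfile(bg)
    if spec.kind == "rectangle":
        bg = np.full(horizon_days, spec.baseline)
        bg[: min(spec.duration_days, horizon_days)] = float(spec.level)
        return GlucoseProfile(bg)
    if spec.kind == "ramp":
        ramp = np.linspace(spec.baseline, float(spec.level), spec.duration_days)
        bg = np.full(horizon_days, float(spec.level))
        bg[: min(spec.duration_days, horizon_days)] = ramp[:horizon_days]
        return GlucoseProfile(bg)
    # composite: daily patterns -> daily means, special day every 1/frequency days
    if spec.base_day is None or spec.hypo_day is None:
        raise ValueError("composite scenario needs base_day and hypo_day patterns")
    base = float(np.mean(np.asarray(spec.base_day, dtype=float)))
    hypo = float(np.mean(np.asarray(spec.hypo_day, dtype=float)))
    if base <= 0 or hypo <= 0:
        raise ValueError("daily patterns must be positive")
    bg = np.full(horizon_days, base)
    if spec.frequency > 0:
        period = max(1, int(round(1.0 / spec.frequency)))
        bg[period - 1 :: period] = hypo
    return GlucoseProfile(bg)


def profile_stats(profile: GlucoseProfile) -> dict[str, float]:
    """Mean (MBG) and population SD of the daily glucose values, mmol/l."""
    return {"mbg": profile.mbg, "sd": profile.sd}
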
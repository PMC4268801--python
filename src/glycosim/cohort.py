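"""Erythrocyte-cohort hemoglobin glycation model.

Hemoglobin glycation in a cohort of same-aged red cells follows
second-order kinetics in the non-glycated hemoglobin HbA and the plasma
glucose concentration BG:

    d HbA / dt = -k * HbA * BG

with k the overall glycation rate constant (l mmol^-1 s^-1).  For a
glucose level held constant over an interval the solution is exact:
the glycated fraction after cumulative exposure E = integral BG dt
(mmol day l^-1) is 1 - exp(-k_day * E) with k_day = 86400 k.

The circulating population is represented by ``lifespan_days`` equal
sized cohorts aged 1..LS days.  Each simulated day every cohort updates
its glycated fraction with that day's glucose, the oldest cohort is
eliminated (chronological removal), and a fresh reticulocyte cohort with
zero glycated hemoglobin enters.  Cells are released continuously over
the day, so the entering cohort is credited half of its birth-day
exposure; with this midpoint convention the population mean at steady
state agrees with the continuous-age closed form

    HbA1c(%) = 91.5 * (1 - (1 - e^-x) / x) + 2.15,   x = k * LS * MBG

(LS in seconds here) to well below printed precision.  Blood HbA1c is
the cell-weighted mean glycated fraction over all cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .units import DEFAULT_EQUATION, HbA1cValue, NgspIfccEquation

__all__ = [
    "SECONDS_PER_DAY",
    "DEFAULT_K",
    "K_SD",
    "GlycationParams",
    "GlucoseProfile",
    "CohortPopulation",
    "glycated_fraction",
    "advance_day",
    "population_hba1c",
    "simulate_course",
    "steady_state_hba1c",
    "steady_state_fraction",
]

SECONDS_PER_DAY = 86400.0

#: Population mean and SD of the overall glycation rate constant in adults
#: with type 1 or type 2 diabetes (l mmol^-1 s^-1).
DEFAULT_K = 1.296e-9
K_SD = 0.216e-9


@dataclass(frozen=True)
class GlycationParams:
    """Kinetic parameters of the cohort model.

    Parameters
    ----------
    k
        Overall glycation rate constant, l mmol^-1 s^-1.  Physiological
        values are around 1.3e-9 with ~17% between-subject CV.
    lifespan_days
        Erythrocyte life span LS in days (default 120); the model keeps
        exactly LS cohorts.
    step_days
        Glycation update interval in days for sub-daily glucose inputs
        (in vitro sawtooth); must divide one day.  In vivo dynamics are
        always advanced a day at a time.
    """

    k: float = DEFAULT_K
    lifespan_days: int = 120
    step_days: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"glycation rate constant k must be > 0, got {self.k}")
        if int(self.lifespan_days) != self.lifespan_days or self.lifespan_days < 1:
            raise ValueError(f"lifespan_days must be an integer >= 1, got {self.lifespan_days}")
        steps_per_day = 1.0 / self.step_days
        if self.step_days <= 0 or abs(steps_per_day - round(steps_per_day)) > 1e-9:
            raise ValueError(f"step_days must divide one day, got {self.step_days}")

    @property
    def k_day(self) -> float:
        """Rate constant per (mmol/l)/day: k * 86400."""
        return self.k * SECONDS_PER_DAY

    @property
    def lifespan_seconds(self) -> float:
        return self.lifespan_days * SECONDS_PER_DAY


@dataclass(frozen=True)
class GlucoseProfile:
    """A uniform time grid of plasma glucose concentrations (mmol/l).

    Daily profiles (step_days == 1) drive the in vivo model; sub-daily
    grids are used for the in vitro sawtooth.
    """

    bg: np.ndarray
    step_days: float = 1.0

    def __post_init__(self) -> None:
        bg = np.asarray(self.bg, dtype=float)
        object.__setattr__(self, "bg", bg)
        if bg.ndim != 1 or bg.size == 0:
            raise ValueError("glucose profile must be a non-empty 1-D series")
        if not np.all(np.isfinite(bg)):
            raise ValueError("glucose profile contains non-finite values (gaps?)")
        if np.any(bg <= 0):
            raise ValueError("glucose must be strictly positive everywhere")

    @property
    def t(self) -> np.ndarray:
        """Time grid in days, starting at one step."""
        return (np.arange(self.bg.size) + 1) * self.step_days

    @property
    def n_days(self) -> float:
        return self.bg.size * self.step_days

    @property
    def mbg(self) -> float:
        """Mean glucose over the profile, mmol/l."""
        return float(self.bg.mean())

    @property
    def sd(self) -> float:
        """Population standard deviation of the profile, mmol/l."""
        return float(self.bg.std())

    def daily_means(self) -> "GlucoseProfile":
        """Collapse a sub-daily grid to daily mean glucose."""
        per_day = round(1.0 / self.step_days)
        if per_day == 1:
            return self
        if self.bg.size % per_day:
            raise ValueError("profile does not cover whole days")
        return GlucoseProfile(self.bg.reshape(-1, per_day).mean(axis=1), 1.0)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"day_index": np.arange(1, self.bg.size + 1), "bg_mmol_l": self.bg}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GlucoseProfile":
        df = pd.read_csv(path)
        return cls(df["bg_mmol_l"].to_numpy(dtype=float))


@dataclass(frozen=True)
class CohortPopulation:
    """Per-age state of the red-cell population.

    ``glycated_fraction_by_age[i]`` and ``cells_by_age[i]`` belong to the
    cohort aged ``i + 1`` days.  Cell weights are relative (one unit per
    cohort in vivo); in vitro they shrink as cells die.
    """

    glycated_fraction_by_age: np.ndarray
    cells_by_age: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.glycated_fraction_by_age, dtype=float)
        w = np.asarray(self.cells_by_age, dtype=float)
        object.__setattr__(self, "glycated_fraction_by_age", f)
        object.__setattr__(self, "cells_by_age", w)
        if f.shape != w.shape or f.ndim != 1 or f.size == 0:
            raise ValueError("fractions and cell weights must be equal-length 1-D arrays")
        if np.any((f < -1e-12) | (f > 1 + 1e-12)):
            raise ValueError("glycated fractions must lie in [0, 1]")
        if np.any(w < 0):
            raise ValueError("cell weights must be non-negative")

    @property
    def ages_days(self) -> np.ndarray:
        return np.arange(1, self.glycated_fraction_by_age.size + 1)

    @property
    def lifespan_days(self) -> int:
        return self.glycated_fraction_by_age.size

    @property
    def total_cells(self) -> float:
        return float(self.cells_by_age.sum())

    @classmethod
    def zero(cls, lifespan_days: int) -> "CohortPopulation":
        """All cohorts present, none glycated (used to seed history-free runs)."""
        return cls(np.zeros(lifespan_days), np.ones(lifespan_days))

    @classmethod
    def steady_state(cls, level: float, params: GlycationParams) -> "CohortPopulation":
        """Age profile after indefinite exposure to constant glucose ``level``.

        The cohort aged a has accumulated (a - 1/2) days of exposure
        (half a day on its release day), so f(a) = 1 - exp(-k_day *
        level * (a - 1/2)).  This state is an exact fixed point of
        :func:`advance_day` at the same glucose level.
        """
        if level <= 0:
            raise ValueError("glucose level must be > 0")
        ages = np.arange(1, params.lifespan_days + 1, dtype=float)
        f = -np.expm1(-params.k_day * level * (ages - 0.5))
        return cls(f, np.ones(params.lifespan_days))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "age_days": self.ages_days,
                "glycated_fraction": self.glycated_fraction_by_age,
                "cells": self.cells_by_age,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortPopulation":
        df = pd.read_csv(path).sort_values("age_days")
        return cls(
            df["glycated_fraction"].to_numpy(dtype=float),
            df["cells"].to_numpy(dtype=float),
        )


def glycated_fraction(exposure: float, params: GlycationParams) -> float:
    """Glycated fraction after cumulative glucose exposure (mmol day l^-1).

    Closed-form solution of the second-order kinetics for a cohort that
    started fully non-glycated: 1 - exp(-k_day * exposure).
    """
    if exposure < 0:
        raise ValueError(f"exposure must be >= 0, got {exposure}")
    return float(-np.expm1(-params.k_day * exposure))


def advance_day(
    state: CohortPopulation, bg_today: float, params: GlycationParams
) -> CohortPopulation:
    """One day of in vivo dynamics.

    The oldest cohort is eliminated, surviving cohorts age by one day and
    glycate with today's glucose (exact exponential update within the
    day), and a new reticulocyte cohort enters with zero glycated
    hemoglobin, accruing half a day of today's exposure.  Cohort count is
    conserved at LS.
    """
    if bg_today <= 0:
        raise ValueError(f"glucose must be > 0, got {bg_today}")
    if state.lifespan_days != params.lifespan_days:
        raise ValueError("population size does not match params.lifespan_days")
    decay = np.exp(-params.k_day * bg_today)
    f = np.empty_like(state.glycated_fraction_by_age)
    f[1:] = 1.0 - (1.0 - state.glycated_fraction_by_age[:-1]) * decay
    f[0] = -np.expm1(-params.k_day * bg_today * 0.5)
    w = np.empty_like(state.cells_by_age)
    w[1:] = state.cells_by_age[:-1]
    w[0] = 1.0
    return CohortPopulation(f, w)


def population_hba1c(
    state: CohortPopulation, equation: NgspIfccEquation = DEFAULT_EQUATION
) -> HbA1cValue:
    """Blood HbA1c of a population: cell-weighted mean glycated fraction."""
    total = state.total_cells
    if total <= 0:
        raise ValueError("population has no cells")
    mean_fraction = float(
        np.dot(state.glycated_fraction_by_age, state.cells_by_age) / total
    )
    return HbA1cValue.from_fraction(min(max(mean_fraction, 0.0), 1.0), equation)


def simulate_course(
    profile: GlucoseProfile,
    params: GlycationParams,
    init: CohortPopulation | float,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
    keep_states: bool = False,
) -> pd.DataFrame:
    """Run the cohort model over a daily glucose profile.

    Parameters
    ----------
    profile
        Daily plasma glucose, mmol/l.
    init
        Either an explicit :class:`CohortPopulation` or a constant
        glucose level (mmol/l) from which the steady-state age profile is
        built.
    keep_states
        If True, attach the full population snapshot per day in a
        ``state`` column (needed to seed in vitro runs).

    Returns
    -------
    DataFrame with columns day (1..N), bg_mmol_l, fraction, ngsp_percent,
    ifcc_mmol_mol and optionally state.
    """
    daily = profile.daily_means()
    state = (
        CohortPopulation.steady_state(float(init), params)
        if not isinstance(init, CohortPopulation)
        else init
    )
    rows = []
    for day, bg in enumerate(daily.bg, start=1):
        state = advance_day(state, float(bg), params)
        value = population_hba1c(state, equation)
        row = {
            "day": day,
            "bg_mmol_l": float(bg),
            "fraction": value.glycated_fraction,
            "ngsp_percent": value.ngsp_percent,
            "ifcc_mmol_mol": value.ifcc_mmol_per_mol,
        }
        if keep_states:
            row["state"] = state
        rows.append(row)
    return pd.DataFrame(rows)


def steady_state_fraction(mbg: float, params: GlycationParams) -> float:
    """Continuous-age mean glycated fraction at constant glucose.

    1 - (1 - e^-x)/x with x = k * LS_seconds * MBG; series expansion for
    tiny x to avoid cancellation.
    """
    if mbg <= 0:
        raise ValueError(f"MBG must be > 0, got {mbg}")
    x = params.k * params.lifespan_seconds * mbg
    if x < 1e-6:
        return x / 2.0 - x * x / 6.0
    return float(1.0 + np.expm1(-x) / x)


def steady_state_hba1c(
    mbg: float,
    params: GlycationParams,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> HbA1cValue:
    """Closed-form HbA1c at constant glucose held over a full life span.

    On the NGSP scale this is the analytic relation
    91.5 * (1 - (1 - e^-x)/x) + 2.15 with x = k * LS * MBG (LS in
    seconds), up to the configured master-equation coefficients.
    Strictly increasing in mbg, k and LS.
    """
    return HbA1cValue.from_fraction(steady_state_fraction(mbg, params), equation)
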
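"""Simulation experiments relating glycemic histories to HbA1c.

These are the model's standard thought experiments: step changes of
glycemia (sudden treatment success or failure), a transient 30-day
hyperglycemic rectangle, 120-day linear ramps, steady-state curves under
altered erythrocyte life spans, and glycemia courses with hypoglycemic
days interleaved at varying frequency.  Each scenario starts from the
steady state of the pre-event glucose level (established glycemia before
day zero) and reports HbA1c at chosen evaluation days, optionally with
an uncertainty band obtained by re-running the model with k at the
bounds of its population 95% interval (mean +/- 1.96 SD).

A recurring observation: profiles sharing the same 120-day mean glucose
can produce HbA1c values differing by several percentage points while
the glycemic history is unstable, because recent days weigh more heavily
in the surviving cohorts' exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    DEFAULT_K,
    K_SD,
    CohortPopulation,
    GlucoseProfile,
    GlycationParams,
    population_hba1c,
    simulate_course,
    steady_state_hba1c,
)
from .kestim import _history_profile
from .profiles import ScenarioSpec, scenario_profile
from .units import DEFAULT_EQUATION, HbA1cValue, NgspIfccEquation

__all__ = [
    "ScenarioResult",
    "step_response",
    "rectangle_response",
    "ramp_response",
    "lifespan_steady_curves",
    "hypo_frequency_course",
    "hba1c_ordering_probability",
    "final_hba1c_fractions",
]


@dataclass(frozen=True)
class ScenarioResult:
    """HbA1c at the evaluation days, with a k-uncertainty band."""

    eval_days: np.ndarray
    hba1c: tuple[HbA1cValue, ...]
    band_low: np.ndarray  # NGSP % at k_mean - 1.96 SD
    band_high: np.ndarray  # NGSP % at k_mean + 1.96 SD

    def __post_init__(self) -> None:
        ngsp = self.ngsp
        if np.any(self.band_low > ngsp + 1e-12) or np.any(self.band_high < ngsp - 1e-12):
            raise ValueError("uncertainty band does not contain the central estimate")

    @property
    def ngsp(self) -> np.ndarray:
        return np.array([v.ngsp_percent for v in self.hba1c])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.eval_days,
                "hba1c_ngsp": self.ngsp,
                "band_low": self.band_low,
                "band_high": self.band_high,
            }
        )


def _trajectory(
    bg: np.ndarray,
    init_level: float,
    params: GlycationParams,
    eval_days: np.ndarray,
    equation: NgspIfccEquation,
) -> np.ndarray:
    """NGSP HbA1c at the given day indices (0 = pre-event steady state)."""
    init = CohortPopulation.steady_state(init_level, params)
    values = np.empty(eval_days.size)
    if bg.size:
        course = simulate_course(GlucoseProfile(bg), params, init, equation)
        ngsp_by_day = course["ngsp_percent"].to_numpy()
    else:
        ngsp_by_day = np.empty(0)
    day0 = population_hba1c(init, equation).ngsp_percent
    for i, d in enumerate(eval_days):
        values[i] = day0 if d == 0 else ngsp_by_day[d - 1]
    return values


def _with_band(
    bg: np.ndarray,
    init_level: float,
    params: GlycationParams,
    eval_days: Sequence[int],
    k_sd: float,
    equation: NgspIfccEquation,
) -> ScenarioResult:
    days = np.asarray(list(eval_days), dtype=int)
    if days.size == 0 or np.any(days < 0) or (days.size and bg.size < days.max()):
        raise ValueError("eval_days must be non-negative and within the simulated span")
    central = _trajectory(bg, init_level, params, days, equation)
    if k_sd > 0:
        lo_params = replace(params, k=max(params.k - 1.96 * k_sd, 1e-12))
        hi_params = replace(params, k=params.k + 1.96 * k_sd)
        low = _trajectory(bg, init_level, lo_params, days, equation)
        high = _trajectory(bg, init_level, hi_params, days, equation)
    else:
        low = high = central
    hba1c = tuple(HbA1cValue.from_ngsp(v, equation) for v in central)
    return ScenarioResult(days, hba1c, low, high)


def step_response(
    pre_level: float,
    post_level: float,
    eval_days: Sequence[int],
    params: GlycationParams = GlycationParams(),
    k_sd: float = K_SD,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> ScenarioResult:
    """HbA1c after glycemia steps from ``pre_level`` to ``post_level`` at day 0.

    Starts from the steady state of the pre-step level; by one life span
    after the step the population has fully turned over and HbA1c equals
    the steady state of the post-step level.
    """
    if pre_level <= 0 or post_level <= 0:
        raise ValueError("glucose levels must be > 0")
    horizon = max(int(max(eval_days, default=0)), 1)
    bg = np.full(horizon, float(post_level))
    return _with_band(bg, pre_level, params, eval_days, k_sd, equation)


def rectangle_response(
    baseline: float,
    level: float,
    duration_days: int,
    eval_days: Sequence[int],
    params: GlycationParams = GlycationParams(),
    k_sd: float = K_SD,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> ScenarioResult:
    """HbA1c after a ``duration_days`` glycemic excursion to ``level``.

    The excursion sits on a steady ``baseline`` and ends at day 0;
    ``eval_days`` count from the end of the excursion (day 0 = the
    excursion's last day, where HbA1c peaks for a hyperglycemic
    rectangle).
    """
    if baseline <= 0 or level <= 0:
        raise ValueError("glucose levels must be > 0")
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    days = np.asarray(list(eval_days), dtype=int)
    horizon = duration_days + max(int(days.max(initial=0)), 0)
    bg = np.full(horizon, float(baseline))
    bg[:duration_days] = float(level)
    result = _with_band(bg, baseline, params, days + duration_days, k_sd, equation)
    return ScenarioResult(days, result.hba1c, result.band_low, result.band_high)


def ramp_response(
    start_level: float,
    end_level: float,
    duration_days: int = 120,
    params: GlycationParams = GlycationParams(),
    k_sd: float = K_SD,
    eval_days: Sequence[int] | None = None,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> ScenarioResult:
    """HbA1c along a linear daily glycemia ramp from steady state.

    By default only the ramp's final day is reported.  An improvement
    ramp and a deterioration ramp between the same two levels share
    their mean glucose yet end at clearly different HbA1c: the model
    weights recent glycemia more strongly.
    """
    if start_level <= 0 or end_level <= 0:
        raise ValueError("glucose levels must be > 0")
    spec = ScenarioSpec("ramp", baseline=start_level, level=end_level, duration_days=duration_days)
    bg = scenario_profile(spec, duration_days).bg
    days = eval_days if eval_days is not None else [duration_days]
    return _with_band(bg, start_level, params, days, k_sd, equation)


def lifespan_steady_curves(
    mbg_grid: Sequence[float],
    k: float = DEFAULT_K,
    lifespans: Sequence[int] = (60, 80, 100, 120, 140, 160),
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> pd.DataFrame:
    """Steady-state HbA1c vs MBG for several erythrocyte life spans.

    Longer-lived cells glycate longer, so the curves are strictly
    ordered by life span at every MBG (relevant to hemolytic anemia,
    where a shortened life span depresses HbA1c at unchanged glycemia).

    Returns a DataFrame indexed by MBG with one NGSP column per life span.
    """
    grid = np.asarray(list(mbg_grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("MBG grid must be positive and non-empty")
    data = {
        int(ls): [
            steady_state_hba1c(g, GlycationParams(k=k, lifespan_days=int(ls)), equation).ngsp_percent
            for g in grid
        ]
        for ls in lifespans
    }
    return pd.DataFrame(data, index=pd.Index(grid, name="mbg_mmol_l"))


def hypo_frequency_course(
    base_day: Sequence[float],
    hypo_day: Sequence[float],
    frequency: float,
    params: GlycationParams = GlycationParams(),
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> HbA1cValue:
    """Final HbA1c of a life-span-long course with interleaved hypo days.

    The hypoglycemic daily pattern replaces the base pattern
    deterministically every 1/frequency days (frequency 0 = never,
    1 = every day).  The course itself supplies the cohort history (one
    full pass from an unglycated population), mirroring how measured
    HbA1c reflects the preceding life span of glycemia.
    """
    spec = ScenarioSpec(
        "composite", base_day=tuple(base_day), hypo_day=tuple(hypo_day), frequency=frequency
    )
    profile = scenario_profile(spec, params.lifespan_days)
    course = simulate_course(
        profile, params, CohortPopulation.zero(params.lifespan_days), equation
    )
    return HbA1cValue.from_fraction(float(course["fraction"].iloc[-1]), equation)


def final_hba1c_fractions(
    profile: GlucoseProfile, k_values: np.ndarray, lifespan_days: int = 120
) -> np.ndarray:
    """Terminal mean glycated fraction for many k values at once.

    Uses the closed-form per-cohort solution: the cohort aged a on the
    final day accumulated half its birth-day glucose plus the following
    a - 1 full days, so its fraction is 1 - exp(-k_day * E_a).  The
    course is cycled to one life span if shorter.  Vectorized over k for
    Monte Carlo use; exactly matches the day-by-day simulation.
    """
    bg = _history_profile(profile, lifespan_days).bg
    suffix = np.concatenate([np.cumsum(bg[::-1])[::-1], [0.0]])  # suffix[i] = sum bg[i:]
    born = lifespan_days - np.arange(1, lifespan_days + 1)  # birth index of cohort age a
    exposures = suffix[born + 1] + 0.5 * bg[born]
    k_day = np.atleast_1d(np.asarray(k_values, dtype=float)) * 86400.0
    frac = 1.0 - np.exp(-np.outer(k_day, exposures))
    return frac.mean(axis=1)


def hba1c_ordering_probability(
    profile_a: GlucoseProfile,
    profile_b: GlucoseProfile,
    k_mean: float = DEFAULT_K,
    k_sd: float = K_SD,
    n_draws: int = 100_000,
    seed: int | np.random.Generator = 0,
    lifespan_days: int = 120,
) -> float:
    """P[HbA1c on course A exceeds HbA1c on course B] across subjects.

    Two independent subjects with k drawn from the population
    distribution (normal truncated to k > 0) experience courses A and B;
    between-subject variation in the glycation rate can invert the
    HbA1c ordering expected from the glucose levels alone.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if k_sd == 0:
        ka = kb = np.array([k_mean])
    else:
        a = (0.0 - k_mean) / k_sd
        ka = stats.truncnorm.rvs(a, np.inf, loc=k_mean, scale=k_sd, size=n_draws, random_state=rng)
        kb = stats.truncnorm.rvs(a, np.inf, loc=k_mean, scale=k_sd, size=n_draws, random_state=rng)
    fa = final_hba1c_fractions(profile_a, ka, lifespan_days)
    fb = final_hba1c_fractions(profile_b, kb, lifespan_days)
    return float(np.mean(fa > fb))
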
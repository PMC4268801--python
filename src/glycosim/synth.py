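"""Synthetic patients, CGM sessions, HbA1c assays and cultures.

No patient-level data accompany the glycation-rate study design this
package implements, so parameter-recovery and end-to-end tests run on
synthetic subjects with the same statistical structure: a per-subject
glycation rate constant drawn from the population distribution
(mean 1.296e-9, SD 0.216e-9 l mmol^-1 s^-1, CV ~17%), diurnal glucose
patterns built from a basal level plus three Gaussian meal excursions,
type 1 subjects running ~1.2 mmol/l higher and more variable than
type 2, CGM coverage of three six-day sensor sessions separated by
multi-week gaps, HbA1c measured as the mean of five replicates, and
erythrocyte cultures with exponentially decaying viable-cell counts and
a daily glucose sawtooth whose amplitude shrinks with viability.

Every generator is bit-reproducible under its seed.  The generated
truth is always computed with the package's own forward model, so
recovery tests probe the estimation path, not the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_K,
    K_SD,
    CohortPopulation,
    GlucoseProfile,
    GlycationParams,
    simulate_course,
)
from .invitro import CultureRecord, RemovalMode, simulate_culture
from .kestim import model_hba1c_for_profile
from .profiles import CgmDay, CgmSessionSet
from .units import DEFAULT_EQUATION, HbA1cValue, NgspIfccEquation

__all__ = [
    "SyntheticPatient",
    "SyntheticCulture",
    "make_patient_cohort",
    "true_course",
    "make_cgm_sessions",
    "make_hba1c_measurement",
    "make_culture",
]

#: Culture medium nominal glucose levels, plasma-equivalent mmol/l.
CULTURE_LEVELS = (5.2, 10.5, 15.7)

# Daily-pattern defaults per diabetes type: basal mean/SD (mmol/l), meal
# excursion amplitudes (mmol/l), and the SD of day-to-day offsets of the
# whole profile.  Chosen so mean MBG is ~8.7 (type 1) vs ~7.5 (type 2),
# the reported contrast, with modest day-to-day variation consistent
# with subjects under stable metabolic control.
_TYPE_DEFAULTS = {
    1: {"basal_mean": 7.40, "basal_sd": 0.9, "amplitudes": (2.5, 3.0, 2.8), "day_sd": 0.8},
    2: {"basal_mean": 6.55, "basal_sd": 0.6, "amplitudes": (1.8, 2.2, 2.0), "day_sd": 0.6},
}
_MEAL_TIMES_H = (7.5, 13.0, 19.0)
_MEAL_WIDTH_H = 1.5


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic subject: kinetics plus diurnal-pattern parameters."""

    patient_id: int
    true_k: float  # l mmol^-1 s^-1
    diabetes_type: int  # 1 or 2
    basal: float  # mmol/l
    meal_amplitudes: tuple[float, float, float]
    meal_times_h: tuple[float, float, float] = _MEAL_TIMES_H
    meal_width_h: float = _MEAL_WIDTH_H
    between_day_sd: float = 0.8  # SD of whole-day offsets, mmol/l
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_k <= 0:
            raise ValueError("true_k must be > 0")
        if self.diabetes_type not in (1, 2):
            raise ValueError("diabetes_type must be 1 or 2")
        if self.basal <= 0 or any(a < 0 for a in self.meal_amplitudes):
            raise ValueError("glucose pattern components must be positive")

    def daily_pattern(self, hours: np.ndarray) -> np.ndarray:
        """Noise-free diurnal glucose at clock hours (mmol/l)."""
        bg = np.full_like(np.asarray(hours, dtype=float), self.basal)
        for amp, t0 in zip(self.meal_amplitudes, self.meal_times_h):
            bg = bg + amp * np.exp(-0.5 * ((hours - t0) / self.meal_width_h) ** 2)
        return bg

    @property
    def true_mbg(self) -> float:
        """Mean of the noise-free diurnal pattern (day offsets average out)."""
        hours = (np.arange(288) + 0.5) * 24.0 / 288.0
        return float(self.daily_pattern(hours).mean())


def make_patient_cohort(
    n: int,
    k_mean: float = DEFAULT_K,
    k_sd: float = K_SD,
    seed: int = 0,
) -> list[SyntheticPatient]:
    """Draw n synthetic subjects, alternating type 1 and type 2.

    true_k ~ Normal(k_mean, k_sd) truncated to > 0 (by resampling);
    basal levels and meal amplitudes are jittered per subject.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        k = rng.normal(k_mean, k_sd) if k_sd > 0 else k_mean
        while k <= 0:
            k = rng.normal(k_mean, k_sd)
        dtype = 1 if i % 2 == 0 else 2
        cfg = _TYPE_DEFAULTS[dtype]
        basal = max(float(rng.normal(cfg["basal_mean"], cfg["basal_sd"])), 3.5)
        amps = tuple(float(a * rng.uniform(0.8, 1.2)) for a in cfg["amplitudes"])
        patients.append(
            SyntheticPatient(
                patient_id=i,
                true_k=float(k),
                diabetes_type=dtype,
                basal=basal,
                meal_amplitudes=amps,  # type: ignore[arg-type]
                between_day_sd=cfg["day_sd"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return patients


def _day_offsets(patient: SyntheticPatient, horizon_days: int) -> np.ndarray:
    """Whole-day glucose offsets, one per calendar day; fixed by the
    patient's seed so the CGM sessions sample the same realized days
    that the true course integrates."""
    rng = np.random.default_rng(patient.seed)
    return rng.normal(0.0, patient.between_day_sd, size=horizon_days)


def true_course(patient: SyntheticPatient, horizon_days: int = 120) -> GlucoseProfile:
    """The subject's realized daily-mean glucose over the horizon."""
    base = patient.true_mbg
    bg = np.maximum(base + _day_offsets(patient, horizon_days), 1.0)
    return GlucoseProfile(bg)


def make_cgm_sessions(
    patient: SyntheticPatient,
    n_sensors: int = 3,
    days_per_sensor: int = 6,
    gaps_days: Sequence[int] = (28, 15),
    sample_minutes: int = 5,
    noise_sd: float = 0.3,
    seed: int | None = None,
) -> CgmSessionSet:
    """Simulate sensor sessions over the subject's realized glucose days.

    Sessions of ``days_per_sensor`` consecutive days are separated by the
    given gaps and right-aligned so the last sensor ends on day 120 (the
    HbA1c draw).  Each sampled day is the diurnal pattern plus that
    day's realized offset plus autocorrelated sensor noise (AR(1),
    lag-1 correlation 0.9, stationary SD ``noise_sd``).  Workday/weekend
    labels follow a Monday-start calendar.
    """
    if n_sensors < 1 or days_per_sensor < 1 or len(gaps_days) < n_sensors - 1:
        raise ValueError("invalid CGM session layout")
    rng = np.random.default_rng(patient.seed + 1 if seed is None else seed)
    horizon = 120
    offsets = _day_offsets(patient, horizon)
    samples_per_day = 24 * 60 // sample_minutes
    hours = (np.arange(samples_per_day) + 0.5) * 24.0 / samples_per_day
    pattern = patient.daily_pattern(hours)

    # last session ends on the final day of the 120-day window
    starts = []
    end = horizon
    for s in range(n_sensors - 1, -1, -1):
        start = end - days_per_sensor
        starts.append(start)
        if s > 0:
            end = start - gaps_days[s - 1]
    starts.reverse()
    if starts[0] < 0:
        raise ValueError("sessions do not fit in the 120-day window")

    phi = 0.9
    innov_sd = noise_sd * np.sqrt(1.0 - phi**2)
    days: list[CgmDay] = []
    t0 = pd.Timestamp("2014-03-03")  # a Monday
    for start in starts:
        for d in range(start, start + days_per_sensor):
            noise = np.empty(samples_per_day)
            noise[0] = rng.normal(0.0, noise_sd)
            for i in range(1, samples_per_day):
                noise[i] = phi * noise[i - 1] + rng.normal(0.0, innov_sd)
            bg = np.maximum(pattern + offsets[d] + noise, 1.0)
            date = t0 + pd.Timedelta(days=d)
            day_type = "weekend" if date.dayofweek >= 5 else "workday"
            days.append(CgmDay(date, day_type, bg))
    return CgmSessionSet(tuple(days))


def make_hba1c_measurement(
    patient: SyntheticPatient,
    assay_sd: float = 0.05,  # NGSP %, per replicate
    replicates: int = 5,
    seed: int | None = None,
    lifespan_days: int = 120,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> HbA1cValue:
    """HbA1c at the end of the 120-day window: replicate mean with noise.

    The underlying truth runs the forward model over the subject's
    realized course at true_k (the course is the full cohort history);
    each replicate adds independent Normal(0, assay_sd) on the NGSP
    scale.
    """
    rng = np.random.default_rng(patient.seed + 2 if seed is None else seed)
    params = GlycationParams(k=patient.true_k, lifespan_days=lifespan_days)
    truth = model_hba1c_for_profile(true_course(patient, lifespan_days), params, equation)
    if assay_sd > 0:
        reps = truth.ngsp_percent + rng.normal(0.0, assay_sd, size=replicates)
        return HbA1cValue.from_ngsp(float(reps.mean()), equation)
    return truth


@dataclass(frozen=True)
class SyntheticCulture:
    """One generated culture: its records, the seeding population and the
    removal mode used as generating truth."""

    glucose_level: float  # nominal plasma-equivalent mmol/l
    records: tuple[CultureRecord, ...]
    init_state: CohortPopulation
    true_mode: RemovalMode


def make_culture(
    patient: SyntheticPatient,
    glucose_levels: Sequence[float] = CULTURE_LEVELS,
    days: int = 35,
    decay_rate: float = 0.05,  # per day, viable-count exponential decay
    obs_noise: float = 0.0,  # NGSP % SD on measured HbA1c
    true_mode: RemovalMode = RemovalMode("combined", 0.5),
    seed: int | None = None,
    lifespan_days: int = 120,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> list[SyntheticCulture]:
    """Generate cultures of the subject's erythrocytes at several levels.

    The seeding state is the in vivo end-state of the subject's realized
    course.  Viable counts decay exponentially; the daily sawtooth drop
    of medium glucose shrinks proportionally to viability (fewer cells
    metabolize less glucose).  Measured HbA1c is the forward prediction
    under ``true_mode`` plus observation noise.
    """
    if days < 1 or days > 35:
        raise ValueError("culture duration must be 1..35 days")
    if any(g <= 0 for g in glucose_levels):
        raise ValueError("glucose levels must be positive")
    rng = np.random.default_rng(patient.seed + 3 if seed is None else seed)
    params = GlycationParams(k=patient.true_k, lifespan_days=lifespan_days)
    course = simulate_course(
        true_course(patient, lifespan_days),
        params,
        CohortPopulation.zero(lifespan_days),
        equation,
        keep_states=True,
    )
    init_state: CohortPopulation = course["state"].iloc[-1]

    day_idx = np.arange(1, days + 1)
    viable = np.exp(-decay_rate * day_idx)
    cultures = []
    for level in glucose_levels:
        medium_nominal = level * 1.06  # medium scale
        drop0 = 0.8  # mmol/l consumed per day at full viability
        recs = []
        for d, v in zip(day_idx, viable):
            start = medium_nominal
            end = max(start - drop0 * v, 0.5)
            recs.append(CultureRecord(int(d), start, end, float(v)))
        predicted = simulate_culture(init_state, recs, params, true_mode, equation=equation)
        measured = predicted["ngsp_percent"].to_numpy().copy()
        if obs_noise > 0:
            measured = measured + rng.normal(0.0, obs_noise, size=measured.size)
        recs = [
            CultureRecord(
                r.day,
                r.medium_glucose_start,
                r.medium_glucose_end,
                r.viable_fraction,
                HbA1cValue.from_ngsp(float(m), equation),
            )
            for r, m in zip(recs, measured)
        ]
        cultures.append(SyntheticCulture(float(level), tuple(recs), init_state, true_mode))
    return cultures
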
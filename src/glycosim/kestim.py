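"""Estimation of the overall glycation rate constant k.

Given a 120-day (or life-span-long) glycemia course and one measured
HbA1c, the cohort model's terminal HbA1c is a strictly increasing
function of k, so k is found by bisection until the modeled and measured
HbA1c agree to within 0.05 mmol/mol on the IFCC scale.  The model is
initialized history-free: the course itself supplies each cohort's full
exposure history (the cohort aged a on the final day has lived through
exactly the last a days of the course), which is why the course must
span at least one life span.

Under constant glycemia the model admits the closed form

    HbA1c(%) = 91.5 * (1 - (1 - e^-x)/x) + 2.15,  x = k * LS * MBG

(LS in seconds), which is inverted by monotone root finding to give the
analytic estimate of k from the mean glucose alone.  Because k and LS
enter the model only through their product, a life-span sweep shows k
scaling roughly inversely with the assumed life span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    CohortPopulation,
    GlucoseProfile,
    GlycationParams,
    simulate_course,
    steady_state_fraction,
)
from .units import DEFAULT_EQUATION, HbA1cValue, NgspIfccEquation

__all__ = [
    "IFCC_TOLERANCE",
    "K_BRACKET",
    "KEstimate",
    "model_hba1c_for_profile",
    "estimate_k_iterative",
    "k_from_mbg_analytic",
    "lifespan_sweep",
]

#: Stopping rule of the iterative fit: |modeled - measured| on the IFCC
#: scale, mmol/mol (equivalently 0.046% NGSP).
IFCC_TOLERANCE = 0.05

#: Search bracket for k (l mmol^-1 s^-1); covers the physiological range
#: (population range roughly 0.96-1.80 x 1e-9) with wide margins.
K_BRACKET = (1e-10, 1e-8)

MAX_ITERATIONS = 60


@dataclass(frozen=True)
class KEstimate:
    """Result of a rate-constant fit."""

    k: float  # l mmol^-1 s^-1
    method: str  # ww_iterative | id_iterative | analytic_mbg
    lifespan_days: int
    residual_ifcc: float  # |modeled - measured| at termination, mmol/mol
    iterations: int

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "method": self.method,
            "lifespan_days": self.lifespan_days,
            "residual_ifcc": self.residual_ifcc,
            "iterations": self.iterations,
        }


def _history_profile(profile: GlucoseProfile, lifespan_days: int) -> GlucoseProfile:
    """The last life span of the course; shorter courses are cycled out."""
    bg = profile.daily_means().bg
    if bg.size < lifespan_days:
        reps = int(np.ceil(lifespan_days / bg.size))
        bg = np.tile(bg, reps)
    return GlucoseProfile(bg[-lifespan_days:])


def model_hba1c_for_profile(
    profile: GlucoseProfile,
    params: GlycationParams,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> HbA1cValue:
    """Terminal model HbA1c with the course as the full cohort history.

    Runs the last ``lifespan_days`` of the profile from an unglycated
    population, so the cohort aged a at the end has seen exactly the last
    a days.
    """
    hist = _history_profile(profile, params.lifespan_days)
    course = simulate_course(hist, params, CohortPopulation.zero(params.lifespan_days), equation)
    return HbA1cValue.from_fraction(float(course["fraction"].iloc[-1]), equation)


def estimate_k_iterative(
    profile: GlucoseProfile,
    measured: HbA1cValue,
    lifespan_days: int = 120,
    method: str = "ww_iterative",
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> KEstimate:
    """Fit k by bisection so the modeled HbA1c matches the measurement.

    The comparison runs on the IFCC scale and stops when the absolute
    difference drops below 0.05 mmol/mol.  The modeled HbA1c is strictly
    increasing in k, so bisection on the bracket (1e-10, 1e-8) always
    converges; an error is raised if the measurement falls outside the
    HbA1c range the bracket can produce.
    """
    if measured.ngsp_percent <= equation.ngsp_floor:
        raise ValueError(
            f"measured HbA1c {measured.ngsp_percent:.3f}% is at or below the "
            f"non-glycated floor {equation.ngsp_floor:.3f}%"
        )
    target = measured.ifcc_mmol_per_mol

    def model_ifcc(k: float) -> float:
        params = GlycationParams(k=k, lifespan_days=lifespan_days)
        return model_hba1c_for_profile(profile, params, equation).ifcc_mmol_per_mol

    lo, hi = K_BRACKET
    f_lo = model_ifcc(lo) - target
    f_hi = model_ifcc(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"measured HbA1c {measured.ngsp_percent:.2f}% not bracketed by "
            f"k in {K_BRACKET} on this profile (model range "
            f"{f_lo + target:.1f}..{f_hi + target:.1f} mmol/mol)"
        )
    iterations = 0
    k_mid = 0.5 * (lo + hi)
    residual = np.inf
    while iterations < MAX_ITERATIONS:
        iterations += 1
        k_mid = 0.5 * (lo + hi)
        f_mid = model_ifcc(k_mid) - target
        residual = abs(f_mid)
        if residual < IFCC_TOLERANCE:
            break
        if f_mid < 0:
            lo = k_mid
        else:
            hi = k_mid
    if residual >= IFCC_TOLERANCE:
        raise RuntimeError(
            f"bisection did not reach {IFCC_TOLERANCE} mmol/mol in {MAX_ITERATIONS} iterations"
        )
    return KEstimate(k_mid, method, lifespan_days, residual, iterations)


def k_from_mbg_analytic(
    mbg: float,
    measured: HbA1cValue,
    lifespan_days: int = 120,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> KEstimate:
    """Analytic k from the mean glucose, inverting the closed form.

    Solves 1 - (1 - e^-x)/x = measured glycated fraction for x and
    returns k = x / (LS_seconds * MBG).
    """
    if mbg <= 0:
        raise ValueError(f"MBG must be > 0, got {mbg}")
    if measured.ngsp_percent <= equation.ngsp_floor:
        raise ValueError("measured HbA1c at or below the non-glycated floor")
    if measured.ngsp_percent >= equation.ngsp_ceiling:
        raise ValueError(
            f"measured HbA1c {measured.ngsp_percent:.2f}% is at or above the "
            f"fully-glycated asymptote {equation.ngsp_ceiling:.2f}%"
        )
    m = measured.glycated_fraction

    def objective(x: float) -> float:
        return (1.0 + np.expm1(-x) / x) - m

    lo, hi = 1e-12, 1.0
    while objective(hi) < 0:
        hi *= 10.0
        if hi > 1e8:
            raise RuntimeError("failed to bracket the analytic solution")
    x = brentq(objective, lo, hi, xtol=1e-14, rtol=1e-14)
    ls_seconds = lifespan_days * 86400.0
    return KEstimate(x / (ls_seconds * mbg), "analytic_mbg", lifespan_days, 0.0, 0)


def lifespan_sweep(
    profile: GlucoseProfile,
    measured: HbA1cValue,
    lifespans: Sequence[int] = (60, 80, 100, 120, 140, 160),
    method: str = "ww_iterative",
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> dict[int, KEstimate]:
    """Re-fit k under alternative assumed erythrocyte life spans.

    The shorter the assumed life span, the higher the fitted glycation
    rate must be (k decreases monotonically across increasing life
    spans); their product stays nearly constant.
    """
    return {
        int(ls): estimate_k_iterative(profile, measured, int(ls), method, equation)
        for ls in lifespans
    }
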
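"""HbA1c prediction during erythrocyte culture.

Cultured red cells keep glycating but are neither replaced nor (in the
model) born: the simulation starts from the in vivo end-state of the
cohort population and, each day, applies the glycation update driven by
the medium glucose and then removes exactly the cell mass implied by the
measured viable-cell fraction.  Because no method observes *which* cells
die, four removal modes are compared:

* chronological — oldest cohorts truncated first (in vivo senescence);
* counter_chronological — youngest first (a deliberately unphysiological
  control: it inflates HbA1c because the cells removed carry less
  glycated hemoglobin than average);
* uniform — every cohort scaled by the same survival factor;
* combined — a fixed share of each day's loss chronological, the rest
  uniform (default half and half); the best-performing assumption.

Medium glucose is replaced daily, so its concentration follows a daily
sawtooth: it is interpolated linearly within each day between the
measured start and end values and divided by 1.06 to convert the medium
scale to plasma equivalents.  Prediction error against measured HbA1c is
summarized by the mean difference (MD) and mean absolute difference
(MAD) on the NGSP scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortPopulation, GlucoseProfile, GlycationParams, population_hba1c
from .units import (
    DEFAULT_EQUATION,
    DEFAULT_GLUCOSE_CONFIG,
    GlucoseConversionConfig,
    HbA1cValue,
    NgspIfccEquation,
    medium_to_plasma_equivalent,
)

__all__ = [
    "CultureRecord",
    "RemovalMode",
    "sawtooth_glucose",
    "simulate_culture",
    "md_mad",
]

REMOVAL_KINDS = ("chronological", "counter_chronological", "uniform", "combined")


@dataclass(frozen=True)
class CultureRecord:
    """One culture day: medium glucose at medium change and a day later,
    plus the viable-cell fraction relative to day 0."""

    day: int
    medium_glucose_start: float  # mmol/l, medium scale
    medium_glucose_end: float
    viable_fraction: float
    measured_hba1c: HbA1cValue | None = None

    def __post_init__(self) -> None:
        if self.medium_glucose_start <= 0 or self.medium_glucose_end <= 0:
            raise ValueError("medium glucose must be > 0")
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValueError("viable_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class RemovalMode:
    """Which cells die when the viable count drops."""

    kind: Literal["chronological", "counter_chronological", "uniform", "combined"]
    combined_weight: float = 0.5  # share of the daily loss removed chronologically

    def __post_init__(self) -> None:
        if self.kind not in REMOVAL_KINDS:
            raise ValueError(f"removal kind must be one of {REMOVAL_KINDS}")
        if not 0.0 <= self.combined_weight <= 1.0:
            raise ValueError("combined_weight must lie in [0, 1]")


def sawtooth_glucose(
    records: Sequence[CultureRecord],
    steps_per_day: int = 24,
    config: GlucoseConversionConfig = DEFAULT_GLUCOSE_CONFIG,
) -> GlucoseProfile:
    """Sub-daily plasma-equivalent glucose implied by the daily sawtooth.

    Within each day the medium concentration falls linearly from the
    start to the end value (evaluated at sub-step midpoints, so the day
    mean is exactly the start/end average); the medium is then replaced,
    producing a discontinuity.  Values are divided by the medium water
    factor.
    """
    if not records:
        raise ValueError("no culture records")
    mid = (np.arange(steps_per_day) + 0.5) / steps_per_day
    chunks = []
    for rec in sorted(records, key=lambda r: r.day):
        chunks.append(rec.medium_glucose_start + mid * (rec.medium_glucose_end - rec.medium_glucose_start))
    medium = np.concatenate(chunks)
    return GlucoseProfile(medium_to_plasma_equivalent(medium, config), 1.0 / steps_per_day)


def _remove_chronological(w: np.ndarray, loss: float, oldest_first: bool) -> None:
    """Truncate ``loss`` cell mass cohort by cohort, in place; the boundary
    cohort is removed fractionally so the target is met exactly."""
    order = range(w.size - 1, -1, -1) if oldest_first else range(w.size)
    for i in order:
        if loss <= 0:
            break
        take = min(w[i], loss)
        w[i] -= take
        loss -= take


def simulate_culture(
    init: CohortPopulation,
    records: Sequence[CultureRecord],
    params: GlycationParams,
    mode: RemovalMode,
    steps_per_day: int = 24,
    config: GlucoseConversionConfig = DEFAULT_GLUCOSE_CONFIG,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> pd.DataFrame:
    """Predict the daily HbA1c course of one culture.

    Each day the surviving cohorts glycate under the sawtooth glucose
    (the exact exponential update makes this equivalent to using the
    day's cumulative exposure), then cell mass is removed so the
    surviving mass equals init mass x the day's viable fraction.  No new
    cohorts enter.

    Returns a DataFrame with columns day, ngsp_percent, ifcc_mmol_mol,
    fraction, cell_mass.
    """
    recs = sorted(records, key=lambda r: r.day)
    viable = np.array([r.viable_fraction for r in recs])
    if np.any(np.diff(viable) > 1e-12):
        raise ValueError("viable_fraction must be non-increasing over culture days")
    f = init.glycated_fraction_by_age.copy()
    w = init.cells_by_age.astype(float).copy()
    init_mass = w.sum()
    rows = []
    for rec in recs:
        # glycation first: exact update with the day's cumulative exposure
        day_profile = sawtooth_glucose([rec], steps_per_day, config)
        exposure = day_profile.bg.mean()  # mmol day / l over one day
        f = 1.0 - (1.0 - f) * np.exp(-params.k_day * exposure)
        # then removal down to the measured viable mass
        target = init_mass * rec.viable_fraction
        current = w.sum()
        loss = current - target
        if loss < -1e-9:
            raise ValueError(f"viable_fraction implies cell gain on day {rec.day}")
        if mode.kind == "uniform":
            w *= target / current if current > 0 else 0.0
        elif mode.kind == "chronological":
            _remove_chronological(w, loss, oldest_first=True)
        elif mode.kind == "counter_chronological":
            _remove_chronological(w, loss, oldest_first=False)
        else:  # combined
            _remove_chronological(w, mode.combined_weight * loss, oldest_first=True)
            current = w.sum()
            if current > 0:
                w *= target / current
        mass = w.sum()
        if mass <= 0:
            warnings.warn(f"culture extinct on day {rec.day}; stopping", stacklevel=2)
            break
        value = population_hba1c(CohortPopulation(np.clip(f, 0.0, 1.0), w), equation)
        rows.append(
            {
                "day": rec.day,
                "fraction": value.glycated_fraction,
                "ngsp_percent": value.ngsp_percent,
                "ifcc_mmol_mol": value.ifcc_mmol_per_mol,
                "cell_mass": mass,
            }
        )
    return pd.DataFrame(rows)


def _as_ngsp(values: Iterable) -> np.ndarray:
    return np.array(
        [v.ngsp_percent if isinstance(v, HbA1cValue) else float(v) for v in values]
    )


def md_mad(measured: Sequence, predicted: Sequence) -> dict[str, float]:
    """Mean difference and mean absolute difference, NGSP %.

    md = mean(measured - predicted); mad = mean |measured - predicted|.
    Accepts HbA1cValue instances or NGSP percentages, paired by position.
    """
    m = _as_ngsp(measured)
    p = _as_ngsp(predicted)
    if m.size != p.size:
        raise ValueError(f"length mismatch: {m.size} measured vs {p.size} predicted")
    if m.size == 0:
        raise ValueError("empty sequences")
    diff = m - p
    return {"md": float(diff.mean()), "mad": float(np.abs(diff).mean())}
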
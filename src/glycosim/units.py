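"""Scale and unit conversions for HbA1c and glucose measurements.

HbA1c is reported on two aligned scales: the NGSP scale (percent of total
hemoglobin) and the IFCC scale (mmol glycated hemoglobin per mol total
hemoglobin).  The IFCC value is, by construction, 1000 times the glycated
fraction of hemoglobin; the NGSP value is tied to the IFCC value by the
linear "master equation"

    NGSP(%) = 0.09148 * IFCC(mmol/mol) + 2.152

whose coefficients are configurable (older reports round them to
91.5 / 2.15 when written against the glycated fraction directly).

Glucose readings also live on several scales: glucometer whole-blood
readings are first mapped to reference-analyzer whole-blood values by a
linear recalibration, then multiplied by 1.11 to convert whole-blood to
plasma concentration.  Culture-medium glucose is divided by 1.06 to give
the plasma-equivalent concentration (the medium has a higher water
content than plasma).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "MASTER_SLOPE",
    "MASTER_INTERCEPT",
    "NgspIfccEquation",
    "HbA1cValue",
    "GlucoseConversionConfig",
    "convert_hba1c",
    "rescale_meter_glucose",
    "medium_to_plasma_equivalent",
    "mgdl_to_mmol",
]

#: NGSP/IFCC master-equation coefficients: NGSP(%) = slope * IFCC + intercept.
MASTER_SLOPE = 0.09148
MASTER_INTERCEPT = 2.152

#: mg/dl -> mmol/l for glucose (1 / 18.016 g/mol, conventional factor).
MGDL_TO_MMOL = 0.0555

_SCALES = ("ngsp", "ifcc", "fraction")


@dataclass(frozen=True)
class NgspIfccEquation:
    """Linear NGSP-IFCC relation, NGSP(%) = slope * IFCC(mmol/mol) + intercept."""

    slope: float = MASTER_SLOPE
    intercept: float = MASTER_INTERCEPT

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"master-equation slope must be positive, got {self.slope}")

    def ngsp_from_fraction(self, fraction: float) -> float:
        return 1000.0 * self.slope * fraction + self.intercept

    def fraction_from_ngsp(self, ngsp: float) -> float:
        return (ngsp - self.intercept) / (1000.0 * self.slope)

    @property
    def ngsp_floor(self) -> float:
        """NGSP value of fully non-glycated hemoglobin (fraction 0)."""
        return self.intercept

    @property
    def ngsp_ceiling(self) -> float:
        """NGSP value of fully glycated hemoglobin (fraction 1)."""
        return 1000.0 * self.slope + self.intercept


DEFAULT_EQUATION = NgspIfccEquation()


def convert_hba1c(
    value: float,
    from_scale: str,
    to_scale: str,
    equation: NgspIfccEquation = DEFAULT_EQUATION,
) -> float:
    """Convert one HbA1c quantity between the ngsp, ifcc and fraction scales.

    The three scales are linearly related, so any composition of
    conversions is exact (round trips return the input to ~1e-9).

    Parameters
    ----------
    value
        The HbA1c quantity on ``from_scale``.
    from_scale, to_scale
        One of ``"ngsp"`` (percent), ``"ifcc"`` (mmol/mol) or
        ``"fraction"`` (dimensionless, in [0, 1]).
    equation
        The NGSP-IFCC master equation to use.
    """
    if from_scale not in _SCALES:
        raise ValueError(f"unknown HbA1c scale {from_scale!r}; expected one of {_SCALES}")
    if to_scale not in _SCALES:
        raise ValueError(f"unknown HbA1c scale {to_scale!r}; expected one of {_SCALES}")
    if not np.isfinite(value):
        raise ValueError(f"HbA1c value must be finite, got {value}")

    if from_scale == "fraction":
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"glycated fraction must lie in [0, 1], got {value}")
        fraction = float(value)
    elif from_scale == "ifcc":
        fraction = float(value) / 1000.0
    else:  # ngsp
        fraction = equation.fraction_from_ngsp(float(value))

    if to_scale == "fraction":
        return fraction
    if to_scale == "ifcc":
        return 1000.0 * fraction
    return equation.ngsp_from_fraction(fraction)


@dataclass(frozen=True)
class HbA1cValue:
    """One HbA1c quantity carried on all three aligned scales.

    ``ifcc_mmol_per_mol`` is 1000x the glycated fraction; ``ngsp_percent``
    follows from the master equation.  Build instances through
    :meth:`from_fraction`, :meth:`from_ngsp` or :meth:`from_ifcc` so the
    scales stay aligned.
    """

    glycated_fraction: float
    ngsp_percent: float
    ifcc_mmol_per_mol: float
    equation: NgspIfccEquation = field(default=DEFAULT_EQUATION, compare=False)

    @classmethod
    def from_fraction(cls, fraction: float, equation: NgspIfccEquation = DEFAULT_EQUATION) -> "HbA1cValue":
        f = convert_hba1c(fraction, "fraction", "fraction", equation)
        return cls(f, equation.ngsp_from_fraction(f), 1000.0 * f, equation)

    @classmethod
    def from_ngsp(cls, ngsp: float, equation: NgspIfccEquation = DEFAULT_EQUATION) -> "HbA1cValue":
        return cls.from_fraction(convert_hba1c(ngsp, "ngsp", "fraction", equation), equation)

    @classmethod
    def from_ifcc(cls, ifcc: float, equation: NgspIfccEquation = DEFAULT_EQUATION) -> "HbA1cValue":
        return cls.from_fraction(convert_hba1c(ifcc, "ifcc", "fraction", equation), equation)

    def round_for_display(self) -> tuple[float, int]:
        """(NGSP rounded to 1 decimal, IFCC rounded to integer) — reporting style."""
        return round(self.ngsp_percent, 1), int(round(self.ifcc_mmol_per_mol))

    def __str__(self) -> str:  # e.g. "7.0% (53 mmol/mol)"
        ngsp, ifcc = self.round_for_display()
        return f"{ngsp:.1f}% ({ifcc:d} mmol/mol)"


@dataclass(frozen=True)
class GlucoseConversionConfig:
    """Linear maps between glucose measurement scales.

    meter -> reference analyzer (whole blood): linear recalibration;
    whole blood -> plasma: multiply by ``whole_blood_to_plasma_factor``;
    culture medium -> plasma equivalent: divide by ``medium_water_factor``.
    """

    meter_to_reference_slope: float = 1.0
    meter_to_reference_intercept: float = 0.0
    whole_blood_to_plasma_factor: float = 1.11
    medium_water_factor: float = 1.06

    def __post_init__(self) -> None:
        if self.meter_to_reference_slope <= 0:
            raise ValueError("meter_to_reference_slope must be > 0")
        if self.whole_blood_to_plasma_factor <= 0 or self.medium_water_factor <= 0:
            raise ValueError("conversion factors must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "GlucoseConversionConfig":
        """Load from YAML or JSON with keys meter_slope, meter_intercept,
        plasma_factor, medium_factor (all optional)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = data or {}
        return cls(
            meter_to_reference_slope=float(data.get("meter_slope", 1.0)),
            meter_to_reference_intercept=float(data.get("meter_intercept", 0.0)),
            whole_blood_to_plasma_factor=float(data.get("plasma_factor", 1.11)),
            medium_water_factor=float(data.get("medium_factor", 1.06)),
        )


DEFAULT_GLUCOSE_CONFIG = GlucoseConversionConfig()


def rescale_meter_glucose(
    series: Iterable[float],
    config: GlucoseConversionConfig = DEFAULT_GLUCOSE_CONFIG,
) -> np.ndarray:
    """Map glucometer whole-blood readings (mmol/l) to plasma glucose.

    Applies the meter-to-reference linear recalibration and then the
    whole-blood-to-plasma factor (default 1.11).  With the default
    identity recalibration a warning is emitted once per call: real meter
    data needs device-specific coefficients.
    """
    values = np.asarray(list(series), dtype=float)
    if values.size and np.any(values <= 0):
        raise ValueError("glucose readings must be strictly positive")
    if (
        config.meter_to_reference_slope == 1.0
        and config.meter_to_reference_intercept == 0.0
    ):
        warnings.warn(
            "meter-to-reference recalibration left at identity; supply "
            "device-specific slope/intercept for real glucometer data",
            stacklevel=2,
        )
    reference = config.meter_to_reference_slope * values + config.meter_to_reference_intercept
    return reference * config.whole_blood_to_plasma_factor


def medium_to_plasma_equivalent(
    medium_glucose: float | np.ndarray,
    config: GlucoseConversionConfig = DEFAULT_GLUCOSE_CONFIG,
) -> float | np.ndarray:
    """Culture-medium glucose (mmol/l) -> plasma-equivalent concentration.

    Divides by the medium water-content factor (default 1.06).
    """
    arr = np.asarray(medium_glucose, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("medium glucose must be strictly positive")
    out = arr / config.medium_water_factor
    return float(out) if np.isscalar(medium_glucose) else out


def mgdl_to_mmol(value_mgdl: float | np.ndarray) -> float | np.ndarray:
    """Optional input helper: glucose mg/dl -> mmol/l (x 0.0555)."""
    arr = np.asarray(value_mgdl, dtype=float) * MGDL_TO_MMOL
    return float(arr) if np.isscalar(value_mgdl) else arr
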
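"""Piecewise power-law GFR estimating equations.

Estimated glomerular filtration rate (eGFR, ml/min/1.73 m²) is computed from
serum creatinine (SC, mg/dl), age (years) and sex by a four-branch power law:

    eGFR = k * (SC / tau)^c * a^age

where the branch — and hence the coefficients ``(k, c, a)`` — is selected by
sex and by whether SC lies at/below or above a sex-specific threshold ``tau``
(1.2 mg/dl for women, 1.0 mg/dl for men).  The equation is continuous in SC
within each branch but not across the male threshold, where the published
coefficients produce an upward jump (98 at SC = 1.0 versus ~105 just above);
this behaviour is reproduced deliberately.

The module also provides the affine calibration applied to renal dynamic
imaging GFR to place it on the dual-plasma-sample scale, and creatinine unit
conversion (µmol/l → mg/dl).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Side",
    "DomainError",
    "AgeRangeWarning",
    "PatientRecord",
    "EquationBranch",
    "CalibrationCoefficients",
    "BRANCHES",
    "select_branch",
    "estimate_gfr_regression",
    "estimate_gfr_frame",
    "calibrate_imaging_gfr",
    "convert_creatinine",
    "records_to_frame",
    "frame_to_records",
    "UMOL_PER_MGDL",
    "ADULT_AGE_RANGE",
]

#: µmol/l per mg/dl of creatinine.
UMOL_PER_MGDL = 88.4

#: Ages outside this range trigger a warning (the equations remain defined).
ADULT_AGE_RANGE = (18.0, 100.0)


class DomainError(ValueError):
    """An input violates the mathematical domain of an operation."""


class AgeRangeWarning(UserWarning):
    """Age outside the typical adult range; silence with
    ``warnings.filterwarnings("ignore", category=AgeRangeWarning)``."""


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Side(str, Enum):
    AT_OR_BELOW = "at_or_below"
    ABOVE = "above"


@dataclass(frozen=True)
class PatientRecord:
    """One subject: identifier, age (years), sex, serum creatinine (mg/dl),
    and optionally a measured GFR (ml/min/1.73 m²)."""

    id: str
    age: float
    sex: Sex
    scr: float
    mgfr: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if not (self.scr > 0 and math.isfinite(self.scr)):
            raise DomainError(f"serum creatinine must be positive, got {self.scr!r}")
        if not (self.age >= 0 and math.isfinite(self.age)):
            raise DomainError(f"age must be non-negative, got {self.age!r}")
        if self.mgfr is not None and not (self.mgfr > 0 and math.isfinite(self.mgfr)):
            raise DomainError(f"measured GFR must be positive, got {self.mgfr!r}")
        lo, hi = ADULT_AGE_RANGE
        if not lo <= self.age <= hi:
            warnings.warn(
                f"age {self.age} outside typical adult range [{lo}, {hi}]; "
                "the estimating equations are extrapolating",
                AgeRangeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class EquationBranch:
    """One branch of the piecewise equation: coefficients (k, c, a) valid for
    one sex on one side of the creatinine threshold tau."""

    sex: Sex
    threshold: float  # tau, mg/dl
    side: Side
    scale: float  # k, ml/min/1.73 m²
    creatinine_exponent: float  # c, dimensionless, < 0
    age_base: float  # a, per-year multiplicative factor, in (0, 1)

    def evaluate(self, scr: float, age: float) -> float:
        return (
            self.scale
            * (scr / self.threshold) ** self.creatinine_exponent
            * self.age_base ** age
        )


BRANCHES: tuple[EquationBranch, ...] = (
    EquationBranch(Sex.FEMALE, 1.2, Side.AT_OR_BELOW, 92.0, -0.534, 0.994),
    EquationBranch(Sex.FEMALE, 1.2, Side.ABOVE, 79.0, -0.516, 0.994),
    EquationBranch(Sex.MALE, 1.0, Side.AT_OR_BELOW, 98.0, -0.450, 0.996),
    EquationBranch(Sex.MALE, 1.0, Side.ABOVE, 105.0, -0.640, 0.993),
)


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Affine calibration from renal-dynamic-imaging GFR to the
    dual-plasma-sample scale: calibrated = intercept + slope * imaging."""

    intercept: float = 0.167  # ml/min/1.73 m²
    slope: float = 1.057  # dimensionless

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise DomainError("calibration slope must be positive")


def select_branch(sex: Sex | str, scr: float) -> EquationBranch:
    """Return the equation branch for ``sex`` whose creatinine interval
    contains ``scr``; threshold values resolve to the at-or-below branch."""
    if not scr > 0:
        raise DomainError(f"serum creatinine must be positive, got {scr!r}")
    sex = Sex(sex)
    for branch in BRANCHES:
        if branch.sex is not sex:
            continue
        if branch.side is Side.AT_OR_BELOW and scr <= branch.threshold:
            return branch
        if branch.side is Side.ABOVE and scr > branch.threshold:
            return branch
    raise AssertionError("branch table does not partition the domain")  # pragma: no cover


def estimate_gfr_regression(patient: PatientRecord) -> float:
    """Estimated GFR (ml/min/1.73 m²) for one patient from the piecewise
    power-law equation."""
    branch = select_branch(patient.sex, patient.scr)
    return branch.evaluate(patient.scr, patient.age)


def estimate_gfr_frame(cohort: pd.DataFrame) -> np.ndarray:
    """Vectorised piecewise equation over a cohort frame with columns
    ``age``, ``sex`` and ``scr`` (mg/dl).  Returns one eGFR per row."""
    scr = np.asarray(cohort["scr"], dtype=float)
    age = np.asarray(cohort["age"], dtype=float)
    if np.any(~np.isfinite(scr)) or np.any(scr <= 0):
        raise DomainError("serum creatinine must be positive and finite")
    if np.any(~np.isfinite(age)) or np.any(age < 0):
        raise DomainError("age must be non-negative and finite")
    male = _male_indicator(cohort["sex"])
    out = np.empty(len(scr), dtype=float)
    for branch in BRANCHES:
        is_male = branch.sex is Sex.MALE
        if branch.side is Side.AT_OR_BELOW:
            mask = (male == is_male) & (scr <= branch.threshold)
        else:
            mask = (male == is_male) & (scr > branch.threshold)
        out[mask] = (
            branch.scale
            * (scr[mask] / branch.threshold) ** branch.creatinine_exponent
            * branch.age_base ** age[mask]
        )
    return out


def _male_indicator(sex: Iterable) -> np.ndarray:
    vals = pd.Series(sex).astype(str).str.lower().str.strip()
    mapping = {"m": True, "male": True, "f": False, "female": False}
    unknown = sorted(set(vals) - set(mapping))
    if unknown:
        raise DomainError(f"unrecognised sex labels: {unknown}")
    return vals.map(mapping).to_numpy(dtype=bool)


def calibrate_imaging_gfr(
    imaging_gfr: float, coeffs: CalibrationCoefficients = CalibrationCoefficients()
) -> float:
    """Calibrate a renal-dynamic-imaging GFR to the dual-plasma-sample scale
    (intercept + slope * imaging_gfr)."""
    if not imaging_gfr >= 0:
        raise DomainError(f"imaging GFR must be non-negative, got {imaging_gfr!r}")
    return coeffs.intercept + coeffs.slope * imaging_gfr


def convert_creatinine(value: float, unit: str) -> float:
    """Convert a creatinine value to mg/dl.  ``unit`` is ``mg_per_dl``
    (identity) or ``umol_per_l`` (divide by 88.4)."""
    if not value > 0:
        raise DomainError(f"creatinine must be positive, got {value!r}")
    if unit == "mg_per_dl":
        return float(value)
    if unit == "umol_per_l":
        return float(value) / UMOL_PER_MGDL
    raise ValueError(f"unknown creatinine unit {unit!r}")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Canonical cohort frame (columns id, age, sex, scr, mgfr)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex.value for r in records],
            "scr": [r.scr for r in records],
            "mgfr": [r.mgfr if r.mgfr is not None else np.nan for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in frame.iterrows():
        mgfr = row.get("mgfr", np.nan)
        records.append(
            PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=Sex.MALE if _male_indicator([row["sex"]])[0] else Sex.FEMALE,
                scr=float(row["scr"]),
                mgfr=None if pd.isna(mgfr) else float(mgfr),
            )
        )
    return records
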
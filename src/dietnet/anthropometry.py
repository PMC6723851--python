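"""BMI computation and percentile-based anthropometric classification.

BMI is weight/height**2 after subtracting a uniform-clothing correction
(default 0.1 kg).  Classification compares BMI with sex- and age-specific
percentile cut-offs (3rd, 85th, 97th) supplied as a reference table:
below p3 -> underweight, [p3, p85) -> eutrophy (normal weight),
[p85, p97) -> overweight, >= p97 -> obesity.  The reference cut-offs are
user-supplied data (e.g. BMI-for-age growth-reference tables); the package
ships only a clearly synthetic table for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ANTHRO_CLASSES",
    "DEFAULT_UNIFORM_CORRECTION_KG",
    "BMIReferenceTable",
    "compute_bmi",
    "lookup_cutoffs",
    "classify_anthropometric",
    "classify_roster",
    "make_synthetic_reference_table",
]

#: Class labels in increasing-BMI order.
ANTHRO_CLASSES: tuple[str, ...] = ("underweight", "eutrophy", "overweight", "obesity")

DEFAULT_UNIFORM_CORRECTION_KG = 0.1

SEXES = ("male", "female")


@dataclass(frozen=True)
class BMIReferenceTable:
    """Percentile cut-offs (kg/m^2) keyed by sex and age in months."""

    table: pd.DataFrame  # columns: sex, age_months, bmi_p3, bmi_p85, bmi_p97

    def __post_init__(self) -> None:
        required = {"sex", "age_months", "bmi_p3", "bmi_p85", "bmi_p97"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        t = self.table
        if not ((t["bmi_p3"] < t["bmi_p85"]) & (t["bmi_p85"] < t["bmi_p97"])).all():
            raise ValueError("cut-offs must satisfy p3 < p85 < p97 in every row")
        for sex, sub in t.groupby("sex"):
            ages = sub["age_months"].to_numpy()
            if not np.all(np.diff(np.sort(ages)) > 0):
                raise ValueError(f"age grid for sex={sex!r} must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "BMIReferenceTable":
        return cls(pd.read_csv(path))

    def age_range(self, sex: str) -> tuple[float, float]:
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise ValueError(f"no reference rows for sex={sex!r}")
        return float(sub["age_months"].min()), float(sub["age_months"].max())


def compute_bmi(
    weight_kg: float,
    height_m: float,
    uniform_correction_kg: float = DEFAULT_UNIFORM_CORRECTION_KG,
) -> float:
    """BMI in kg/m^2 with the clothing weight subtracted before division."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    corrected = weight_kg - uniform_correction_kg
    if corrected <= 0:
        raise ValueError(
            f"weight {weight_kg} kg does not exceed the uniform correction "
            f"{uniform_correction_kg} kg"
        )
    return corrected / (height_m**2)


def lookup_cutoffs(
    ref: BMIReferenceTable, sex: str, age_years: float
) -> tuple[float, float, float]:
    """(p3, p85, p97) cut-offs at an age, linearly interpolated in months.

    An age exactly on a grid row returns that row; ages outside the grid for
    the given sex raise a range error naming the bound.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    age_months = age_years * 12.0
    sub = ref.table[ref.table["sex"] == sex].sort_values("age_months")
    if sub.empty:
        raise ValueError(f"no reference rows for sex={sex!r}")
    lo, hi = float(sub["age_months"].min()), float(sub["age_months"].max())
    if age_months < lo or age_months > hi:
        raise ValueError(
            f"age {age_months:.1f} months outside reference range "
            f"[{lo:.1f}, {hi:.1f}] for sex={sex!r}"
        )
    grid = sub["age_months"].to_numpy(dtype=float)
    return tuple(
        float(np.interp(age_months, grid, sub[col].to_numpy(dtype=float)))
        for col in ("bmi_p3", "bmi_p85", "bmi_p97")
    )


def classify_anthropometric(bmi: float, cutoffs: tuple[float, float, float]) -> str:
    """Map a BMI to a class given ordered (p3, p85, p97) cut-offs.

    Boundary convention: lower bounds are closed for the upper class, i.e.
    bmi == p85 is overweight and bmi == p97 is obesity.
    """
    p3, p85, p97 = cutoffs
    if not (p3 < p85 < p97):
        raise ValueError("cut-offs must be strictly increasing (p3 < p85 < p97)")
    if bmi < p3:
        return "underweight"
    if bmi < p85:
        return "eutrophy"
    if bmi < p97:
        return "overweight"
    return "obesity"


def classify_roster(
    roster: pd.DataFrame,
    ref: BMIReferenceTable,
    uniform_correction_kg: float = DEFAULT_UNIFORM_CORRECTION_KG,
) -> pd.DataFrame:
    """Append derived ``bmi`` and ``anthro_class`` columns to a roster.

    The roster needs ``sex``, ``age`` (decimal years), ``weight`` (kg) and
    ``height`` (m) columns; existing derived columns are recomputed.
    """
    out = roster.copy()
    bmis, classes = [], []
    for r in out.itertuples(index=False):
        bmi = compute_bmi(float(r.weight), float(r.height), uniform_correction_kg)
        cut = lookup_cutoffs(ref, str(r.sex), float(r.age))
        bmis.append(bmi)
        classes.append(classify_anthropometric(bmi, cut))
    out["bmi"] = bmis
    out["anthro_class"] = classes
    return out


def make_synthetic_reference_table(
    age_min_months: int = 120, age_max_months: int = 228, step: int = 6
) -> BMIReferenceTable:
    """SYNTHETIC percentile table for tests and simulations.

    Monotone, plausible adolescent BMI-for-age cut-offs; this is NOT real
    growth-reference data and must never be used for clinical classification.
    """
    rows = []
    for sex, offset in (("male", 0.0), ("female", 0.3)):
        for m in range(age_min_months, age_max_months + 1, step):
            p3 = 14.0 + 0.015 * (m - age_min_months) + offset
            rows.append(
                {
                    "sex": sex,
                    "age_months": m,
                    "bmi_p3": round(p3, 3),
                    "bmi_p85": round(p3 + 6.5, 3),
                    "bmi_p97": round(p3 + 9.5, 3),
                }
            )
    return BMIReferenceTable(pd.DataFrame(rows))
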
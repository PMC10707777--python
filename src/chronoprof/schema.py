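"""Meal-slot schema, contact records and cohort table I/O.

The unit of observation is a 24-h dietary recall reduced to 11 binary "food
contact" flags (3 main meals, 4 snack slots, 4 nibbling slots), each tied to a
fixed clock window.  A patient's day is expanded into an hourly step function
y(t), t = 1..24, with y(t) = 1 when hour t falls inside the window of at least
one flagged slot.

Cohort tables are plain pandas DataFrames with a documented column dictionary;
missing cells are written as empty CSV fields with an explicit boolean mask
column (``miss_<name>``) alongside, so no sentinel numbers ever appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_HOURS = 24

#: Canonical slot windows, hours inclusive on both ends (clock hours 1..24).
DEFAULT_SLOT_WINDOWS: dict[str, tuple[int, int]] = {
    "breakfast": (7, 8),
    "morning_nibbling": (9, 12),
    "morning_snack": (10, 11),
    "lunch": (12, 13),
    "afternoon_nibbling": (14, 18),
    "afternoon_snack": (16, 17),
    "dinner": (19, 20),
    "evening_nibbling": (21, 24),
    "evening_snack": (21, 22),
    "night_nibbling": (1, 6),
    "night_snack": (3, 4),
}

SLOT_NAMES: tuple[str, ...] = tuple(DEFAULT_SLOT_WINDOWS)

#: "post-dinner"/"late-night" naming used in some clinical write-ups maps onto
#: the canonical evening/night slots.
SLOT_ALIASES: dict[str, str] = {
    "post_dinner_snack": "evening_snack",
    "post_dinner_nibbling": "evening_nibbling",
    "late_night_snack": "night_snack",
    "late_night_nibbling": "night_nibbling",
}

#: Columns whose cells may legitimately be missing and therefore carry a
#: companion ``miss_<name>`` mask column in CSV output.
MASKABLE_COLUMNS: tuple[str, ...] = (
    "dyslipidemia", "shift_work", "BIS11", "TC", "HDL", "LDL", "TG", "HOMA",
)

COVARIATE_COLUMNS = (
    "gender", "age", "education", "physical_activity", "alcohol", "smoking",
    "shift_work", "weight", "height", "BMI", "BMI_tertile",
)
OUTCOME_COLUMNS = (
    "hypertension", "diabetes", "dyslipidemia", "statins",
    "TC", "HDL", "LDL", "TG", "insulin", "FPG", "insulin_treated", "HOMA",
    "SCL90_GSI", "SF36_PH", "SF36_MH", "YFAS", "EAT26", "BIS11", "BES",
)


class SchemaError(ValueError):
    """A cohort file or slot schema violates its documented contract."""


@dataclass(frozen=True)
class MealSlotSchema:
    """The 11 meal slots with their clock windows.

    Windows are inclusive integer hour ranges within 1..24; the window of a
    snack may sit inside the window of the corresponding nibbling slot
    (e.g. morning snack 10-11 inside morning nibbling 9-12).
    """

    windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SLOT_WINDOWS))

    def __post_init__(self) -> None:
        if len(self.windows) != 11:
            raise SchemaError(f"expected exactly 11 slots, got {len(self.windows)}")
        for name, (a, b) in self.windows.items():
            if not (1 <= a <= 24 and 1 <= b <= 24 and b >= a):
                raise SchemaError(f"slot {name!r}: invalid window [{a}, {b}]")

    @property
    def slot_names(self) -> tuple[str, ...]:
        return tuple(self.windows)

    def hours(self, slot: str) -> np.ndarray:
        """Integer hours covered by a slot's window (inclusive both ends)."""
        a, b = self.windows[slot]
        return np.arange(a, b + 1)


@dataclass(frozen=True)
class ContactRecord:
    """One patient's 11 binary meal-contact flags."""

    patient_id: str
    flags: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(SLOT_NAMES) - set(self.flags)
        if missing:
            raise SchemaError(f"record {self.patient_id}: missing slots {sorted(missing)}")
        for name, v in self.flags.items():
            if v not in (0, 1):
                raise ValueError(
                    f"record {self.patient_id}: flag {name!r}={v!r} is not binary")


@dataclass(frozen=True)
class ContactSeries:
    """Hourly eating indicator y(t) on the grid t = 1..24."""

    patient_id: str
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.shape != (N_HOURS,) or not np.isin(y, (0, 1)).all():
            raise ValueError("y must be 24 binary values")
        object.__setattr__(self, "y", y.astype(float))


def expand_contacts_to_series(record: ContactRecord,
                              schema: MealSlotSchema | None = None) -> ContactSeries:
    """Union the windows of all flagged slots into the hourly step function.

    Overlapping windows (snack within nibbling) contribute once: y(t) is a
    binary presence indicator, not a count.
    """
    schema = schema or MealSlotSchema()
    y = np.zeros(N_HOURS)
    for slot in schema.slot_names:
        if record.flags[slot]:
            y[schema.hours(slot) - 1] = 1.0
    return ContactSeries(record.patient_id, y)


def records_from_frame(df: pd.DataFrame) -> list[ContactRecord]:
    """Build ContactRecords from the flag columns of a cohort table."""
    missing = [c for c in SLOT_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory flag column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        flags = {}
        for slot in SLOT_NAMES:
            v = getattr(row, slot)
            if pd.isna(v) or float(v) not in (0.0, 1.0):
                raise ValueError(f"row {i}: non-binary flag {slot}={v!r}")
            flags[slot] = int(v)
        pid = str(getattr(row, "patient_id", i))
        records.append(ContactRecord(pid, flags))
    return records


def load_contacts_csv(path: str | Path) -> tuple[list[ContactRecord], pd.DataFrame]:
    """Read a cohort CSV, returning contact records plus the full table.

    Unknown columns are preserved as passthrough.  Flag columns must be
    present and strictly binary.
    """
    df = read_cohort_csv(path)
    return records_from_frame(df), df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with empty cells for NA plus explicit mask columns."""
    out = df.copy()
    for col in MASKABLE_COLUMNS:
        if col in out.columns:
            out[f"miss_{col}"] = out[col].isna().astype(int)
    out.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Mask columns are consumed (cells they flag become NA) and dropped.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in list(df.columns):
        if col.startswith("miss_"):
            target = col[len("miss_"):]
            if target in df.columns:
                df.loc[df[col] == 1, target] = np.nan
            df = df.drop(columns=col)
    return df


def cohorts_equal(a: pd.DataFrame, b: pd.DataFrame, rtol: float = 1e-12) -> bool:
    """Field-by-field equality of two cohort tables, NA-aware."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        xa, xb = a[col], b[col]
        if not (xa.isna().values == xb.isna().values).all():
            return False
        ma = ~xa.isna()
        if pd.api.types.is_numeric_dtype(xa) and pd.api.types.is_numeric_dtype(xb):
            if not np.allclose(xa[ma].astype(float), xb[ma].astype(float), rtol=rtol):
                return False
        else:
            if not (xa[ma].astype(str).values == xb[ma].astype(str).values).all():
                return False
    return True
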
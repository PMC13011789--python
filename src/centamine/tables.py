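"""Long-format measurement tables (SBR and Centamine values).

Both table kinds share one schema::

    subject, tracer, session_years, age, sex, region, side, value

with ``sex`` coded 0 = female / 1 = male, ``session_years`` the time from the
subject's baseline scan, and ``side`` one of left/right/bilateral.  The key
(subject, tracer, session_years, region, side) must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "KEY_COLUMNS", "MeasurementTable", "SbrTable", "CmTable"]

COLUMNS = ["subject", "tracer", "session_years", "age", "sex", "region", "side", "value"]
KEY_COLUMNS = ["subject", "tracer", "session_years", "region", "side"]
_SIDES = {"left", "right", "bilateral"}


class TableError(ValueError):
    """Raised for malformed measurement tables."""


class MeasurementTable:
    """Thin validated wrapper around a long-format pandas DataFrame."""

    kind = "value"

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise TableError(f"missing columns: {missing}")
        df = df[COLUMNS].copy()
        if validate:
            self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            raise TableError("table is empty")
        for col in ("session_years", "age", "value"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(df.index[vals.isna()][0])
                raise TableError(f"non-numeric {col!r} at row {row}")
            df[col] = vals.astype(float)
        sex = pd.to_numeric(df["sex"], errors="coerce")
        if sex.isna().any() or not set(np.unique(sex)) <= {0.0, 1.0}:
            bad = df.index[sex.isna() | ~sex.isin([0, 1])][0]
            raise TableError(
                f"sex must be coded 0 (female) or 1 (male); offending row {bad}"
            )
        df["sex"] = sex.astype(int)
        bad_side = ~df["side"].isin(_SIDES)
        if bad_side.any():
            row = int(df.index[bad_side][0])
            raise TableError(f"unknown side {df.loc[row, 'side']!r} at row {row}")
        if (df["age"] <= 0).any():
            raise TableError("age must be positive")
        if (df["session_years"] < 0).any():
            raise TableError("session_years must be >= 0")
        if not np.isfinite(df["value"]).all():
            raise TableError("values must be finite")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            key = df.loc[df.index[dup][0], KEY_COLUMNS].tolist()
            raise TableError(f"duplicate record key {key}")

    def __len__(self) -> int:
        return len(self.df)

    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    def select(self, **criteria) -> pd.DataFrame:
        out = self.df
        for col, val in criteria.items():
            out = out[out[col] == val]
        return out

    def concat(self, other: "MeasurementTable") -> "MeasurementTable":
        return type(self)(pd.concat([self.df, other.df], ignore_index=True))


class SbrTable(MeasurementTable):
    """Specific binding ratios: value = SUV_target / SUV_reference - 1."""

    kind = "sbr"


class CmTable(MeasurementTable):
    """Centamine values (%): 100 = mean healthy specific binding, 0 = none."""

    kind = "cm"
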
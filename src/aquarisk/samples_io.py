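"""Survey table data model, CSV reader/writer, and validation.

A survey is a per-sample water-chemistry table: sample id, provenance class
(aquifer well / spring / lake-drain), pH, the eight major ions and the eight
heavy metals, all in mg/L. The canonical CSV schema is

    sample_id,source_class,pH,Na,K,Ca,Mg,Cl,SO4,HCO3,CO3,Cd,Cr,Cu,Fe,Mn,Ni,Pb,Zn

Headers are matched case-insensitively; extra columns are carried through
untouched. Missing values are empty cells and stay explicit (NaN) — they are
never silently treated as zero; downstream computations raise when a
required analyte is missing. Files ending in ``.gz`` are read and written
gzip-compressed transparently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .parameters import METALS

__all__ = [
    "IONS",
    "SOURCE_CLASSES",
    "SCHEMA_COLUMNS",
    "SchemaError",
    "ValidationError",
    "WaterSample",
    "SurveyTable",
    "read_survey",
    "write_survey",
]

#: major ions, canonical column order (cations then anions)
IONS: tuple[str, ...] = ("Na", "K", "Ca", "Mg", "Cl", "SO4", "HCO3", "CO3")

SOURCE_CLASSES: tuple[str, ...] = ("TCA_well", "spring", "lake_drain")

SCHEMA_COLUMNS: tuple[str, ...] = ("sample_id", "source_class", "pH") + IONS + METALS

_ANALYTES = IONS + METALS


class SchemaError(ValueError):
    """CSV header does not match the documented survey schema."""


class ValidationError(ValueError):
    """Survey content violates a validity rule (with row-addressed details)."""


@dataclass(frozen=True)
class WaterSample:
    """One survey row: pH plus ion and metal concentrations in mg/L.

    Missing analytes are NaN and must be handled explicitly by consumers.
    """

    sample_id: str
    source_class: str
    ph: float
    ions: dict[str, float]
    metals: dict[str, float]


@dataclass
class SurveyTable:
    """An ordered collection of water samples backed by a DataFrame.

    ``data`` always carries the canonical schema columns first (extra
    pass-through columns after); ``provenance`` records where the table came
    from (a file path or ``synthetic:seed=N``).
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = _validate(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def samples(self) -> Iterable[WaterSample]:
        for _, row in self.data.iterrows():
            yield WaterSample(
                sample_id=row["sample_id"],
                source_class=row["source_class"],
                ph=row["pH"],
                ions={i: row[i] for i in IONS},
                metals={m: row[m] for m in METALS},
            )


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError("survey must contain at least one sample")

    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate sample_id(s): {', '.join(dupes)}")

    problems: list[str] = []
    bad_class = ~df["source_class"].isin(SOURCE_CLASSES)
    for idx in df.index[bad_class]:
        problems.append(
            f"row {idx} ({df.at[idx, 'sample_id']}): source_class "
            f"{df.at[idx, 'source_class']!r} not one of {SOURCE_CLASSES}"
        )

    for col in ("pH",) + _ANALYTES:
        coerced = pd.to_numeric(df[col], errors="coerce")
        was_value = df[col].notna() & ~df[col].astype(str).str.strip().eq("")
        non_numeric = was_value & coerced.isna()
        for idx in df.index[non_numeric]:
            problems.append(f"row {idx} ({df.at[idx, 'sample_id']}): {col} is not numeric: {df.at[idx, col]!r}")
        df[col] = coerced

    for col in _ANALYTES:
        negative = df[col] < 0
        for idx in df.index[negative]:
            problems.append(f"row {idx} ({df.at[idx, 'sample_id']}): {col} is negative ({df.at[idx, col]})")
    with np.errstate(invalid="ignore"):
        bad_ph = (df["pH"] < 0) | (df["pH"] > 14)
    for idx in df.index[bad_ph]:
        problems.append(f"row {idx} ({df.at[idx, 'sample_id']}): pH {df.at[idx, 'pH']} outside [0, 14]")
    inf_cols = df[list(("pH",) + _ANALYTES)].apply(lambda s: np.isinf(s))
    for col in inf_cols.columns[inf_cols.any()]:
        for idx in df.index[inf_cols[col]]:
            problems.append(f"row {idx} ({df.at[idx, 'sample_id']}): {col} is not finite")

    if problems:
        raise ValidationError("invalid survey rows:\n  " + "\n  ".join(problems))

    extra = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    return df[list(SCHEMA_COLUMNS) + extra].reset_index(drop=True)


def read_survey(path, provenance: str | None = None) -> SurveyTable:
    """Read and validate a survey CSV (optionally gzip-compressed).

    Header names are matched case-insensitively against the canonical
    schema. Rows with negative or non-numeric concentrations are rejected
    with row-addressed messages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    lower_to_canonical = {c.lower(): c for c in SCHEMA_COLUMNS}
    df = df.rename(columns=lambda c: lower_to_canonical.get(str(c).strip().lower(), c))
    return SurveyTable(data=df, provenance=provenance or str(path))


def write_survey(table: SurveyTable, path) -> None:
    """Write a survey as CSV in the documented column order, full precision.

    Floats are rendered with Python's shortest round-trip repr, so
    ``read_survey(write_survey(t))`` reproduces the values exactly.
    """
    table.data.to_csv(path, index=False)
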
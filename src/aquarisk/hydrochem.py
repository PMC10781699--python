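"""Hydrochemical derived quantities and classifications.

Covers the simple water-origin diagnostics used alongside the pollution
indices: milliequivalent conversion, TDS by ion summation, the ionic
balance error (IBE), Schoeller's first chloro-alkaline index (CAI-I),
salinity classing on TDS, and the Sulin genetic water typing.

All ratio indices work on a milliequivalent (meq/L) basis, obtained by
dividing each mg/L concentration by the ion's equivalent weight
(molar mass / charge):

    Na 22.99   K 39.10   Ca 20.04   Mg 12.155
    Cl 35.45   SO4 48.03   HCO3 61.02   CO3 30.005

Sign conventions: CAI-I = [Cl - (Na + K)] / Cl (meq); positive values
indicate reverse ion exchange (aquifer rock taking up Na+/K+ and releasing
Ca2+/Mg2+). IBE = 100 * (sum cations - sum anions)/(sum cations + sum
anions); |IBE| <= 5% is the conventional analytical acceptance rule.

The Sulin typing uses the genetic coefficients on a meq basis: waters with
Na/Cl > 1 are meteoric (Na2SO4 when (Na-Cl)/SO4 < 1, else NaHCO3), waters
with Na/Cl <= 1 are marine (MgCl2 when (Cl-Na)/Mg < 1, else CaCl2). The
threshold rules are a reconstruction of the classical graph; boundaries
(ratio exactly 1) are assigned deterministically as documented: Na/Cl = 1
falls on the marine branch, the inner coefficients at exactly 1 go to the
CaCl2 / NaHCO3 side. The rules are scale-invariant, so raw meq and meq%
give the same type.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .samples_io import IONS, SurveyTable

__all__ = [
    "EQUIVALENT_WEIGHTS",
    "CATIONS",
    "ANIONS",
    "SALINITY_CLASSES",
    "SULIN_TYPES",
    "MissingAnalyteError",
    "UndefinedIndexError",
    "to_meq",
    "tds_by_summation",
    "ionic_balance_error",
    "cai_one",
    "classify_salinity",
    "sulin_type",
    "hydrochem_summary",
]

#: equivalent weight g/eq = molar mass / |charge|
EQUIVALENT_WEIGHTS: dict[str, float] = {
    "Na": 22.99,
    "K": 39.10,
    "Ca": 20.04,
    "Mg": 12.155,
    "Cl": 35.45,
    "SO4": 48.03,
    "HCO3": 61.02,
    "CO3": 30.005,
}

CATIONS: tuple[str, ...] = ("Na", "K", "Ca", "Mg")
ANIONS: tuple[str, ...] = ("Cl", "SO4", "HCO3", "CO3")

SALINITY_CLASSES: tuple[str, ...] = ("fresh", "brackish", "saline", "hypersaline")
SULIN_TYPES: tuple[str, ...] = ("MgCl2", "CaCl2", "Na2SO4", "NaHCO3")


class MissingAnalyteError(ValueError):
    """A required ion or metal is absent or NaN."""


class UndefinedIndexError(ValueError):
    """The requested index is undefined for this composition (zero denominator)."""


def _ion_values(ions: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for ion in IONS:
        try:
            v = float(ions[ion])
        except (KeyError, TypeError):
            raise MissingAnalyteError(f"missing ion {ion!r}") from None
        if v != v:  # NaN
            raise MissingAnalyteError(f"missing ion {ion!r} (NaN)")
        if v < 0:
            raise ValueError(f"negative concentration for {ion!r}: {v}")
        out[ion] = v
    return out


def to_meq(ions: Mapping[str, float]) -> dict[str, float]:
    """Convert ion concentrations from mg/L to meq/L."""
    vals = _ion_values(ions)
    return {ion: vals[ion] / EQUIVALENT_WEIGHTS[ion] for ion in IONS}


def tds_by_summation(ions: Mapping[str, float]) -> float:
    """Total dissolved solids as the sum of the eight major ions, mg/L."""
    vals = _ion_values(ions)
    return float(sum(vals.values()))


def ionic_balance_error(ions: Mapping[str, float]) -> float:
    """Percent ionic balance error on a meq basis.

    IBE = 100 * (sum cations - sum anions) / (sum cations + sum anions).
    """
    meq = to_meq(ions)
    cations = sum(meq[i] for i in CATIONS)
    anions = sum(meq[i] for i in ANIONS)
    total = cations + anions
    if total == 0:
        raise UndefinedIndexError("ionic balance undefined: all ions are zero")
    return 100.0 * (cations - anions) / total


def cai_one(ions: Mapping[str, float]) -> float:
    """Schoeller's chloro-alkaline index CAI-I = [Cl - (Na + K)] / Cl, meq basis."""
    meq = to_meq(ions)
    if meq["Cl"] == 0:
        raise UndefinedIndexError("CAI-I undefined: Cl is zero")
    return (meq["Cl"] - (meq["Na"] + meq["K"])) / meq["Cl"]


def classify_salinity(tds: float) -> str:
    """Salinity class from TDS (mg/L): fresh < 1e3 <= brackish < 1e4 <= saline < 1e5 <= hypersaline."""
    if tds < 0:
        raise ValueError(f"TDS must be >= 0, got {tds}")
    if tds < 1_000:
        return "fresh"
    if tds < 10_000:
        return "brackish"
    if tds < 100_000:
        return "saline"
    return "hypersaline"


def sulin_type(ions: Mapping[str, float]) -> str:
    """Sulin genetic water type from the Na/Cl family of meq ratios.

    Returns one of ``MgCl2`` (recent marine), ``CaCl2`` (old marine),
    ``Na2SO4`` or ``NaHCO3`` (meteoric).
    """
    meq = to_meq(ions)
    if meq["Cl"] == 0:
        raise UndefinedIndexError("Sulin type undefined: Cl is zero")
    if meq["Na"] / meq["Cl"] > 1:
        if meq["SO4"] == 0:
            raise UndefinedIndexError("Sulin type undefined: SO4 is zero on the meteoric branch")
        return "Na2SO4" if (meq["Na"] - meq["Cl"]) / meq["SO4"] < 1 else "NaHCO3"
    if meq["Mg"] == 0:
        raise UndefinedIndexError("Sulin type undefined: Mg is zero on the marine branch")
    return "MgCl2" if (meq["Cl"] - meq["Na"]) / meq["Mg"] < 1 else "CaCl2"


def hydrochem_summary(table: SurveyTable) -> pd.DataFrame:
    """Per-sample hydrochemical summary columns for a survey.

    Returns a DataFrame with ``sample_id, TDS_sum, IBE_pct, CAI_I,
    salinity_class, sulin_type`` in survey order.
    """
    rows = []
    for sample in table.samples():
        tds = tds_by_summation(sample.ions)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "TDS_sum": tds,
                "IBE_pct": ionic_balance_error(sample.ions),
                "CAI_I": cai_one(sample.ions),
                "salinity_class": classify_salinity(tds),
                "sulin_type": sulin_type(sample.ions),
            }
        )
    return pd.DataFrame(rows)
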
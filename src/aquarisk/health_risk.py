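"""Deterministic USEPA-style health risk: CDI, HQ, HI and CR.

Exposure to metals in drinking water is assessed through two routes for two
receptors (adult, child). Chronic daily intakes (mg/kg/day):

    CDI_oral   = C * IR * EF * ED / (BW * AT)
    CDI_dermal = C * ET * EF * Kp * SA * CF * ED / (BW * AT)

Non-carcinogenic risk is the hazard quotient HQ = CDI / RfD with the
route-matched reference dose (RfD_dermal = RfD_oral * ABS), and the hazard
index HI = sum of the eight per-metal HQs for one route. Carcinogenic risk
CR = CDI * CSF is defined for Cd, Cr and Pb only; for the other metals it
is not applicable (never silently zero).

Decision rules are strict inequalities: HI > 1 flags non-carcinogenic high
risk, CR > 1e-4 flags unacceptable cancer risk.

The same averaging time AT = ED * 365 is used for both endpoints, so the
ED/AT ratio cancels to 1/365 and, e.g., the child/adult oral HQ ratio is
the constant (IR_child/IR_adult) * (BW_adult/BW_child) for every metal.

Scalar primitives (:func:`cdi_oral` ... :func:`cr`) define the arithmetic;
:func:`risk_table` is the vectorized survey-level engine producing per-metal
and per-route tables plus a report-style summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hydrochem import MissingAnalyteError
from .parameters import (
    CARCINOGENS,
    METALS,
    RECEPTORS,
    ExposureProfile,
    ParameterError,
    ParameterSet,
    load_default_parameters,
)
from .samples_io import SurveyTable

__all__ = [
    "ROUTES",
    "HI_THRESHOLD",
    "CR_THRESHOLD",
    "NotApplicableError",
    "cdi_oral",
    "cdi_dermal",
    "hq",
    "hi",
    "cr",
    "classify_hi",
    "classify_cr",
    "RiskTables",
    "risk_table",
]

ROUTES: tuple[str, ...] = ("oral", "dermal")

HI_THRESHOLD = 1.0
CR_THRESHOLD = 1e-4


class NotApplicableError(ValueError):
    """Carcinogenic risk requested for a metal without a slope factor."""


def cdi_oral(c: float, profile: ExposureProfile) -> float:
    """Chronic daily intake by ingestion, mg/kg/day, for concentration c (mg/L)."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c * profile.ir * profile.ef * profile.ed / (profile.bw * profile.at)


def cdi_dermal(c: float, profile: ExposureProfile, kp: float) -> float:
    """Chronic daily intake by skin absorption, mg/kg/day.

    kp is the metal's dermal permeability coefficient (cm/h).
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if not kp > 0:
        raise ParameterError(f"kp must be > 0, got {kp}")
    return (
        c
        * profile.et
        * profile.ef
        * kp
        * profile.sa
        * profile.cf
        * profile.ed
        / (profile.bw * profile.at)
    )


def hq(cdi: float, rfd: float) -> float:
    """Hazard quotient = CDI / RfD (route-matched reference dose)."""
    if not rfd > 0:
        raise ParameterError(f"rfd must be > 0, got {rfd}")
    return cdi / rfd


def hi(hqs: Mapping[str, float]) -> float:
    """Hazard index: sum of the eight per-metal hazard quotients of one route."""
    if set(hqs) != set(METALS):
        raise ValueError(
            f"hi expects exactly the eight metals {METALS}, got {sorted(hqs)}"
        )
    return float(sum(hqs[m] for m in METALS))


def cr(cdi: float, csf: float | None) -> float:
    """Carcinogenic risk = CDI * CSF; raises if the metal has no slope factor."""
    if csf is None:
        raise NotApplicableError("no cancer slope factor for this metal/route")
    if csf < 0:
        raise ParameterError(f"csf must be >= 0, got {csf}")
    return cdi * csf


def classify_hi(value: float) -> str:
    """``high_risk`` iff HI > 1 (strict), else ``low_risk``."""
    if value < 0:
        raise ValueError(f"HI must be >= 0, got {value}")
    return "high_risk" if value > HI_THRESHOLD else "low_risk"


def classify_cr(value: float) -> str:
    """``high_risk`` iff CR > 1e-4 (strict), else ``acceptable``."""
    if value < 0:
        raise ValueError(f"CR must be >= 0, got {value}")
    return "high_risk" if value > CR_THRESHOLD else "acceptable"


@dataclass
class RiskTables:
    """Survey-level risk output.

    per_metal : tidy per (sample, receptor, route, metal) CDI/HQ/CR table
    hazard    : per (sample, receptor, route) HI with class and total CR
    summary   : report-style min/max/mean + class counts per criterion
    """

    per_metal: pd.DataFrame
    hazard: pd.DataFrame
    summary: pd.DataFrame


def _unit_cdi(metal_kp: float, profile: ExposureProfile, route: str) -> float:
    """CDI at unit concentration (1 mg/L) for the given route."""
    if route == "oral":
        return cdi_oral(1.0, profile)
    if route == "dermal":
        return cdi_dermal(1.0, profile, metal_kp)
    raise ValueError(f"unknown route {route!r}")


def risk_table(
    table: SurveyTable,
    params: ParameterSet | None = None,
    receptors: Iterable[str] = RECEPTORS,
    routes: Iterable[str] = ROUTES,
) -> RiskTables:
    """Deterministic risk for every sample, receptor and route of a survey.

    Raises on missing metal concentrations before any output is produced
    (no partial tables). CDI/HQ/CR are homogeneous of degree one in
    concentration, so each (metal, receptor, route) reduces to a constant
    unit-risk factor times the concentration column.
    """
    params = params or load_default_parameters()
    receptors = tuple(receptors)
    routes = tuple(routes)
    for r in receptors:
        params.profile(r)  # validate early
    if not set(routes) <= set(ROUTES):
        raise ValueError(f"unknown route(s) {set(routes) - set(ROUTES)}")

    conc = table.data[list(METALS)]
    if conc.isna().any().any():
        bad = conc.columns[conc.isna().any()].tolist()
        raise MissingAnalyteError(
            f"missing concentration(s) for {bad}; cannot compute risk"
        )

    per_metal_rows = []
    hazard_rows = []
    ids = table.data["sample_id"].to_numpy()
    for receptor in receptors:
        profile = params.profile(receptor)
        for route in routes:
            hq_matrix = {}
            cr_matrix = {}
            for metal in METALS:
                tox = params.toxicity(metal)
                unit = _unit_cdi(tox.kp, profile, route)
                cdi_col = conc[metal].to_numpy(float) * unit
                hq_col = cdi_col / tox.rfd(route)
                hq_matrix[metal] = hq_col
                csf = tox.csf(route)
                cr_col = cdi_col * csf if csf is not None else None
                cr_matrix[metal] = cr_col
                df = pd.DataFrame(
                    {
                        "sample_id": ids,
                        "receptor": receptor,
                        "route": route,
                        "metal": metal,
                        "concentration": conc[metal].to_numpy(float),
                        "cdi": cdi_col,
                        "hq": hq_col,
                    }
                )
                df["cr"] = cr_col if cr_col is not None else np.nan
                df["cr_class"] = (
                    [classify_cr(v) for v in cr_col]
                    if cr_col is not None
                    else "not_applicable"
                )
                per_metal_rows.append(df)
            hi_col = np.sum([hq_matrix[m] for m in METALS], axis=0)
            total_cr = np.sum([cr_matrix[m] for m in CARCINOGENS], axis=0)
            hazard_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": ids,
                        "receptor": receptor,
                        "route": route,
                        "hi": hi_col,
                        "hi_class": [classify_hi(v) for v in hi_col],
                        "total_cr": total_cr,
                    }
                )
            )

    per_metal = pd.concat(per_metal_rows, ignore_index=True)
    hazard = pd.concat(hazard_rows, ignore_index=True)
    summary = _summarize(per_metal, hazard)
    return RiskTables(per_metal=per_metal, hazard=hazard, summary=summary)


def _summarize(per_metal: pd.DataFrame, hazard: pd.DataFrame) -> pd.DataFrame:
    """Report-style summary rows mirroring the HI / CR criteria layout."""
    rows = []
    n_total = hazard.groupby(["receptor", "route"]).size().iloc[0]
    for (receptor, route), grp in hazard.groupby(["receptor", "route"], sort=False):
        vals = grp["hi"]
        for cls, label in (("low_risk", "< 1"), ("high_risk", "> 1")):
            n = int((grp["hi_class"] == cls).sum())
            rows.append(
                {
                    "criterion": f"HI {receptor.capitalize()} ({route.capitalize()})",
                    "min": vals.min(),
                    "max": vals.max(),
                    "mean": vals.mean(),
                    "range": label,
                    "class": cls,
                    "n": n,
                    "pct": 100.0 * n / n_total,
                }
            )
    carcinogenic = per_metal[per_metal["metal"].isin(CARCINOGENS)]
    for (metal, receptor, route), grp in carcinogenic.groupby(
        ["metal", "receptor", "route"], sort=False
    ):
        vals = grp["cr"]
        for cls, label in (("acceptable", "< 1e-4"), ("high_risk", "> 1e-4")):
            n = int((grp["cr_class"] == cls).sum())
            rows.append(
                {
                    "criterion": f"CR {metal} {receptor.capitalize()} ({route.capitalize()})",
                    "min": vals.min(),
                    "max": vals.max(),
                    "mean": vals.mean(),
                    "range": label,
                    "class": cls,
                    "n": n,
                    "pct": 100.0 * n / len(grp),
                }
            )
    return pd.DataFrame(rows)
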
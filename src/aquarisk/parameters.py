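"""Reference toxicological and exposure constants.

This module freezes the parameter set used throughout the risk engine:
per-metal toxicological reference data (oral reference dose RfD, the
gastrointestinal absorption fraction ABS, dermal permeability Kp, cancer
slope factors CSF, and the drinking-water standard Si that doubles as the
upper allowable limit UAL) together with the receptor exposure profiles
(adult / child ingestion rate, exposure frequency and duration, body
weight, averaging time, skin area, exposure time and unit conversion).

All concentrations are mg/L, doses mg/kg/day, slope factors (mg/kg/day)^-1,
Kp cm/h. The dermal reference dose obeys the route-extrapolation identity

    RfD_dermal = RfD_oral * ABS

which every default row satisfies exactly; the constructor enforces it to
one part in 1e6 so user overrides stay internally consistent.

Cancer slope factors are defined for Cd, Cr and Pb only; the dermal slope
factor for these three metals is 1000x the oral one, the conventional
gastro-intestinal absorption adjustment (CSF_dermal = CSF_oral / 0.001).

Everything is user-overridable: a full parameter set round-trips through a
YAML mapping (with mandatory unit strings) via :func:`to_yaml` /
:func:`from_yaml`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "METALS",
    "CARCINOGENS",
    "RECEPTORS",
    "ParameterError",
    "MetalToxicity",
    "ExposureProfile",
    "ParameterSet",
    "derive_rfd_dermal",
    "load_default_parameters",
    "to_yaml",
    "from_yaml",
]

#: canonical metal order used everywhere (tables, Monte Carlo streams, CSV)
METALS: tuple[str, ...] = ("Cd", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn")

#: metals with a cancer slope factor; CR is undefined for the others
CARCINOGENS: tuple[str, ...] = ("Cd", "Cr", "Pb")

RECEPTORS: tuple[str, ...] = ("adult", "child")

_RFD_IDENTITY_RTOL = 1e-6

#: unit strings that a parameter config file must carry, keyed by field
UNITS: dict[str, str] = {
    "rfd_oral": "mg/kg/day",
    "abs_gi": "dimensionless",
    "rfd_dermal": "mg/kg/day",
    "csf_oral": "(mg/kg/day)^-1",
    "csf_dermal": "(mg/kg/day)^-1",
    "kp": "cm/h",
    "standard_si": "mg/L",
    "ir": "L/day",
    "ef": "day/year",
    "ed": "year",
    "bw": "kg",
    "at": "day",
    "sa": "cm^2",
    "et": "h/day",
    "cf": "L/cm^3",
}


class ParameterError(ValueError):
    """Invalid or inconsistent reference parameter."""


def derive_rfd_dermal(rfd_oral: float, abs_gi: float) -> float:
    """Dermal reference dose from the oral one: RfD_dermal = RfD_oral * ABS.

    Parameters
    ----------
    rfd_oral : float
        Oral reference dose, mg/kg/day, > 0.
    abs_gi : float
        Gastrointestinal absorption fraction, in (0, 1].
    """
    if not rfd_oral > 0:
        raise ParameterError(f"rfd_oral must be > 0, got {rfd_oral!r}")
    if not 0 < abs_gi <= 1:
        raise ParameterError(f"abs_gi must be in (0, 1], got {abs_gi!r}")
    return rfd_oral * abs_gi


@dataclass(frozen=True)
class MetalToxicity:
    """Per-metal toxicological reference values.

    ``csf_oral`` / ``csf_dermal`` are ``None`` for non-carcinogens; they must
    be present together. ``standard_si`` is the drinking-water limit used as
    Si in the pollution index and as the UAL in the metal index.
    """

    metal: str
    rfd_oral: float
    abs_gi: float
    rfd_dermal: float
    kp: float
    standard_si: float
    csf_oral: float | None = None
    csf_dermal: float | None = None

    def __post_init__(self) -> None:
        if self.metal not in METALS:
            raise ParameterError(f"unknown metal {self.metal!r}")
        for name in ("rfd_oral", "rfd_dermal", "kp", "standard_si"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{self.metal}: {name} must be > 0, got {v!r}")
        if not 0 < self.abs_gi <= 1:
            raise ParameterError(f"{self.metal}: abs_gi must be in (0,1], got {self.abs_gi!r}")
        expected = self.rfd_oral * self.abs_gi
        if abs(self.rfd_dermal - expected) > _RFD_IDENTITY_RTOL * expected:
            raise ParameterError(
                f"{self.metal}: rfd_dermal={self.rfd_dermal} violates "
                f"rfd_oral*abs_gi={expected}"
            )
        if (self.csf_oral is None) != (self.csf_dermal is None):
            raise ParameterError(f"{self.metal}: csf_oral and csf_dermal must be set together")
        if self.csf_oral is not None and (self.csf_oral < 0 or self.csf_dermal < 0):
            raise ParameterError(f"{self.metal}: slope factors must be >= 0")

    @property
    def is_carcinogen(self) -> bool:
        return self.csf_oral is not None

    def rfd(self, route: str) -> float:
        if route == "oral":
            return self.rfd_oral
        if route == "dermal":
            return self.rfd_dermal
        raise ParameterError(f"unknown route {route!r}")

    def csf(self, route: str) -> float | None:
        if route == "oral":
            return self.csf_oral
        if route == "dermal":
            return self.csf_dermal
        raise ParameterError(f"unknown route {route!r}")


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor exposure constants for the intake equations.

    ir: ingestion rate L/day; ef: exposure frequency day/year; ed: exposure
    duration year; bw: body weight kg; at: averaging time day; sa: exposed
    skin area cm^2; et: exposure time h/day; cf: volumetric conversion
    L/cm^3. The averaging time equals ed * 365 for both receptors.
    """

    receptor: str
    ir: float
    ef: float
    ed: float
    bw: float
    at: float
    sa: float
    et: float
    cf: float

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ParameterError(f"unknown receptor {self.receptor!r}")
        if not 0 < self.ef <= 365:
            raise ParameterError(f"ef must be in (0,365], got {self.ef!r}")
        for name in ("ir", "ed", "bw", "at", "sa", "et", "cf"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Complete frozen parameter bundle: 8 metals + 2 exposure profiles."""

    metals: dict[str, MetalToxicity]
    exposure: dict[str, ExposureProfile]

    def __post_init__(self) -> None:
        missing = set(METALS) - set(self.metals)
        if missing:
            raise ParameterError(f"missing toxicity data for {sorted(missing)}")
        if set(self.exposure) != set(RECEPTORS):
            raise ParameterError("exposure profiles must cover exactly adult and child")

    def toxicity(self, metal: str) -> MetalToxicity:
        try:
            return self.metals[metal]
        except KeyError:
            raise ParameterError(f"unknown metal {metal!r}") from None

    def profile(self, receptor: str) -> ExposureProfile:
        try:
            return self.exposure[receptor]
        except KeyError:
            raise ParameterError(f"unknown receptor {receptor!r}") from None

    @property
    def standards(self) -> dict[str, float]:
        """Metal -> drinking-water standard Si (== UAL), mg/L."""
        return {m: self.metals[m].standard_si for m in METALS}

    def with_standards(self, standards: dict[str, float]) -> "ParameterSet":
        """New set with some drinking-water standards overridden."""
        metals = dict(self.metals)
        for m, si in standards.items():
            metals[m] = replace(self.toxicity(m), standard_si=si)
        return ParameterSet(metals=metals, exposure=self.exposure)

    def content_hash(self) -> str:
        """Stable hash of all numeric values (for run logs)."""
        payload = _as_mapping(self)
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --- frozen defaults -------------------------------------------------------
# metal: (rfd_oral, abs_gi, rfd_dermal, kp, standard_si, csf_oral, csf_dermal)
_DEFAULT_TOXICITY: dict[str, tuple] = {
    "Cd": (0.0005, 0.05, 0.000025, 0.001, 0.003, 6.1, 6100.0),
    "Cr": (0.003, 0.025, 0.000075, 0.002, 0.05, 0.5, 500.0),
    "Cu": (0.04, 0.3, 0.012, 0.001, 3.0, None, None),
    "Fe": (0.7, 0.2, 0.14, 0.001, 0.3, None, None),
    "Mn": (0.024, 0.04, 0.00096, 0.001, 0.05, None, None),
    "Ni": (0.02, 0.04, 0.0008, 0.0002, 0.07, None, None),
    "Pb": (0.0014, 0.3, 0.00042, 0.0001, 0.01, 0.5, 500.0),
    "Zn": (0.3, 0.2, 0.06, 0.0006, 1.0, None, None),
}

_DEFAULT_EXPOSURE: dict[str, tuple] = {
    # receptor: (ir, ef, ed, bw, at, sa, et, cf)
    "adult": (2.2, 350.0, 70.0, 70.0, 25550.0, 18000.0, 0.58, 0.001),
    "child": (1.8, 350.0, 6.0, 15.0, 2190.0, 6600.0, 1.0, 0.001),
}


def load_default_parameters() -> ParameterSet:
    """The frozen default parameter set (8 metals, adult + child)."""
    metals = {
        m: MetalToxicity(m, ro, ab, rd, kp, si, csfo, csfd)
        for m, (ro, ab, rd, kp, si, csfo, csfd) in _DEFAULT_TOXICITY.items()
    }
    exposure = {
        r: ExposureProfile(r, *vals) for r, vals in _DEFAULT_EXPOSURE.items()
    }
    return ParameterSet(metals=metals, exposure=exposure)


# --- YAML round-trip -------------------------------------------------------

_METAL_FIELDS = ("rfd_oral", "abs_gi", "rfd_dermal", "kp", "standard_si", "csf_oral", "csf_dermal")
_EXPOSURE_FIELDS = ("ir", "ef", "ed", "bw", "at", "sa", "et", "cf")


def _as_mapping(params: ParameterSet) -> dict:
    return {
        "units": dict(UNITS),
        "metals": {
            m: {f: getattr(params.metals[m], f) for f in _METAL_FIELDS}
            for m in METALS
        },
        "exposure": {
            r: {f: getattr(params.exposure[r], f) for f in _EXPOSURE_FIELDS}
            for r in RECEPTORS
        },
    }


def to_yaml(params: ParameterSet, path) -> None:
    """Write the full parameter set, unit strings included, as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_as_mapping(params), fh, sort_keys=True)


def from_yaml(path) -> ParameterSet:
    """Read a parameter set written by :func:`to_yaml`.

    The ``units`` block is mandatory and must match the documented unit
    strings; this guards against silently importing constants on the wrong
    scale (e.g. ug/L standards).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "units" not in doc:
        raise ParameterError("parameter file must carry a 'units' mapping")
    for key, unit in UNITS.items():
        if doc["units"].get(key) != unit:
            raise ParameterError(
                f"unit mismatch for {key!r}: expected {unit!r}, got {doc['units'].get(key)!r}"
            )
    metals = {
        m: MetalToxicity(metal=m, **{f: vals.get(f) for f in _METAL_FIELDS})
        for m, vals in doc.get("metals", {}).items()
    }
    exposure = {
        r: ExposureProfile(receptor=r, **{f: vals[f] for f in _EXPOSURE_FIELDS})
        for r, vals in doc.get("exposure", {}).items()
    }
    return ParameterSet(metals=metals, exposure=exposure)
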
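"""Heavy metal pollution index (HPI) and metal index (MI).

HPI is a standard-weighted mean of per-metal sub-indices,

    Qi  = 100 * Ci / Si          (sub-index, percent of the standard)
    wi  = 1 / Si                 (weight, L/mg)
    HPI = sum(wi * Qi) / sum(wi)

where Ci is the sample concentration and Si the drinking-water standard of
metal i. MI sums concentrations scaled by the upper allowable limit (the
same standards table): MI = sum(Ci / UALi). Both are linear in the
concentration vector, so the index of a survey's mean composition equals
the mean of the per-sample indices.

Classification scales (half-open bins; the conventional printed scale
leaves a gap between 25 and 26, resolved here as contiguous bins):

    HPI: [0,25) excellent, [25,50) good, [50,75) poor, [75,100) very_poor,
         [100,inf) unsuitable
    MI:  [0,0.3) very_clean, [0.3,1) clean, [1,2) partly_affected,
         [2,4) moderately_affected, [4,6) heavily_affected,
         [6,inf) severely_affected

MI is reported per sample (so survey minima/maxima are meaningful); the
survey-mean variant — MI evaluated at the mean concentration of each metal,
which equals the mean per-sample MI by linearity — is exposed separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .hydrochem import MissingAnalyteError
from .parameters import METALS, load_default_parameters
from .samples_io import SurveyTable

__all__ = [
    "HPI_CLASSES",
    "MI_CLASSES",
    "IndexBreakdown",
    "hpi",
    "mi",
    "index_breakdown",
    "classify_hpi",
    "classify_mi",
    "indices_table",
    "mi_survey_mean",
    "summarize_indices",
]

HPI_CLASSES: tuple[str, ...] = ("excellent", "good", "poor", "very_poor", "unsuitable")
MI_CLASSES: tuple[str, ...] = (
    "very_clean",
    "clean",
    "partly_affected",
    "moderately_affected",
    "heavily_affected",
    "severely_affected",
)

#: (upper bound, label) for the half-open classification bins
_HPI_BINS = [(25.0, "excellent"), (50.0, "good"), (75.0, "poor"), (100.0, "very_poor")]
_MI_BINS = [
    (0.3, "very_clean"),
    (1.0, "clean"),
    (2.0, "partly_affected"),
    (4.0, "moderately_affected"),
    (6.0, "heavily_affected"),
]

#: human-readable range labels, mirroring the conventional report layout
HPI_RANGE_LABELS = {
    "excellent": "< 25",
    "good": "25 - 50",
    "poor": "50 - 75",
    "very_poor": "75 - 100",
    "unsuitable": "> 100",
}
MI_RANGE_LABELS = {
    "very_clean": "MI < 0.3",
    "clean": "0.3 < MI < 1",
    "partly_affected": "1 < MI < 2",
    "moderately_affected": "2 < MI < 4",
    "heavily_affected": "4 < MI < 6",
    "severely_affected": "MI > 6",
}


def _metal_values(metals: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for m in METALS:
        try:
            v = float(metals[m])
        except (KeyError, TypeError):
            raise MissingAnalyteError(f"missing metal {m!r}") from None
        if v != v:
            raise MissingAnalyteError(f"missing metal {m!r} (NaN)")
        if v < 0:
            raise ValueError(f"negative concentration for {m!r}: {v}")
        out[m] = v
    return out


def _standards(standards: Mapping[str, float] | None) -> dict[str, float]:
    if standards is None:
        return load_default_parameters().standards
    out = {}
    for m in METALS:
        if m not in standards:
            raise MissingAnalyteError(f"missing standard Si for metal {m!r}")
        si = float(standards[m])
        if not si > 0:
            raise ValueError(f"standard Si for {m!r} must be > 0, got {si}")
        out[m] = si
    return out


@dataclass(frozen=True)
class IndexBreakdown:
    """Per-sample pollution index decomposition."""

    qi: dict[str, float]
    wi: dict[str, float]
    hpi: float
    mi: float
    hpi_class: str
    mi_class: str


def hpi(metals: Mapping[str, float], standards: Mapping[str, float] | None = None) -> float:
    """Heavy metal pollution index: sum(wi*Qi)/sum(wi), wi = 1/Si, Qi = 100 Ci/Si."""
    c = _metal_values(metals)
    si = _standards(standards)
    num = sum((1.0 / si[m]) * (100.0 * c[m] / si[m]) for m in METALS)
    den = sum(1.0 / si[m] for m in METALS)
    return num / den


def mi(metals: Mapping[str, float], standards: Mapping[str, float] | None = None) -> float:
    """Metal index: sum of concentrations over upper allowable limits."""
    c = _metal_values(metals)
    ual = _standards(standards)
    return sum(c[m] / ual[m] for m in METALS)


def index_breakdown(
    metals: Mapping[str, float], standards: Mapping[str, float] | None = None
) -> IndexBreakdown:
    """Full HPI + MI decomposition (Qi, wi, values and classes) for one sample."""
    c = _metal_values(metals)
    si = _standards(standards)
    qi = {m: 100.0 * c[m] / si[m] for m in METALS}
    wi = {m: 1.0 / si[m] for m in METALS}
    hpi_val = sum(wi[m] * qi[m] for m in METALS) / sum(wi.values())
    mi_val = sum(c[m] / si[m] for m in METALS)
    return IndexBreakdown(
        qi=qi,
        wi=wi,
        hpi=hpi_val,
        mi=mi_val,
        hpi_class=classify_hpi(hpi_val),
        mi_class=classify_mi(mi_val),
    )


def classify_hpi(value: float) -> str:
    """HPI quality class on the five-bin scale (unsuitable above 100)."""
    if value < 0:
        raise ValueError(f"HPI must be >= 0, got {value}")
    for upper, label in _HPI_BINS:
        if value < upper:
            return label
    return "unsuitable"


def classify_mi(value: float) -> str:
    """MI contamination class on the six-bin scale (severely affected above 6)."""
    if value < 0:
        raise ValueError(f"MI must be >= 0, got {value}")
    for upper, label in _MI_BINS:
        if value < upper:
            return label
    return "severely_affected"


def indices_table(
    table: SurveyTable, standards: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Per-sample HPI/MI with classes: columns sample_id, HPI, HPI_class, MI, MI_class."""
    si = _standards(standards)
    rows = []
    for sample in table.samples():
        b = index_breakdown(sample.metals, si)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "HPI": b.hpi,
                "HPI_class": b.hpi_class,
                "MI": b.mi,
                "MI_class": b.mi_class,
            }
        )
    return pd.DataFrame(rows)


def mi_survey_mean(
    table: SurveyTable, standards: Mapping[str, float] | None = None
) -> float:
    """MI evaluated at the survey-mean concentrations (equals mean per-sample MI)."""
    means = {m: float(table.data[m].mean()) for m in METALS}
    return mi(means, standards)


def summarize_indices(
    table: SurveyTable, standards: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Report-style summary: min/max/mean plus class counts and percentages.

    One row per (criterion, class bin): columns ``criterion, min, max, mean,
    range, class, n, pct``.
    """
    per_sample = indices_table(table, standards)
    n_total = len(per_sample)
    rows = []
    for crit, classes, labels in (
        ("MI", MI_CLASSES, MI_RANGE_LABELS),
        ("HPI", HPI_CLASSES, HPI_RANGE_LABELS),
    ):
        values = per_sample[crit]
        counts = per_sample[f"{crit}_class"].value_counts()
        for cls in classes:
            n = int(counts.get(cls, 0))
            rows.append(
                {
                    "criterion": crit,
                    "min": float(values.min()),
                    "max": float(values.max()),
                    "mean": float(values.mean()),
                    "range": labels[cls],
                    "class": cls,
                    "n": n,
                    "pct": 100.0 * n / n_total,
                }
            )
    return pd.DataFrame(rows)
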
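import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aquarisk import SurveyTable, generate_survey, load_default_parameters
from aquarisk.parameters import METALS
from aquarisk.samples_io import IONS

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


def build_survey(rows: list[dict]) -> SurveyTable:
    """Survey from a list of row dicts; unspecified analytes default small."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "sample_id": row.get("sample_id", f"S{i + 1}"),
            "source_class": row.get("source_class", "TCA_well"),
            "pH": row.get("pH", 7.5),
        }
        for col in IONS:
            rec[col] = row.get(col, 10.0)
        for col in METALS:
            rec[col] = row.get(col, 0.01)
        records.append(rec)
    return SurveyTable(data=pd.DataFrame(records), provenance="test")


def random_survey(rng: np.random.Generator, n: int = 10) -> SurveyTable:
    """Random valid survey with positive, right-skewed concentrations."""
    records = []
    for i in range(n):
        rec = {
            "sample_id": f"R{i + 1}",
            "source_class": "TCA_well",
            "pH": float(rng.uniform(6.5, 8.8)),
        }
        for col in IONS:
            rec[col] = float(rng.lognormal(3.0, 1.0))
        for col in METALS:
            rec[col] = float(rng.lognormal(-2.5, 1.2))
        records.append(rec)
    return SurveyTable(data=pd.DataFrame(records), provenance="test")


@pytest.fixture
def toy_survey():
    return build_survey(
        [
            {"sample_id": "A", "Na": 230.0, "Cl": 355.0, "Cd": 0.003},
            {"sample_id": "B", "Na": 460.0, "Cl": 710.0, "Cd": 0.03},
            {"sample_id": "C", "Na": 920.0, "Cl": 1420.0, "Cd": 0.15},
        ]
    )


@pytest.fixture(scope="session")
def survey_seed1():
    return generate_survey(seed=1)


@pytest.fixture(scope="session")
def twenty_surveys():
    return [generate_survey(seed=k) for k in range(20)]
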
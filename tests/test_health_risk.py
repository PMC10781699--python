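"""Deterministic intake and risk arithmetic, route consistency, vectorization."""

import numpy as np
import pandas as pd
import pytest

from aquarisk.health_risk import (
    NotApplicableError,
    cdi_dermal,
    cdi_oral,
    classify_cr,
    classify_hi,
    cr,
    hi,
    hq,
    risk_table,
)
from aquarisk.hydrochem import MissingAnalyteError
from aquarisk.parameters import CARCINOGENS, METALS, ParameterError
from aquarisk.samples_io import SurveyTable
from .conftest import build_survey, random_survey


class TestCdiOral:
    def test_unit_concentration_adult(self, params):
        # 2.2 * 350 * 70 / (70 * 25550) by hand
        assert cdi_oral(1.0, params.profile("adult")) == pytest.approx(
            53900.0 / 1788500.0, rel=1e-12
        )

    def test_zero_concentration(self, params):
        assert cdi_oral(0.0, params.profile("adult")) == 0.0

    def test_chromium_survey_minimum(self, params):
        got = cdi_oral(0.0015, params.profile("adult"))
        assert got == pytest.approx(4.5205e-5, rel=1e-4)


class TestCdiDermal:
    def test_zero(self, params):
        assert cdi_dermal(0.0, params.profile("child"), kp=0.002) == 0.0

    def test_chromium_survey_maximum_child(self, params):
        # 12.3 * 1 * 350 * 0.002 * 6600 * 0.001 * 6 / (15 * 2190) by hand
        expected = 12.3 * 350 * 0.002 * 6600 * 0.001 * 6 / (15 * 2190)
        got = cdi_dermal(12.3, params.profile("child"), kp=0.002)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.0379e-2, rel=1e-4)

    def test_linear_in_skin_area(self, params):
        from dataclasses import replace

        prof = params.profile("adult")
        doubled = replace(prof, sa=2 * prof.sa)
        assert cdi_dermal(1.0, doubled, 0.001) == pytest.approx(
            2 * cdi_dermal(1.0, prof, 0.001), rel=1e-12
        )


class TestHq:
    def test_zinc_adult_oral_minimum(self, params):
        """The smallest oral hazard quotient in the survey: Zn at 0.0002 mg/L."""
        got = hq(cdi_oral(0.0002, params.profile("adult")), params.toxicity("Zn").rfd_oral)
        assert got == pytest.approx(2.01e-5, rel=5e-3)

    def test_zinc_adult_dermal_minimum(self, params):
        got = hq(
            cdi_dermal(0.0002, params.profile("adult"), params.toxicity("Zn").kp),
            params.toxicity("Zn").rfd_dermal,
        )
        assert got == pytest.approx(2.86e-7, rel=5e-3)

    def test_cdi_equal_rfd_is_one(self):
        assert hq(0.3, 0.3) == 1.0

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(ParameterError):
            hq(0.1, 0.0)

    def test_route_consistency(self, params):
        """HQ_dermal via RfD_dermal equals HQ via RfD_oral*ABS for every metal."""
        for m in METALS:
            tox = params.toxicity(m)
            for receptor in ("adult", "child"):
                cdi = cdi_dermal(0.37, params.profile(receptor), tox.kp)
                assert hq(cdi, tox.rfd_dermal) == pytest.approx(
                    hq(cdi, tox.rfd_oral * tox.abs_gi), rel=1e-9
                )

    def test_child_to_adult_oral_ratio_is_constant(self, params):
        """ED/AT cancels to 1/365 for both receptors, leaving the fixed
        ratio (IR_child/IR_adult)*(BW_adult/BW_child) ~ 3.818."""
        expected = (1.8 / 2.2) * (70.0 / 15.0)
        rng = np.random.default_rng(5)
        for m in METALS:
            c = float(rng.uniform(1e-4, 10))
            rfd = params.toxicity(m).rfd_oral
            ratio = hq(cdi_oral(c, params.profile("child")), rfd) / hq(
                cdi_oral(c, params.profile("adult")), rfd
            )
            assert ratio == pytest.approx(expected, rel=1e-12)


class TestHi:
    def test_zeros(self):
        assert hi({m: 0.0 for m in METALS}) == 0.0

    def test_single_contribution(self):
        hqs = {m: 0.0 for m in METALS}
        hqs["Cd"] = 2.0
        assert hi(hqs) == 2.0

    def test_equals_brute_force_resum(self):
        rng = np.random.default_rng(1)
        hqs = {m: float(rng.uniform(0, 5)) for m in METALS}
        assert hi(hqs) == pytest.approx(float(np.sum(sorted(hqs.values()))), rel=1e-12)

    def test_wrong_metal_set_rejected(self):
        with pytest.raises(ValueError, match="eight metals"):
            hi({"Cd": 1.0})


class TestCr:
    def test_chromium_adult_oral_minimum(self, params):
        got = cr(cdi_oral(0.0015, params.profile("adult")), params.toxicity("Cr").csf_oral)
        assert got == pytest.approx(2.26e-5, rel=5e-3)

    def test_chromium_child_oral_minimum(self, params):
        got = cr(cdi_oral(0.0015, params.profile("child")), params.toxicity("Cr").csf_oral)
        assert got == pytest.approx(8.63e-5, rel=5e-3)

    def test_cadmium_adult_oral_at_survey_mean(self, params):
        got = cr(cdi_oral(0.04, params.profile("adult")), params.toxicity("Cd").csf_oral)
        assert got == pytest.approx(0.007, rel=0.06)

    def test_zero_cdi(self):
        assert cr(0.0, 6.1) == 0.0

    def test_missing_slope_factor_not_applicable(self, params):
        with pytest.raises(NotApplicableError):
            cr(1e-3, params.toxicity("Zn").csf_oral)


class TestClassification:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "low_risk"), (1.0, "low_risk"), (1.6, "high_risk")],
    )
    def test_hi_strict_threshold(self, value, expected):
        assert classify_hi(value) == expected

    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "acceptable"), (1e-4, "acceptable"), (1.001e-4, "high_risk")],
    )
    def test_cr_strict_threshold(self, value, expected):
        assert classify_cr(value) == expected


class TestRiskTable:
    def test_hi_is_sum_of_hqs(self, params, toy_survey):
        tables = risk_table(toy_survey, params)
        for (sid, receptor, route), grp in tables.per_metal.groupby(
            ["sample_id", "receptor", "route"]
        ):
            hi_row = tables.hazard.query(
                "sample_id == @sid and receptor == @receptor and route == @route"
            )["hi"].item()
            assert hi_row == pytest.approx(grp["hq"].sum(), rel=1e-12)

    def test_cr_only_for_carcinogens(self, params, toy_survey):
        tables = risk_table(toy_survey, params)
        na = tables.per_metal[~tables.per_metal["metal"].isin(CARCINOGENS)]
        assert (na["cr_class"] == "not_applicable").all()
        assert na["cr"].isna().all()
        carc = tables.per_metal[tables.per_metal["metal"].isin(CARCINOGENS)]
        assert carc["cr"].notna().all()

    def test_missing_concentration_no_partial_output(self, params, toy_survey):
        df = toy_survey.data.copy()
        df.loc[0, "Fe"] = np.nan
        with pytest.raises(MissingAnalyteError, match="Fe"):
            risk_table(SurveyTable(data=df), params)

    def test_vectorized_equals_scalar_loop(self, params):
        """The survey engine must agree with the scalar per-sample path."""
        rng = np.random.default_rng(99)
        survey = random_survey(rng, n=12)
        tables = risk_table(survey, params)
        for _, row in tables.per_metal.iterrows():
            tox = params.toxicity(row["metal"])
            profile = params.profile(row["receptor"])
            if row["route"] == "oral":
                cdi = cdi_oral(row["concentration"], profile)
            else:
                cdi = cdi_dermal(row["concentration"], profile, tox.kp)
            assert row["cdi"] == pytest.approx(cdi, rel=1e-12)
            assert row["hq"] == pytest.approx(hq(cdi, tox.rfd(row["route"])), rel=1e-12)
            if row["metal"] in CARCINOGENS:
                assert row["cr"] == pytest.approx(
                    cr(cdi, tox.csf(row["route"])), rel=1e-12
                )

    def test_summary_percentages_match_recount(self, params, survey_seed1):
        tables = risk_table(survey_seed1, params)
        for _, row in tables.summary.iterrows():
            crit = row["criterion"]
            if crit.startswith("HI"):
                receptor = "adult" if "Adult" in crit else "child"
                route = "oral" if "Oral" in crit else "dermal"
                grp = tables.hazard.query("receptor == @receptor and route == @route")
                n = (grp["hi_class"] == row["class"]).sum()
            else:
                _, metal, receptor, route = crit.replace("(", "").replace(")", "").split()
                grp = tables.per_metal.query(
                    "metal == @metal and receptor == @receptor.lower() and route == @route.lower()"
                )
                n = (grp["cr_class"] == row["class"]).sum()
            assert row["n"] == n

    def test_linearity_mean_hi_equals_hi_of_mean(self, params):
        rng = np.random.default_rng(7)
        survey = random_survey(rng, n=25)
        tables = risk_table(survey, params)
        mean_row = {m: float(survey.data[m].mean()) for m in METALS}
        mean_survey = build_survey([mean_row])
        mean_tables = risk_table(mean_survey, params)
        merged = tables.hazard.groupby(["receptor", "route"])["hi"].mean().reset_index()
        for _, row in merged.iterrows():
            expected = mean_tables.hazard.query(
                "receptor == @row.receptor and route == @row.route"
            )["hi"].item()
            assert row["hi"] == pytest.approx(expected, rel=1e-9)
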
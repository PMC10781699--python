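"""Distribution fitting, simulation reproducibility and convergence."""

import numpy as np
import pytest
from scipy import integrate, stats

from aquarisk.health_risk import NotApplicableError, cdi_oral, cr
from aquarisk.monte_carlo import (
    DistributionError,
    convergence_report,
    fit_distribution,
    simulate_risk,
    specs_from_stats,
)
from aquarisk.synthetic_data import table2_defaults

CD_STATS = dict(mean=0.04, sd=0.03, lower=0.002, upper=0.19)


class TestFitDistribution:
    def test_lognormal_closed_form_parameters(self):
        """Moment matching on the untruncated law: sigma^2 = ln(1+CV^2),
        mu = ln(mean) - sigma^2/2; verified by inverting back to (mean, sd)."""
        spec = fit_distribution("Cd", **CD_STATS)
        assert spec.sigma == pytest.approx(0.66805, rel=1e-4)
        assert spec.mu == pytest.approx(-3.44202, rel=1e-4)
        # independent check: the untruncated lognormal with these parameters
        # must reproduce the target moments
        mean_back = np.exp(spec.mu + spec.sigma**2 / 2)
        sd_back = mean_back * np.sqrt(np.expm1(spec.sigma**2))
        assert mean_back == pytest.approx(CD_STATS["mean"], rel=1e-12)
        assert sd_back == pytest.approx(CD_STATS["sd"], rel=1e-12)

    def test_zero_sd_gives_point_mass(self):
        spec = fit_distribution("Cd", mean=0.04, sd=0.0, lower=0.002, upper=0.19)
        rng = np.random.default_rng(0)
        assert np.all(spec.sample(rng, 100) == 0.04)

    def test_untruncated_sampling_recovers_mean(self):
        """Law of large numbers on the fitted law with loose bounds."""
        spec = fit_distribution("Cd", mean=0.04, sd=0.03, lower=0.0, upper=np.inf)
        rng = np.random.default_rng(123)
        draws = spec.sample(rng, 1_000_000)
        tol = 3 * 0.03 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.04) < tol

    def test_truncated_mean_matches_numerical_integration(self):
        spec = fit_distribution("Cd", **CD_STATS)
        pdf = stats.lognorm(s=spec.sigma, scale=np.exp(spec.mu))
        mass = pdf.cdf(spec.upper) - pdf.cdf(spec.lower)
        num, _ = integrate.quad(lambda x: x * pdf.pdf(x), spec.lower, spec.upper)
        assert spec.true_mean() == pytest.approx(num / mass, rel=1e-9)

    def test_nonpositive_mean_suggests_alternatives(self):
        with pytest.raises(DistributionError, match="truncated_normal"):
            fit_distribution("CO3", mean=0.0, sd=1.0, lower=0.0, upper=5.0)

    def test_infeasible_stats_rejected(self):
        with pytest.raises(DistributionError):
            fit_distribution("Cd", mean=0.5, sd=0.1, lower=0.0, upper=0.2)
        with pytest.raises(DistributionError):
            fit_distribution("Cd", mean=0.1, sd=0.1, lower=0.3, upper=0.2)

    def test_draws_respect_truncation_bounds(self):
        stats_table = table2_defaults()
        rng = np.random.default_rng(77)
        for metal, spec in specs_from_stats(stats_table).items():
            draws = spec.sample(rng, 5000)
            assert draws.min() >= spec.lower
            assert draws.max() <= spec.upper


class TestSimulateRisk:
    def test_point_mass_reproduces_deterministic_risk(self, params):
        """With a degenerate concentration distribution every draw equals
        the deterministic cancer risk at the survey-mean concentration."""
        spec = fit_distribution("Cd", mean=0.04, sd=0.0, lower=0.002, upper=0.19)
        res = simulate_risk(
            {"Cd": spec}, params, "adult", "oral", "CR", n_iter=10_000, seed=3
        )["Cd"]
        expected = cr(cdi_oral(0.04, params.profile("adult")), params.toxicity("Cd").csf_oral)
        assert np.all(res.draws == expected)
        assert res.mean == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0074, rel=0.01)

    def test_percentiles_ordered(self, params):
        specs = specs_from_stats(table2_defaults())
        res = simulate_risk(specs, params, "child", "dermal", "HQ", n_iter=2000, seed=9)
        for r in res.values():
            assert r.p5 <= r.p50 <= r.p95

    def test_mc_mean_matches_analytic_truncated_mean(self, params):
        """MC mean CR agrees with the deterministic risk at the truncated
        distribution's analytic mean within 3 standard errors."""
        spec = fit_distribution("Cd", **CD_STATS)
        res = simulate_risk({"Cd": spec}, params, "adult", "oral", "CR", n_iter=10_000, seed=11)["Cd"]
        unit_risk = cr(cdi_oral(1.0, params.profile("adult")), params.toxicity("Cd").csf_oral)
        analytic = spec.true_mean() * unit_risk
        se = res.draws.std(ddof=1) / np.sqrt(res.n_iter)
        assert abs(res.mean - analytic) < 3 * se

    def test_identical_seeds_bit_identical(self, params):
        specs = specs_from_stats(table2_defaults())
        a = simulate_risk(specs, params, "adult", "oral", "HQ", n_iter=1000, seed=21)
        b = simulate_risk(specs, params, "adult", "oral", "HQ", n_iter=1000, seed=21)
        for m in a:
            assert a[m].mean == b[m].mean
            assert (a[m].p5, a[m].p50, a[m].p95) == (b[m].p5, b[m].p50, b[m].p95)
            assert np.array_equal(a[m].draws, b[m].draws)

    def test_risk_percentiles_scale_concentration_percentiles(self, params):
        """Risk is concentration times a constant, so percentiles commute
        with the scaling at machine precision on the same draw set."""
        spec = fit_distribution("Cr", mean=0.6, sd=1.63, lower=0.0015, upper=12.3)
        res = simulate_risk({"Cr": spec}, params, "child", "oral", "CR", n_iter=5000, seed=2)["Cr"]
        unit_risk = cr(cdi_oral(1.0, params.profile("child")), params.toxicity("Cr").csf_oral)
        conc = res.draws / unit_risk
        for q, got in ((5, res.p5), (50, res.p50), (95, res.p95)):
            assert got == pytest.approx(np.percentile(conc, q) * unit_risk, rel=1e-12)

    def test_cr_for_non_carcinogen_not_applicable(self, params):
        spec = fit_distribution("Zn", mean=0.03, sd=0.024, lower=0.0002, upper=0.1)
        with pytest.raises(NotApplicableError):
            simulate_risk({"Zn": spec}, params, "adult", "oral", "CR", n_iter=10, seed=0)

    def test_exceedance_fraction_consistent_with_draws(self, params):
        spec = fit_distribution("Cd", **CD_STATS)
        res = simulate_risk({"Cd": spec}, params, "child", "oral", "CR", n_iter=4000, seed=5)["Cd"]
        assert res.fraction_exceeding == pytest.approx(np.mean(res.draws > 1e-4))
        assert 0.0 <= res.fraction_exceeding <= 1.0

    def test_single_draw_percentiles_collapse(self, params):
        spec = fit_distribution("Cd", **CD_STATS)
        res = simulate_risk({"Cd": spec}, params, "adult", "oral", "HQ", n_iter=1, seed=8)["Cd"]
        assert res.p5 == res.p50 == res.p95 == res.draws[0]


class TestConvergence:
    def test_dispersion_shrinks_with_iterations(self, params):
        spec = {"Cd": fit_distribution("Cd", **CD_STATS)}
        report = convergence_report(
            spec, params, "adult", "oral", "CR",
            n_grid=(100, 10_000), seeds=range(5),
        )
        sd_by_n = report.groupby("n_iter")["sd_p95"].first()
        assert sd_by_n.loc[10_000] < sd_by_n.loc[100]

    def test_single_seed_rows_identical_across_repeats(self, params):
        spec = {"Cd": fit_distribution("Cd", **CD_STATS)}
        a = convergence_report(spec, params, n_grid=(50, 100), seeds=[4])
        b = convergence_report(spec, params, n_grid=(50, 100), seeds=[4])
        assert a.equals(b)

    def test_requires_two_grid_points(self, params):
        with pytest.raises(ValueError):
            convergence_report({}, params, n_grid=(100,), seeds=[0])
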
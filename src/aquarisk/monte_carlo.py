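"""Probabilistic (Monte Carlo) risk assessment.

Concentration uncertainty is propagated through the deterministic intake
and risk equations by simulation: a distribution is fitted to each metal's
survey summary statistics (mean, SD, min, max), ``n_iter`` concentrations
are drawn per metal, converted to CDI for the chosen receptor and route,
and summarized as HQ or CR with mean, 5th/50th/95th percentiles and the
fraction of draws exceeding the decision threshold (HQ > 1, CR > 1e-4).

Distribution families
---------------------
``truncated_lognormal`` (default; right-skewed, strictly positive analytes):
log-scale parameters are moment-matched on the *untruncated* law,

    sigma^2 = ln(1 + (sd/mean)^2),    mu = ln(mean) - sigma^2 / 2,

then the law is restricted to [min, max] by inverse-CDF conditioning.
``truncated_normal`` and ``uniform`` are provided for sensitivity analysis;
``empirical`` resamples observed values. A zero SD collapses any family to
a point mass, which makes the simulation reproduce the deterministic risk
exactly.

Reproducibility contract: one generator, seeded once per
:func:`simulate_risk` call; metals consume fixed-length blocks of the
stream in canonical metal order, so identical (specs, parameters, seed,
n_iter) give bit-identical results. Percentiles use linear interpolation
between order statistics (``numpy.percentile`` default). Because risk is
linear in concentration, risk percentiles equal concentration percentiles
times the deterministic unit-concentration risk factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .health_risk import CR_THRESHOLD, HI_THRESHOLD, NotApplicableError, _unit_cdi
from .parameters import METALS, ParameterSet, load_default_parameters

__all__ = [
    "FAMILIES",
    "DistributionError",
    "DistributionSpec",
    "fit_distribution",
    "specs_from_stats",
    "MCResult",
    "simulate_risk",
    "convergence_report",
]

FAMILIES: tuple[str, ...] = ("truncated_lognormal", "truncated_normal", "uniform", "empirical")


class DistributionError(ValueError):
    """Infeasible summary statistics or unsupported family for them."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted concentration distribution for one metal (mg/L).

    ``mu``/``sigma`` are the log-scale parameters of the lognormal family;
    ``values`` backs the empirical family. ``sd == 0`` denotes a point mass
    at ``mean`` regardless of family.
    """

    metal: str
    family: str
    mean: float
    sd: float
    lower: float
    upper: float
    mu: float | None = None
    sigma: float | None = None
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionError(f"unknown family {self.family!r}")
        if self.lower > self.upper:
            raise DistributionError(f"{self.metal}: lower {self.lower} > upper {self.upper}")
        if not self.lower <= self.mean <= self.upper:
            raise DistributionError(
                f"{self.metal}: mean {self.mean} outside [{self.lower}, {self.upper}]"
            )
        if self.sd < 0:
            raise DistributionError(f"{self.metal}: sd must be >= 0")

    @property
    def is_point_mass(self) -> bool:
        return self.sd == 0 or self.lower == self.upper

    def _frozen(self):
        if self.family == "truncated_lognormal":
            return stats.lognorm(s=self.sigma, scale=float(np.exp(self.mu)))
        if self.family == "truncated_normal":
            # mu/sigma, when set, are the underlying (pre-truncation)
            # location and scale; otherwise the summary mean/sd stand in
            loc = self.mu if self.mu is not None else self.mean
            scale = self.sigma if self.sigma is not None else self.sd
            return stats.norm(loc=loc, scale=scale)
        raise DistributionError(f"no underlying law for family {self.family!r}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of uniforms in [0,1) onto the truncated law."""
        u = np.asarray(u, float)
        if self.is_point_mass:
            return np.full_like(u, self.mean)
        if self.family == "uniform":
            return self.lower + u * (self.upper - self.lower)
        if self.family == "empirical":
            vals = np.asarray(self.values, float)
            return np.quantile(vals, u)
        dist = self._frozen()
        p_lo = float(dist.cdf(self.lower))
        p_hi = float(dist.cdf(self.upper))
        if not p_hi > p_lo:
            raise DistributionError(
                f"{self.metal}: truncation interval has no probability mass"
            )
        return dist.ppf(p_lo + u * (p_hi - p_lo))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n values; every draw respects the truncation bounds."""
        if self.family == "empirical" and not self.is_point_mass:
            return rng.choice(np.asarray(self.values, float), size=n, replace=True)
        x = self.ppf(rng.random(n))
        return np.clip(x, self.lower, self.upper)  # guard fp round-off at the edges

    def true_mean(self) -> float:
        """Analytic mean of the (truncated) law."""
        if self.is_point_mass:
            return self.mean
        if self.family == "uniform":
            return 0.5 * (self.lower + self.upper)
        if self.family == "empirical":
            return float(np.mean(self.values))
        if self.family == "truncated_normal":
            loc = self.mu if self.mu is not None else self.mean
            scale = self.sigma if self.sigma is not None else self.sd
            a = (self.lower - loc) / scale
            b = (self.upper - loc) / scale
            return float(stats.truncnorm(a, b, loc=loc, scale=scale).mean())
        # truncated lognormal: E[X | a<X<b] in closed form
        mu, sig = self.mu, self.sigma
        a, b = max(self.lower, 0.0), self.upper
        z_a = (np.log(a) - mu) / sig if a > 0 else -np.inf
        z_b = (np.log(b) - mu) / sig
        mass = stats.norm.cdf(z_b) - stats.norm.cdf(z_a)
        partial = stats.norm.cdf(z_b - sig) - stats.norm.cdf(z_a - sig)
        return float(np.exp(mu + sig**2 / 2) * partial / mass)


def fit_distribution(
    metal: str,
    mean: float,
    sd: float,
    lower: float,
    upper: float,
    family: str = "truncated_lognormal",
    values: Sequence[float] | None = None,
) -> DistributionSpec:
    """Fit a concentration distribution to summary statistics.

    For the lognormal family the log-scale parameters are moment-matched on
    the untruncated law and the result truncated to [lower, upper]; a zero
    SD yields a point mass at the mean.
    """
    if lower > upper:
        raise DistributionError(f"{metal}: min {lower} > max {upper}")
    if not lower <= mean <= upper:
        raise DistributionError(f"{metal}: mean {mean} outside [{lower}, {upper}]")
    if sd < 0:
        raise DistributionError(f"{metal}: sd must be >= 0, got {sd}")
    mu = sigma = None
    if family == "truncated_lognormal" and sd > 0:
        if mean <= 0:
            raise DistributionError(
                f"{metal}: lognormal requires mean > 0 (got {mean}); "
                "consider family='truncated_normal' or 'uniform'"
            )
        sigma = float(np.sqrt(np.log(1.0 + (sd / mean) ** 2)))
        mu = float(np.log(mean) - sigma**2 / 2.0)
    if family == "empirical":
        if values is None or len(values) == 0:
            raise DistributionError(f"{metal}: empirical family requires observed values")
        values = tuple(float(v) for v in values)
    return DistributionSpec(
        metal=metal, family=family, mean=mean, sd=sd, lower=lower, upper=upper,
        mu=mu, sigma=sigma, values=values,
    )


def specs_from_stats(
    stats_table: pd.DataFrame, family: str = "truncated_lognormal"
) -> dict[str, DistributionSpec]:
    """Fit one spec per metal from a stats table with columns min,max,mean,sd."""
    out = {}
    for metal in METALS:
        if metal not in stats_table.index:
            continue
        row = stats_table.loc[metal]
        out[metal] = fit_distribution(
            metal, float(row["mean"]), float(row["sd"]),
            float(row["min"]), float(row["max"]), family=family,
        )
    return out


@dataclass
class MCResult:
    """Monte Carlo summary for one metal / receptor / route / endpoint."""

    metal: str
    receptor: str
    route: str
    endpoint: str
    n_iter: int
    seed: int
    mean: float
    p5: float
    p50: float
    p95: float
    fraction_exceeding: float
    draws: np.ndarray = field(repr=False)


def simulate_risk(
    specs: Mapping[str, DistributionSpec],
    params: ParameterSet | None = None,
    receptor: str = "adult",
    route: str = "oral",
    endpoint: str = "HQ",
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict[str, MCResult]:
    """Simulate HQ or CR for each metal in ``specs``.

    Draws are consumed from a single seeded generator in canonical metal
    order (fixed per-metal offsets), so results are bit-reproducible for
    identical inputs. Returns a dict metal -> :class:`MCResult`.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if endpoint not in ("HQ", "CR"):
        raise ValueError(f"endpoint must be 'HQ' or 'CR', got {endpoint!r}")
    params = params or load_default_parameters()
    profile = params.profile(receptor)
    metals = [m for m in METALS if m in specs]
    if endpoint == "CR":
        for m in metals:
            if params.toxicity(m).csf(route) is None:
                raise NotApplicableError(
                    f"{m} has no cancer slope factor; CR is not applicable"
                )
    threshold = HI_THRESHOLD if endpoint == "HQ" else CR_THRESHOLD

    rng = np.random.default_rng(seed)
    out: dict[str, MCResult] = {}
    for metal in metals:
        tox = params.toxicity(metal)
        conc = specs[metal].sample(rng, n_iter)
        unit_cdi = _unit_cdi(tox.kp, profile, route)
        cdi = conc * unit_cdi
        if endpoint == "HQ":
            draws = cdi / tox.rfd(route)
        else:
            draws = cdi * tox.csf(route)
        p5, p50, p95 = np.percentile(draws, [5, 50, 95])
        out[metal] = MCResult(
            metal=metal,
            receptor=receptor,
            route=route,
            endpoint=endpoint,
            n_iter=n_iter,
            seed=seed,
            mean=float(draws.mean()),
            p5=float(p5),
            p50=float(p50),
            p95=float(p95),
            fraction_exceeding=float(np.mean(draws > threshold)),
            draws=draws,
        )
    return out


def results_frame(results: Mapping[str, MCResult]) -> pd.DataFrame:
    """Flatten simulate_risk output into a tidy DataFrame (no draws)."""
    return pd.DataFrame(
        [
            {
                "metal": r.metal,
                "receptor": r.receptor,
                "route": r.route,
                "endpoint": r.endpoint,
                "n_iter": r.n_iter,
                "seed": r.seed,
                "mean": r.mean,
                "p5": r.p5,
                "p50": r.p50,
                "p95": r.p95,
                "fraction_exceeding": r.fraction_exceeding,
            }
            for r in results.values()
        ]
    )


def convergence_report(
    specs: Mapping[str, DistributionSpec],
    params: ParameterSet | None = None,
    receptor: str = "adult",
    route: str = "oral",
    endpoint: str = "HQ",
    n_grid: Iterable[int] = (100, 1_000, 10_000),
    seeds: Iterable[int] = (0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Percentile estimates across iteration counts and replicate seeds.

    Returns a tidy table (n_iter, seed, metal, mean, p5, p50, p95) plus the
    across-seed standard deviation columns ``sd_p5/sd_p50/sd_p95`` merged per
    (n_iter, metal), demonstrating stabilization as n grows.
    """
    n_grid = sorted(set(int(n) for n in n_grid))
    seeds = list(seeds)
    if len(n_grid) < 2:
        raise ValueError("convergence report needs at least two iteration counts")
    rows = []
    for n in n_grid:
        for seed in seeds:
            for r in simulate_risk(
                specs, params, receptor, route, endpoint, n_iter=n, seed=seed
            ).values():
                rows.append(
                    {
                        "n_iter": n,
                        "seed": seed,
                        "metal": r.metal,
                        "mean": r.mean,
                        "p5": r.p5,
                        "p50": r.p50,
                        "p95": r.p95,
                    }
                )
    tidy = pd.DataFrame(rows)
    disp = (
        tidy.groupby(["n_iter", "metal"])[["p5", "p50", "p95"]]
        .std(ddof=1)
        .rename(columns=lambda c: f"sd_{c}")
        .reset_index()
    )
    return tidy.merge(disp, on=["n_iter", "metal"])
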
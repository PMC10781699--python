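"""Synthetic hydrochemical survey generator.

The study region's raw 133-sample survey is unpublished, so this module
generates surveys that emulate its published summary: per-parameter
min/max/mean/SD, right-skewed marginals, the strong inter-ion and
inter-metal correlations, the 113/8/12 split between aquifer wells,
springs and lake/drain samples, and ionic balance within +-5%.

Construction
------------
1. *Marginals.* Each analyte gets a truncated distribution on its printed
   [min, max]: truncated lognormal for ions and metals (right-skewed,
   strictly positive), truncated normal for pH and HCO3 (narrow,
   near-symmetric). Parameters are moment-matched on the **truncated** law
   (numerically, initialised at the untruncated closed form), so the
   truncated mean and SD hit the printed targets without truncation bias.
2. *Dependence.* A Gaussian copula couples the columns. Each published
   Pearson correlation is mapped to a latent normal correlation by Nataf
   calibration: the latent value is root-solved so that the model Pearson
   correlation of the two truncated marginals (computed by Gauss-Hermite
   quadrature) equals the target. The assembled latent matrix is projected
   to the nearest positive semi-definite correlation matrix.
3. *Ionic balance.* Chloride absorbs each sample's residual charge
   imbalance (cations are rescaled when its bounds bind) until |IBE| <=
   the configured tolerance, mirroring the analytical acceptance rule
   applied to the real survey and tying Cl to total mineralization.
4. *Provenance classes.* The lake/drain group is the upper tail: the
   rows with the largest ion sums become ``lake_drain``; springs are drawn
   at random from the remainder.

TDS is never sampled: it is the sum of the generated ions (matching how
the survey's TDS was computed), and its printed statistics serve as
validation targets only. Everything is deterministic under the seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .hydrochem import ANIONS, CATIONS, EQUIVALENT_WEIGHTS
from .monte_carlo import DistributionSpec
from .parameters import METALS
from .samples_io import IONS, SurveyTable

__all__ = [
    "table2_defaults",
    "DEFAULT_CORRELATIONS",
    "VALIDATION_CORRELATIONS",
    "GeneratorConfigError",
    "GeneratorConfig",
    "generate_survey",
]

#: published per-parameter summary statistics (mg/L except pH); TDS is a
#: validation row, not a sampling target
_TARGET_STATS_CSV = """\
parameter,min,max,mean,sd
pH,6.8,8.7,7.9,0.3
TDS,1120,153589,9834.1,20701.9
K,3.5,83,42.8,18.5
Na,192,39500,2240.9,5531.6
Mg,9,12216.6,676.6,1388.8
Ca,19.6,2508.8,366.5,401
Cl,580,94250,5933.9,13042.3
SO4,5,5348.7,486.6,652.4
HCO3,83.7,328.8,166.7,36.5
CO3,0,35.3,6.2,8.8
Cd,0.002,0.19,0.04,0.03
Cr,0.0015,12.3,0.6,1.63
Cu,0.002,15.6,1.14,3.004
Fe,0.003,36.2,2.16,5.35
Mn,0.0002,3.37,0.28,0.68
Ni,0.0001,0.72,0.1,0.12
Pb,0.002,2.23,0.33,0.34
Zn,0.0002,0.1,0.03,0.024
"""


def table2_defaults() -> pd.DataFrame:
    """Published summary statistics: index parameter, columns min/max/mean/sd."""
    df = pd.read_csv(io.StringIO(_TARGET_STATS_CSV), index_col="parameter")
    return df.astype(float)


#: published pairwise Pearson correlations used as copula targets
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("Na", "Mg", 0.97),
    ("Na", "Ca", 0.83),
    ("Na", "Cl", 0.97),
    ("Na", "SO4", 0.92),
    ("Mg", "Cl", 0.96),
    ("Mg", "SO4", 0.95),
    ("Mg", "Ca", 0.82),
    ("Ca", "SO4", 0.86),
    ("Cr", "Cu", 0.81),
    ("Cr", "Fe", 0.77),
    ("Cr", "Ni", 0.59),
    ("Cr", "Mn", 0.8),
    ("Cu", "Fe", 0.85),
    ("Cu", "Mn", 0.9),
    ("Cu", "Ni", 0.65),
    ("Mn", "Ni", 0.64),
    ("Pb", "Ni", 0.52),
)

#: published correlations involving the derived TDS column; these are
#: emergent properties of the generated ion block (validation only)
VALIDATION_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("TDS", "Na", 0.99),
    ("TDS", "Cl", 1.0),
    ("TDS", "Mg", 0.97),
    ("TDS", "Ca", 0.86),
    ("TDS", "SO4", 0.95),
)

# narrow, near-symmetric marginals; CO3 (SD > mean) is infeasible as a
# truncated normal on [0, max] and is sampled lognormal like the metals
_NORMAL_COLUMNS = ("pH", "HCO3")
_COLUMNS = ("pH",) + IONS + METALS


class GeneratorConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for survey generation.

    Defaults reproduce the published survey design: 133 samples split
    113/8/12 across aquifer wells, springs and lakes/drains, marginal
    targets from the published statistics table, copula targets from the
    published correlation list, ionic balance tolerance 5%.
    """

    n_samples: int = 133
    group_sizes: dict = field(
        default_factory=lambda: {"TCA_well": 113, "spring": 8, "lake_drain": 12}
    )
    stats: pd.DataFrame = field(default_factory=table2_defaults)
    correlations: tuple = DEFAULT_CORRELATIONS
    ibe_tolerance: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise GeneratorConfigError("n_samples must be >= 1")
        if sum(self.group_sizes.values()) != self.n_samples:
            raise GeneratorConfigError(
                f"group sizes {self.group_sizes} must sum to n_samples={self.n_samples}"
            )
        if not 0 < self.ibe_tolerance <= 100:
            raise GeneratorConfigError("ibe_tolerance must be in (0, 100]")
        for col in _COLUMNS:
            if col not in self.stats.index:
                raise GeneratorConfigError(f"stats table lacks a row for {col!r}")
            row = self.stats.loc[col]
            if row["min"] > row["max"]:
                raise GeneratorConfigError(f"{col}: min > max")
            if not row["min"] <= row["mean"] <= row["max"]:
                raise GeneratorConfigError(f"{col}: mean outside [min, max]")
            sd = row["sd"]
            if sd == sd and sd < 0:
                raise GeneratorConfigError(f"{col}: sd must be >= 0")
        for a, b, r in self.correlations:
            if not -1 <= r <= 1:
                raise GeneratorConfigError(f"correlation {a}-{b}={r} outside [-1, 1]")

    def resolved_sd(self, col: str) -> float:
        """Target SD; a missing (NaN) SD defaults to (max - min) / 4."""
        row = self.stats.loc[col]
        sd = float(row["sd"])
        if sd != sd:
            sd = (float(row["max"]) - float(row["min"])) / 4.0
        return sd


# --- truncation-aware moment matching --------------------------------------

def _lognormal_trunc_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and SD of a lognormal restricted to [lo, hi].

    Computed in log space so large trial sigmas during fitting cannot
    overflow: with z-scores of the bounds and partial-mass ratios
    D_k = Phi(z_hi - k sigma) - Phi(z_lo - k sigma),

        m1      = exp(mu + sigma^2/2) * D_1 / D_0
        m2/m1^2 = exp(sigma^2) * D_2 * D_0 / D_1^2
    """
    z_lo = (np.log(lo) - mu) / sigma if lo > 0 else -np.inf
    z_hi = (np.log(hi) - mu) / sigma
    d0 = ndtr(z_hi) - ndtr(z_lo)
    d1 = ndtr(z_hi - sigma) - ndtr(z_lo - sigma)
    d2 = ndtr(z_hi - 2 * sigma) - ndtr(z_lo - 2 * sigma)
    if d0 <= 0 or d1 <= 0:
        return np.nan, np.nan
    log_m1 = mu + sigma**2 / 2 + np.log(d1) - np.log(d0)
    m1 = np.exp(log_m1)
    if d2 <= 0:
        return m1, 0.0
    log_ratio = sigma**2 + np.log(d2) + np.log(d0) - 2 * np.log(d1)  # m2/m1^2
    var_ratio = np.expm1(log_ratio) if log_ratio < 500 else np.inf
    return m1, m1 * np.sqrt(max(var_ratio, 0.0))


def _fit_truncated_lognormal(mean: float, sd: float, lo: float, hi: float):
    """(mu, sigma) such that the [lo,hi]-truncated lognormal matches mean/sd."""
    sigma0 = float(np.sqrt(np.log(1.0 + (sd / mean) ** 2)))
    mu0 = float(np.log(mean) - sigma0**2 / 2.0)

    # For analytes whose printed maximum sits close to the mean the printed
    # SD may be unreachable under truncation; weight the mean residual
    # heavily so the fit always honours the mean and treats the SD as
    # best-effort.
    def residuals(p):
        mu, log_sigma = p
        m, s = _lognormal_trunc_moments(mu, np.exp(log_sigma), lo, hi)
        if not (np.isfinite(m) and np.isfinite(s)):
            return [1e6, 1e6]
        return [50.0 * (m / mean - 1.0), s / sd - 1.0]

    # sigma is capped at ~1.65x the closed-form value: larger sigmas can
    # match the printed SD too, but only by piling mass onto the truncation
    # bounds, which is not a credible concentration marginal and makes
    # sample means of small surveys wildly unstable
    sol = optimize.least_squares(
        residuals,
        [mu0, np.log(sigma0)],
        bounds=([mu0 - 10.0, np.log(sigma0) - 2.0], [mu0 + 10.0, np.log(sigma0) + 0.5]),
    )
    if not np.all(np.isfinite(sol.x)) or abs(sol.fun[0]) > 0.5:
        return mu0, sigma0  # refinement failed; untruncated closed form
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _fit_truncated_normal(mean: float, sd: float, lo: float, hi: float):
    """(loc, scale) such that the [lo,hi]-truncated normal matches mean/sd."""

    def residuals(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [(m - mean) / max(sd, 1e-12), (np.sqrt(v) - sd) / max(sd, 1e-12)]

    sol = optimize.least_squares(residuals, [mean, np.log(sd)], xtol=1e-12, ftol=1e-12)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return float(mean), float(sd)
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _column_spec(col: str, config: GeneratorConfig) -> DistributionSpec:
    row = config.stats.loc[col]
    lo, hi, mean = float(row["min"]), float(row["max"]), float(row["mean"])
    sd = config.resolved_sd(col)
    if sd == 0 or lo == hi:
        return DistributionSpec(
            metal=col, family="uniform", mean=mean, sd=0.0, lower=lo, upper=hi
        )
    if col in _NORMAL_COLUMNS or mean <= 0:
        loc, scale = _fit_truncated_normal(mean, sd, lo, hi)
        return DistributionSpec(
            metal=col, family="truncated_normal",
            mean=mean, sd=sd, lower=lo, upper=hi, mu=loc, sigma=scale,
        )
    mu, sigma = _fit_truncated_lognormal(mean, sd, lo, hi)
    return DistributionSpec(
        metal=col, family="truncated_lognormal",
        mean=mean, sd=sd, lower=lo, upper=hi, mu=mu, sigma=sigma,
    )


# --- Nataf latent-correlation calibration -----------------------------------

_GH_NODES = 48
_gh_x, _gh_w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
_gh_w = _gh_w / np.sqrt(2.0 * np.pi)  # weights for E[f(Z)], Z ~ N(0,1)


def _transform_on_nodes(spec: DistributionSpec, z: np.ndarray) -> np.ndarray:
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    return spec.ppf(u)


def _pair_pearson(spec_i, spec_j, rho: float) -> float:
    """Model Pearson correlation of two truncated marginals under a Gaussian
    copula with latent correlation rho (2-D Gauss-Hermite quadrature)."""
    gi = _transform_on_nodes(spec_i, _gh_x)
    mi = float(_gh_w @ gi)
    si = float(np.sqrt(_gh_w @ (gi - mi) ** 2))
    z2 = rho * _gh_x[:, None] + np.sqrt(1 - rho**2) * _gh_x[None, :]
    gj_cond = _transform_on_nodes(spec_j, z2)  # (k, l) grid
    mj = float(_gh_w @ _transform_on_nodes(spec_j, _gh_x))
    sj = float(np.sqrt(_gh_w @ (_transform_on_nodes(spec_j, _gh_x) - mj) ** 2))
    e_xy = float(_gh_w @ (gi * (gj_cond @ _gh_w)))
    return (e_xy - mi * mj) / (si * sj)


def _latent_correlation(spec_i, spec_j, target: float) -> float:
    """Root-solve the latent normal correlation hitting the target Pearson."""
    if target == 0:
        return 0.0
    lo, hi = (0.0, 0.9995) if target > 0 else (-0.9995, 0.0)
    f = lambda rho: _pair_pearson(spec_i, spec_j, rho) - target
    f_hi = f(hi)
    if target > 0 and f_hi < 0:
        return hi  # target unreachable under these marginals; saturate
    if target < 0 and f(lo) > 0:
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def _nearest_correlation(matrix: np.ndarray) -> np.ndarray:
    """Project onto the positive semi-definite correlation matrices
    (eigenvalue clipping followed by diagonal renormalisation)."""
    vals, vecs = np.linalg.eigh((matrix + matrix.T) / 2)
    vals = np.clip(vals, 1e-8, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


_PLAN_CACHE: dict = {}


def _sampling_plan(config: GeneratorConfig):
    """Fitted marginal specs + Cholesky factor of the latent correlation,
    cached on the numeric content of the configuration."""
    key = (
        tuple(np.round(config.stats.loc[list(_COLUMNS)].to_numpy(float).ravel(), 12)),
        tuple(config.correlations),
    )
    if key in _PLAN_CACHE:
        return _PLAN_CACHE[key]
    specs = {col: _column_spec(col, config) for col in _COLUMNS}
    latent = np.eye(len(_COLUMNS))
    index = {c: k for k, c in enumerate(_COLUMNS)}
    for a, b, r in config.correlations:
        if a not in index or b not in index:
            raise GeneratorConfigError(f"correlation references unknown column {a!r}/{b!r}")
        rho = _latent_correlation(specs[a], specs[b], r)
        latent[index[a], index[b]] = latent[index[b], index[a]] = rho
    latent = _nearest_correlation(latent)
    chol = np.linalg.cholesky(latent + 1e-10 * np.eye(len(latent)))
    plan = (specs, chol)
    _PLAN_CACHE[key] = plan
    return plan


# --- ionic balance repair ----------------------------------------------------

def _repair_ionic_balance(
    df: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Bring every sample to |IBE| <= tol by letting chloride absorb the
    residual charge imbalance.

    Charge balance couples the anion block to the cations far more tightly
    than any marginal sampling model can; most freshly drawn samples
    therefore violate the tolerance. For those samples Cl- (the dominant
    anion, with by far the widest printed range) is set so the balance
    lands at a small random residual of the original sign, leaving the
    SO4/HCO3/CO3 marginals untouched and tying Cl to total mineralization
    exactly as observed in the survey. When chloride's printed bounds bind,
    the cations are rescaled instead.
    """
    tol = config.ibe_tolerance
    eq = EQUIVALENT_WEIGHTS
    bounds = {
        ion: (float(config.stats.loc[ion, "min"]), float(config.stats.loc[ion, "max"]))
        for ion in IONS
    }

    def meq_sums(frame):
        cat = sum(frame[i] / eq[i] for i in CATIONS)
        an = sum(frame[i] / eq[i] for i in ANIONS)
        return cat, an

    for iteration in range(10):
        cat, an = meq_sums(df)
        ibe = 100.0 * (cat - an) / (cat + an)
        bad = ibe.abs() > tol
        if not bad.any():
            return df
        # aim at a small residual imbalance keeping the original sign
        e = np.sign(ibe[bad]) * rng.uniform(0.2, 0.8, size=int(bad.sum())) * tol / 100.0
        if iteration % 2 == 0:
            other_an = an[bad] - df.loc[bad, "Cl"] / eq["Cl"]
            cl_meq = cat[bad] * (1 - e) / (1 + e) - other_an
            lo, hi = bounds["Cl"]
            df.loc[bad, "Cl"] = (cl_meq * eq["Cl"]).clip(lo, hi)
        else:  # Cl bound binds: move the cations toward the anions
            factor = (an[bad] * (1 + e) / (1 - e)) / cat[bad]
            for ion in CATIONS:
                lo, hi = bounds[ion]
                df.loc[bad, ion] = (df.loc[bad, ion] * factor).clip(lo, hi)
    cat, an = meq_sums(df)
    ibe = 100.0 * (cat - an) / (cat + an)
    if (ibe.abs() > tol).any():
        raise RuntimeError("ionic balance repair did not converge")  # pragma: no cover
    return df


# --- the generator -----------------------------------------------------------

def generate_survey(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> SurveyTable:
    """Generate a synthetic survey under the configured study conditions.

    ``seed`` overrides ``config.seed``; one of the two must be set. The
    result is a fully validated :class:`SurveyTable` whose provenance
    records the seed.
    """
    config = config if config is not None else GeneratorConfig()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise GeneratorConfigError("a seed is required for reproducible generation")
    specs, chol = _sampling_plan(config)
    rng = np.random.default_rng(seed)

    n = config.n_samples
    z = rng.standard_normal((n, len(_COLUMNS))) @ chol.T
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    data = {
        col: specs[col].ppf(u[:, k]).astype(float) for k, col in enumerate(_COLUMNS)
    }
    df = pd.DataFrame(data)
    df = _repair_ionic_balance(df, config, rng)

    # provenance classes: lake/drain sit in the upper tail of total ions
    ion_sum = df[list(IONS)].sum(axis=1)
    order = np.argsort(-ion_sum.to_numpy())
    classes = np.array(["TCA_well"] * n, dtype=object)
    n_lake = config.group_sizes.get("lake_drain", 0)
    classes[order[:n_lake]] = "lake_drain"
    remaining = order[n_lake:]
    n_spring = config.group_sizes.get("spring", 0)
    if n_spring:
        spring_rows = rng.choice(remaining, size=n_spring, replace=False)
        classes[spring_rows] = "spring"

    out = pd.DataFrame({"sample_id": [f"SW{i + 1:03d}" for i in range(n)]})
    out["source_class"] = classes
    out["pH"] = df["pH"].round(2)
    for col in IONS + METALS:
        out[col] = df[col]
    return SurveyTable(data=out, provenance=f"synthetic:seed={seed}")
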
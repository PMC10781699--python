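# Methods

## Scope and data model

The package operates on per-sample water-chemistry tables: sample id, a
provenance class (`TCA_well` — Tertiary carbonate aquifer well —, `spring`,
`lake_drain`), pH, the eight major ions (Na⁺, K⁺, Ca²⁺, Mg²⁺, Cl⁻, SO₄²⁻,
HCO₃⁻, CO₃²⁻) and eight metals (Cd, Cr, Cu, Fe, Mn, Ni, Pb, Zn), all in
mg/L. Missing values stay explicit (empty CSV cell / NaN); computations
raise on a missing required analyte rather than imputing zero.

## Reference parameters

`parameters.load_default_parameters()` freezes the toxicological and
exposure constants used by the survey study:

| metal | RfD_oral | ABS   | RfD_dermal | Kp (cm/h) | Si = UAL (mg/L) | CSF_oral | CSF_dermal |
|-------|----------|-------|------------|-----------|-----------------|----------|------------|
| Cd    | 0.0005   | 0.05  | 0.000025   | 0.001     | 0.003           | 6.1      | 6100       |
| Cr    | 0.003    | 0.025 | 0.000075   | 0.002     | 0.05            | 0.5      | 500        |
| Cu    | 0.04     | 0.3   | 0.012      | 0.001     | 3               | —        | —          |
| Fe    | 0.7      | 0.2   | 0.14       | 0.001     | 0.3             | —        | —          |
| Mn    | 0.024    | 0.04  | 0.00096    | 0.001     | 0.05            | —        | —          |
| Ni    | 0.02     | 0.04  | 0.0008     | 0.0002    | 0.07            | —        | —          |
| Pb    | 0.0014   | 0.3   | 0.00042    | 0.0001    | 0.01            | 0.5      | 500        |
| Zn    | 0.3      | 0.2   | 0.06       | 0.0006    | 1               | —        | —          |

RfD in mg/kg/day, CSF in (mg/kg/day)⁻¹. The dermal reference dose obeys
RfD_dermal = RfD_oral × ABS for every row (the constructor enforces it to
1 part in 10⁶, which also validates user overrides). The dermal slope
factor is the oral one divided by the conventional 0.001 gastrointestinal
absorption adjustment; its 1000× ratio is asserted as a fixed consistency
check. The Cu standard (3 mg/L) is higher than the common 2 mg/L
guideline; it is kept as the survey's own choice and, like every constant,
is user-overridable through the YAML parameter file (unit strings are
mandatory there to guard against scale mistakes).

Exposure profiles (ingestion rate IR L/day, exposure frequency EF day/yr,
duration ED yr, body weight BW kg, averaging time AT day, skin area SA
cm², exposure time ET h/day, conversion CF L/cm³):

- adult: IR 2.2, EF 350, ED 70, BW 70, AT 25,550, SA 18,000, ET 0.58, CF 0.001
- child: IR 1.8, EF 350, ED 6, BW 15, AT 2,190, SA 6,600, ET 1, CF 0.001

AT = ED × 365 for both receptors and **both endpoints**: the common
alternative of a fixed 70-year averaging time for carcinogenic risk is not
used, because the survey's child cancer-risk values back-compute only
under AT_child = 2,190. A single EF applies to both receptors.

## Indices and risk equations

Per sample: Qᵢ = 100·Cᵢ/Sᵢ, wᵢ = 1/Sᵢ, HPI = Σ wᵢQᵢ / Σ wᵢ and
MI = Σ Cᵢ/UALᵢ over the eight metals. MI is evaluated per sample (so
survey minima/maxima are meaningful); by linearity the survey-mean variant
`mi_survey_mean` equals the mean per-sample MI.

Classification uses half-open bins. The conventional printed HPI scale
leaves a gap between 25 and 26; it is resolved as [0,25) excellent,
[25,50) good, [50,75) poor, [75,100) very poor, [100,∞) unsuitable. MI
bins are [0,0.3), [0.3,1), [1,2), [2,4), [4,6), [6,∞). Decision rules are
strict: HI > 1 and CR > 1×10⁻⁴; the boundary values themselves classify as
low-risk/acceptable.

CDI_oral = C·IR·EF·ED/(BW·AT) and CDI_dermal = C·ET·EF·Kp·SA·CF·ED/(BW·AT)
in mg/kg/day; HQ = CDI/RfD (route-matched), HI = Σ HQ over the eight
metals per route, CR = CDI·CSF for Cd, Cr, Pb only — other metals report
not-applicable, never zero. A total ΣCR column is exposed but not
classified. All quantities are homogeneous of degree one in concentration;
the vectorized survey engine therefore reduces each
(metal, receptor, route) to a constant unit-risk factor times the
concentration column, and is tested against the scalar per-sample path at
1e-12 relative.

Known inconsistency: the survey's printed oral HQ ranges for Cd
(1.12–11.58) and Pb (0.03–28.04) cannot be derived from its own printed
concentration extrema under these equations (they imply a Cd minimum of
~0.019 mg/L and a Pb maximum of ~1.30 mg/L). The engine follows the
equations; no constant was adjusted to chase those two ranges.

## Hydrochemistry

Milliequivalent conversion divides mg/L by the equivalent weights Na
22.99, K 39.10, Ca 20.04, Mg 12.155, Cl 35.45, SO₄ 48.03, HCO₃ 61.02, CO₃
30.005. TDS is the plain sum of the eight ion concentrations. The ionic
balance error is IBE = 100·(ΣC − ΣA)/(ΣC + ΣA) on the meq basis with the
±5% analytical acceptance rule.

The chloro-alkaline index is Schoeller's CAI-I = [Cl − (Na + K)]/Cl (meq);
positive values indicate reverse ion exchange. CAI-II is not implemented
(never used numerically in the source analysis). Salinity classes use the
conventional 1,000 / 10,000 / 100,000 mg/L TDS cuts (fresh / brackish /
saline / hypersaline), consistent with the labels the survey applies to
its own extremes.

Sulin genetic typing is reconstructed from the classical genetic
coefficients, since only the graph is published: Na/Cl > 1 → meteoric
branch (Na₂SO₄ if (Na−Cl)/SO₄ < 1, else NaHCO₃); Na/Cl ≤ 1 → marine
branch (MgCl₂ if (Cl−Na)/Mg < 1, else CaCl₂). Boundaries are deterministic:
Na/Cl = 1 falls on the marine branch, inner coefficients at exactly 1 go
to the CaCl₂/NaHCO₃ side. The rules are ratio-based and hence identical on
raw meq and meq%.

## Monte Carlo engine

`fit_distribution` maps survey summary statistics (mean, SD, min, max) to
a concentration distribution. The default family is the truncated
lognormal: log-scale parameters by moment matching on the untruncated law,
σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2, then inverse-CDF restriction
to [min, max]. sd = 0 collapses to a point mass, which makes the
simulation reproduce the deterministic risk bit-for-bit (a structural
self-check). Truncated normal, uniform and empirical families are provided
for sensitivity analysis because the original study does not state its
sampling law. Exposure parameters are fixed constants in the default run,
matching the single tabulated values.

Reproducibility contract: one `numpy` Generator seeded per
`simulate_risk` call; metals consume fixed blocks of the stream in
canonical metal order. Percentiles use linear interpolation between order
statistics (`numpy.percentile` default). Because risk is linear in
concentration, risk percentiles equal concentration percentiles times the
deterministic unit-concentration factor — asserted at machine precision.
`convergence_report` re-simulates across an iteration grid and replicate
seeds and reports across-seed percentile dispersion; at the study's 10,000
iterations the 95th-percentile dispersion is far below the 100-iteration
value.

The study's published Monte Carlo 5th/95th percentile values are **not
reproducible**: its input distribution is unstated, and the printed
percentiles are inconsistent with lognormal, normal or uniform fits to the
published summary statistics. They are therefore excluded from the
quantitative checks; the simulation engine is validated instead by the
structural properties above (point-mass degeneracy, analytic truncated
mean within Monte Carlo error, percentile ordering, bit-reproducibility).

## Synthetic survey generator

The generator emulates the study conditions: n = 133 samples split
113/8/12 across aquifer wells, springs and lakes/drains; per-parameter
min/max/mean/SD from the published statistics table; the published
inter-element Pearson correlations; |IBE| ≤ 5% everywhere.

1. **Marginals.** Ions and metals are truncated lognormals on their
   printed [min, max]; pH and HCO₃ are truncated normals (narrow,
   near-symmetric). CO₃ is lognormal despite being grouped with the
   carbonates: its printed SD (8.8) exceeds its mean (6.2), which no
   normal truncated at zero can reach. Parameters are moment-matched **on
   the truncated law** (numerically, initialised at the untruncated closed
   form) with the mean residual weighted 50:1 over the SD residual, so the
   truncated mean always hits the printed target. σ is capped at ~1.65×
   the closed-form value: beyond that the fit can also match heavy printed
   SDs, but only by piling probability onto the truncation bounds —
   an implausible concentration marginal that also makes 133-sample means
   unstable. Consequence: the realized SDs of the heaviest-tailed analytes
   (Na, Cl, Cu, Mn) undershoot the printed ones by roughly 20–30%. The
   printed SDs reflect a pooled wells-plus-hypersaline-lakes mixture that
   a single two-parameter family cannot fully reproduce.
2. **Dependence.** A Gaussian copula with Nataf-calibrated latent
   correlations: for each published pair the latent value is root-solved
   (Brent) so the model Pearson correlation of the two truncated
   marginals, computed by 48-node Gauss–Hermite quadrature, equals the
   printed value; unreachable targets saturate at 0.9995. The assembled
   matrix is projected to the nearest positive semi-definite correlation
   matrix (eigenvalue clipping + diagonal renormalisation) before
   Cholesky. Published correlations involving TDS are validation targets
   only — TDS is never sampled, it is the sum of the generated ions,
   matching how the survey computed it. The generated r(TDS, Cl) ≈ 0.99–1
   and r(TDS, Na) ≈ 0.99 emerge without being imposed.
3. **Charge balance.** Most raw copula draws violate |IBE| ≤ 5% because
   electroneutrality is physics, not a marginal property. For violating
   samples chloride — the dominant anion with the widest printed range —
   is set so the balance lands at a small random residual of the original
   sign; cations are rescaled in the rare cases chloride's bounds bind.
   This leaves the SO₄/HCO₃/CO₃ marginals untouched and couples Cl to
   total mineralization, as in the real survey. Chloride's pooled mean
   consequently sits a few percent below its printed target (within the
   15% recovery band).
4. **Provenance classes.** The 12 lake/drain samples are the upper tail of
   the per-sample ion sum; springs are drawn at random from the remainder.
   Hypersaline samples (TDS ≥ 100,000 mg/L) appear in roughly half of the
   seeds; every seed reaches deep into the saline regime.

Everything is deterministic under the seed (`provenance:
"synthetic:seed=N"`). A missing SD in a user-supplied stats table defaults
to (max − min)/4 and a configuration with min > max or a mean outside
[min, max] is rejected.

What the generator does **not** emulate: spatial structure (no
coordinates, no kriging fields), seasonal replicates, the bimodal
well/lake mixture underlying the printed SDs, and the survey's exact MI
floor — the published minimum MI is 6.5, while the generator occasionally
produces single samples with MI ≈ 5–6 (joint low draws the real survey
never shows). Tests therefore assert 100% HPI-unsuitable and ≥99%
MI-severely-affected per survey. Passing tests demonstrate the pipeline's
correctness and the recovery of the published summary structure, not
distributional identity with the unpublished raw data.

## Numerical choices and problem sizes

- Exact-arithmetic oracles (rational-fraction summation) back the index
  tests; hand-arithmetic products back the intake tests.
- Pooled marginal-mean recovery is checked over 20 seeds × 133 samples at
  a 15% band; per-seed means of analytes with CV ≈ 2.5 carry ~21% standard
  error at n = 133 — that noise floor belongs to the survey design itself,
  so recovery is asserted on the pooled estimate.
- Monte Carlo tests run 10,000 iterations (the study's setting) where the
  assertion needs it and 500–2,000 otherwise; the convergence check uses
  grid {100, 10,000} × 5 seeds.
- Generator plans (marginal fits + latent Cholesky factor) are cached on
  the numeric content of the configuration; the first build costs well
  under a second.

## Limitations

- Inhalation exposure, age-interpolated receptors, relative source
  contribution and 2-D (uncertainty × variability) Monte Carlo are out of
  scope.
- CAI-II, Piper/Durov/Gibbs diagrams and saturation indices are not
  implemented.
- The published survey-wide index ranges and class percentages depend on
  the unpublished raw data and are reproduced only in structure (headline
  class proportions, orders of magnitude), not numerically.
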
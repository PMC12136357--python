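# Methods

## Pipeline overview

`cprtrends` models functional-group phytoplankton biomass from
plankton-recorder-style abundance counts in five steps:

1. **Carbon conversion** (`biomass`). Each taxon's mean cell volume V
   (µm³) maps to per-cell carbon (pg C) through a group-specific power law
   log10 C = a + b·log10 V, with defaults a = −0.541, b = 0.811 for
   diatoms and the general-protist fit a = −0.665, b = 0.939 for
   dinoflagellates. The coefficients live in configuration
   (`biomass.ALLOMETRY`), not code. A taxon with unknown volume receives
   the geometric mean per-cell carbon of its group's known taxa —
   imputation on the log-carbon scale, chosen over log-volume imputation
   because carbon is the quantity the pipeline consumes (the two differ
   only through the curvature of the power law). Group biomass per sample
   is Σ abundance × carbon, reported in µg C.
2. **Aggregation and zero imputation** (`aggregate`). Samples are summed
   into province × 2.5°-latitude-band × month × year bins. Bands are
   half-open intervals [k·w, (k+1)·w) anchored at the equator — the width
   is the scientific choice; the anchoring is a reproducible convention.
   Longitude is discarded. Zero bins are then imputed, per group
   independently, at 50% of that group's minimum positive binned biomass
   over the whole aggregated dataset — one global floor per group,
   mirroring a survey-wide minimum detectable biomass. The diatom index
   p = q/(q+r) and its logit h are computed after imputation, so h is
   finite everywhere.
3. **SST anomaly** (`sst`). Observed SST is decomposed per province into
   month effects + latitudinal gradient + linear trend + residual; the
   per-record posterior median residual is the *temperature anomaly*.
   Because the removed structure is exactly the set of predictors in the
   biomass models, the anomaly enters them orthogonally (empirical
   |correlation| with month/latitude/year regressors ≈ 10⁻³ in the test
   suite). A deterministic least-squares mode (`method="ols"`) is provided
   alongside the default Bayesian fit; at survey sample sizes the two
   agree to a few thousandths of a °C RMS, and the Bayesian posterior
   median is the default because it generalizes to small provinces where
   the flat-prior equivalence is less exact.
4. **Trend models** (`models`). Four responses (ln q, ln r, ln (q+r), h)
   under two variants: Time-Space-Temperature (anomaly covariate) and
   Time-Space (decade steps with an extended Bayesian LASSO prior).
5. **Diagnostics and reporting** (`diagnostics`, `report`). Posterior
   predictive checks, Bayesian R², leave-one-predictor-out importance,
   percent-per-year and compounded-change conversions, monthly
   climatologies and effect tables.

## Model and priors

For province A, band latitude l, month m, year y:

    y ~ Normal(μ, σ²_A)
    μ = θ_{m,A} + η_A (l − l̄_A) + γ_A (y − 1960) + [φ_A·sst | δ_{d,A}]

There is no global intercept: the twelve θ_{m,A} absorb each province's
mean, and identifiability comes from the hierarchical priors rather than
sum-to-zero constraints. l̄_A is the mean latitude of the *observed* bins
of province A (stored on the results object), and years are centered on
1960.

Priors: each effect family (θ, η, γ, φ, and the SST model's analogous
α, ρ, β) is exchangeable Normal(0, s²) across provinces (and months, for
θ) with s² ~ InvGamma(0.1, 0.1); province residual sds are Uniform(0, 10).
Decade steps take the extended Bayesian LASSO:

    δ_{d,A} ~ N(0, σ²_{A,δ}),   σ²_{A,δ} ~ Exp(rate = λ²_A/2),
    λ_A = λ·ξ_A,   λ ~ Gamma(1, 1),   ξ_A ~ Uniform(0, 2).

The exponential is parameterized by **rate** (prior mean 2/λ²_A); textbook
Bayesian-LASSO presentations differ on this convention, so it is fixed
here explicitly. The decade steps are nearly collinear with the linear
year term by construction; the shrinkage prior is what resolves that
competition, and replacing it with a flat prior on δ would reintroduce the
degeneracy.

## Sampler

All full conditionals are conjugate except three scalar families, so the
models are fitted with a purpose-built Gibbs sampler (`_gibbs`):

* effects and decade steps: Normal conditionals, updated blockwise with
  `bincount` accumulations (cost O(n) per family per sweep);
* hyper-variances: inverse-gamma conditionals;
* residual sds (Uniform(0, U) prior): truncated inverse-gamma, sampled by
  CDF inversion of the precision;
* σ²_{A,δ}: generalized inverse Gaussian, GIG(1 − D/2, Σδ², λ²_A), via
  `scipy.stats.geninvgauss`;
* ξ_A: the conditional of ξ² is Gamma(3/2, λ²σ²_{A,δ}/2) truncated to
  (0, 4), by CDF inversion;
* λ: log-density (2P)·log λ − λ − λ²Σ_A ξ²_Aσ²_{A,δ}/2, updated by
  univariate slice sampling.

With no data the same sweep samples the joint prior; the test suite
verifies the marginals (scaled-t for effects, Uniform for σ and ξ,
Gamma(1,1) for λ) by KS tests at α = 0.01.

The default protocol is 3 chains × 10,000 iterations, 4,000 burn-in,
thinning 10 (1,800 retained draws), matching classic BUGS-era practice.
This Gibbs sampler mixes well at a fraction of that: the tests and the
acceptance studies use 2 chains × 1,500 iterations (burn-in 500, thinning
2) on fits of ~3,000–10,000 bins, where R-hat < 1.05 and ESS > 100 are
routinely achieved in a few seconds. Convergence is assessed
quantitatively — split-chain R-hat below 1.05 and ESS above 100 per
parameter family (configurable) — and a failing fit carries
`converged=False` plus a `ConvergenceWarning` rather than an exception,
so flagged-but-usable posteriors remain inspectable. Decade-step fits
show the slowest mixing (R-hat ≈ 1.1 at short chain lengths) precisely
because of the trend-step collinearity.

## Diagnostics

**Posterior predictive checks** draw `n_rep` (default 100) replicate
datasets y* ~ Normal(μ⁽ʲ⁾, σ⁽ʲ⁾²) at the observed design points, one
posterior draw j per replicate, and report the Bayesian p-value
P(T(y*) ≥ T(y)) for T ∈ {mean, variance}, pooled by default with a
per-province option. Values outside [0.25, 0.75] are flagged as potential
misfit; the calibration tests require (0.05, 0.95) and the fourfold
variance-inflation probe drives the variance p-value to ≈ 0.

**Bayesian R²** is the draws-based definition: per posterior draw,
var(μ)/(var(μ) + σ²_pooled), with province residual variances pooled by
observation count, summarized by the posterior median. This is the
Gelman-style fitted-variance formulation, chosen because it is
well-defined per draw and monotone in the signal-to-noise ratio.

**Variable importance** refits the model with one predictor neutralized —
months collapsed to a single province intercept, latitude centered away,
anomaly zeroed — and reports ΔR² against the full fit with the same MCMC
configuration. Neutralizing rather than restructuring keeps the parameter
count and priors comparable across refits.

## Synthetic data

`GenerativeParams` defines the simulated study: five provinces
(ARCT/SARC/NWCS/NADR/NECS as categorical labels with declared latitude
spans mimicking their real extents — no polygon geometry, since the
models use only the label and latitude), monthly sampling 1960–2017,
2.5° bands. Defaults encode: diatom seasonal peak in May and
dinoflagellate in July (near-flat dino cycle in NWCS); index trends of
−0.8%/yr in ARCT and +0.8 to +2.4%/yr elsewhere, from group trends of
−0.8 to +2%/yr (diatoms) and −2 to +1.2%/yr (dinoflagellates); weak
latitudinal gradients (diatoms relatively favored northward in SARC/NADR,
dinoflagellates in NWCS), sized so latitude explains ~1–2% of response
variance; positive anomaly effects on both groups (dinoflagellate
response larger except in NWCS, making the index anomaly effect ≈ −0.15
elsewhere and ≈ −0.02 there); SST with a winter-low/August-high seasonal
cycle, −0.3 °C/°lat gradient, +0.015 °C/yr warming and 1 °C residual sd.
Group log-residual sds are 0.8 with a within-bin cross-group correlation
of 0.45 representing shared tow-level variability (filtered volume, ship
speed) — the same mechanism that makes the biomass *ratio* robust to
ship-speed drift. Under these defaults the full-model Bayesian R² falls
in the 32–64% band for all four responses and the logit index is
approximately Normal in every province.

Zeros are generated as **detection-limit censoring**: per group and
province, the configured zero fraction (5% diatoms; 22–27%
dinoflagellates, averaging 24% and concentrated in the two northernmost
provinces) of lowest-biomass cells is recorded as absent. Censoring
rather than independent Bernoulli thinning matters: it keeps the
half-minimum imputation floor close to the censored truth, as in a real
survey where zeros mean "below the minimum detectable biomass". Cells
losing both groups are dropped entirely. Dinoflagellate province bases
are kept within ~0.7 natural-log units so that detection thresholds are
commensurable across provinces (one instrument-wide floor); province
contrasts ride mainly on the diatom-minus-dinoflagellate difference.

Abundance records realize the binned truth: each surviving cell becomes
one sample at the band center, its group biomass partitioned across the
group's known-volume taxa with symmetric Dirichlet(1) weights (the
within-group abundance distribution is a stand-in choice — maximally
uninformative — not an empirical claim), and divided by per-cell carbon
so the downstream sum reconstructs the cell biomass exactly. Abundances
are unitless "abundance units" proportional to cell density, as recorder
data are conventionally treated.

What the generator does **not** emulate: ship-track geometry and route
drift, effort changes over time, within-cell spatial heterogeneity,
taxonomic misidentification, autocorrelated (e.g. bloom-driven) residuals,
and real Longhurst polygon shapes. Passing recovery tests therefore show
that the estimation machinery is correct under the stated model, not that
the model is adequate for any particular real dataset.

## Numerical choices and edge cases

* Quantiles (2.5/17/50/83/97.5%) are exact sample quantiles of the
  retained draws; 66% and 95% intervals come from the same grid.
* Percent conversions use the exact exponential form 100·(e^γ − 1); the
  common 100·γ approximation agrees to printed precision for |γ| ≤ 0.03
  and is noted, not used.
* `logit` rejects arguments outside the open unit interval; bins must be
  imputation-complete before modeling (the model constructor checks for
  non-finite responses).
* Degenerate designs (single year, single band per province, all-zero
  group) are rejected with explicit errors rather than fitted.
* Truncated-gamma CDF inversions guard against ppf overflow with a
  mode-based fallback; the GIG χ parameter is floored at 10⁻¹² when all
  decade steps are near zero.
* RNG streams: every simulator derives an independent `SeedSequence`
  child from the user seed, so the same seed can safely drive the SST
  field, the biomass field and the taxon partition without inducing
  spurious cross-correlations.

## Problem sizes used in tests and acceptance studies

Unit and acceptance fits use 30–40 simulated years over the five
provinces (≈ 3,000–11,000 bins or SST records) with the reduced MCMC
protocol above; the credible-interval coverage study runs 20 independent
seeds of a 5-province × 4-band × 12-month × 40-year design (9,600 cells,
75 parameters checked per seed). These sizes give stable interval
estimates while keeping a full validation run in the minutes range on a
single CPU.

## Known limitations

* The sampler is single-threaded; very long chains on very large bin
  tables scale linearly.
* The decade-step and trend terms remain weakly identified jointly — by
  design — so decade-effect posteriors should be read as shrinkage
  estimates, not unconstrained decade means.
* The anomaly is a posterior summary (median) plugged into the biomass
  models, not jointly sampled; uncertainty in the anomaly itself is not
  propagated (this matches the two-stage construction the models are
  defined with).
* Total biomass ln(q+r) is modeled on imputation-completed bins; no
  separate floor is derived for the sum.
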
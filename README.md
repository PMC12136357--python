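# cprtrends

Hierarchical Bayesian trend analysis of diatom and dinoflagellate carbon
biomass in plankton-recorder-style survey data.

## The problem

Multi-decadal plankton surveys (towed silk-mesh recorders) yield
semi-quantitative taxon abundance counts across ocean basins. Turning those
counts into a defensible statement like *"the diatom share of diatom +
dinoflagellate biomass has risen 1–2% per year in this province"* requires a
chain of steps, each with pitfalls: allometric conversion of counts to carbon
biomass, spatio-temporal aggregation that tames the many zero observations,
construction of a temperature covariate that is orthogonal to the space-time
structure already in the model, and a hierarchical model that separates
seasonal cycles, latitudinal gradients, decadal steps and long-term trends.
`cprtrends` implements that whole chain as a tested library with a
synthetic-data generator, so every stage can be validated against known
ground truth without access to restricted survey archives.

It is aimed at quantitative plankton ecologists and biostatisticians who
want either the full pipeline or individual, well-tested pieces (the
allometric conversion, the binning/imputation rules, the Gibbs sampler for
the hierarchical model, the posterior predictive machinery).

## The model

Let q and r be diatom and dinoflagellate carbon biomass (µg C) aggregated
into province × 2.5°-latitude-band × month × year bins, and
h = logit(q/(q+r)) the log-odds diatom index. Each response
y ∈ {ln q, ln r, ln(q+r), h} is modeled as Normal with variance σ²_A and
mean, for province A, band latitude l, month m, year y:

**Time-Space-Temperature:**
μ = θ_{m,A} + η_A (l − l̄_A) + γ_A (y − 1960) + φ_A · sst_{A,l,m,y}

**Time-Space:**
μ = θ_{m,A} + η_A (l − l̄_A) + γ_A (y − 1960) + δ_{d,A}

where θ_{m,A} are month effects (absorbing province means), η_A a
latitudinal gradient, γ_A the interannual trend, φ_A the effect of the SST
anomaly, and δ_{d,A} decade steps. The SST anomaly is the posterior median
residual of the same decomposition applied to observed SST (month +
latitude + trend), which makes it empirically orthogonal to the other
predictors. Priors are exchangeable Normals with InvGamma(0.1, 0.1)
hyper-variances, Uniform(0, 10) residual sds, and — because decade steps
are nearly collinear with the linear trend — an extended Bayesian LASSO on
δ_{d,A}: δ_{d,A} ~ N(0, σ²_{A,δ}), σ²_{A,δ} ~ Exp(rate = λ²_A/2),
λ_A = λ·ξ_A, λ ~ Gamma(1,1), ξ_A ~ Uniform(0,2). Sampling is by a
conjugate Gibbs sampler written for exactly this structure (see
`docs/methods.md`); convergence is summarized with split-chain R-hat and
effective sample size via `arviz`.

A trend γ maps to percent change per year as 100·(e^γ − 1), and an annual
rate compounds over an n-year horizon as 100·((1 + rate/100)ⁿ − 1) — so
+1%/yr ≈ +82% and +2%/yr ≈ +228% over 60 years.

## Worked example

```python
import cprtrends as ct

params = ct.GenerativeParams(years=(1978, 2007))   # synthetic study conditions
sst = ct.simulate_sst(params, seed=42)
bins = ct.impute_zeros(ct.simulate_bins(params, sst, seed=42))

cfg = ct.ModelConfig(chains=3, iterations=4000, burn_in=1000, thinning=5, seed=42)
anom = ct.fit_sst_model(sst, cfg).anomalies()

model = ct.PlanktonTrendModel(bins, response="logit_index",
                              variant="time-space-temperature", anomalies=anom)
res = model.fit(cfg)
print(res.summary())
```

```
Plankton trend model
================================================================
response:  logit_index              variant: time-space-temperature
bins:      8022                     provinces: 5
chains:    3  iterations: 4000  burn-in: 1000  thin: 5
retained draws: 1800   converged: True
----------------------------------------------------------------
effect    province      median      2.5%     97.5%
trend     ARCT         -0.0049   -0.0096    0.0000
trend     NADR          0.0154    0.0103    0.0202
trend     NECS          0.0181    0.0129    0.0232
trend     NWCS         -0.0026   -0.0097    0.0047
trend     SARC          0.0153    0.0110    0.0197
...
```

The trend rows are the headline numbers: e.g. the NECS diatom index rises
at median slope 0.018/yr ≈ +1.8%/yr. Converting and compounding:

```python
rep = res.trend_report(horizon_years=60)
print(rep[["province", "slope_median", "pct_per_yr", "compounded_pct"]].round(3))
```

```
province  slope_median  pct_per_yr  compounded_pct
    ARCT        -0.005      -0.493         -25.647
    NADR         0.015       1.554         152.303
    NECS         0.018       1.825         195.984
    NWCS        -0.003      -0.262         -14.573
    SARC         0.015       1.537         149.734
```

`compounded_pct` is the total percent change implied by 60 years at that
annual rate. Fit quality:

```python
print("Bayesian R2:", round(res.bayesian_r2(), 3))        # 0.412
print(res.posterior_predictive_check("variance", seed=42).p_value)  # 0.59
```

An R² of 0.41 (41% of variance explained) and a posterior predictive
p-value near 0.5 indicate the model reproduces the observed variance well.
These estimates recover the generator's truth: the index trend was
simulated positive (+1.2 to +2.4%/yr) everywhere except ARCT and NWCS-adjacent
values, and the anomaly effect negative (warm anomalies favor
dinoflagellates) in all provinces, weakest in NWCS.

## Command line

The same pipeline is scriptable:

```sh
cprtrends simulate --seed 1 --outdir sim
cprtrends prepare  --indir sim --outdir prep --sst-method bayes
cprtrends fit      --indir prep --outdir fit --response logit_index
cprtrends check    --fitdir fit --outdir check
cprtrends report   --fitdir fit --outdir report
```

Each command reads/writes plain CSV/YAML artifacts (documented columns:
bins.csv has `province, lat_band, year, month, decade, diatom_ugC,
dinoflagellate_ugC, diatom_imputed, dinoflagellate_imputed, p, h`);
`truth.yaml` records the generator's parameters for recovery checks.

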
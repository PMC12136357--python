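"""Simulation studies validating the estimation machinery.

Each study simulates data with known generative truth, runs the relevant
pipeline stage, and returns summary metrics.  They are used both by the
test suite and by ``scripts/acceptance.py``; all randomness is derived
from the caller's seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import impute_zeros
from .diagnostics import posterior_predictive_check
from .models import ModelConfig, PlanktonTrendModel
from .sst import SSTAnomalyModel
from .synthetic import GenerativeParams, simulate_bins, simulate_sst

#: reduced-draw MCMC protocol used by the studies (the Gibbs sampler
#: mixes fast enough that 2 x 1500 iterations give stable 95% intervals)
STUDY_CONFIG = dict(chains=2, iterations=1500, burn_in=500, thinning=2)


def _study_params(n_bands: int = 4, years=(1960, 1999),
                  zero_inflation: float = 0.0) -> GenerativeParams:
    """Clean-simulation conditions: 5 provinces x `n_bands` bands, no zeros."""
    p = GenerativeParams(years=years)
    width = 2.5 * n_bands
    p.lat_ranges = {"ARCT": (60.0, 60.0 + width), "SARC": (55.0, 55.0 + width),
                    "NWCS": (37.5, 37.5 + width), "NADR": (42.5, 42.5 + width),
                    "NECS": (47.5, 47.5 + width)}
    for g in p.zero_inflation:
        p.zero_inflation[g] = {pr: zero_inflation for pr in p.provinces}
    return p


def _clean_bins(p: GenerativeParams, seed: int):
    sst = simulate_sst(p, seed)
    bins = impute_zeros(simulate_bins(p, sst, seed))
    anoms = sst[["province", "lat_band", "year", "month"]].copy()
    anoms["anomaly"] = sst["anomaly_true"].to_numpy()
    return bins, anoms


def recovery_study(seed: int, n_seeds: int = 20,
                   response: str = "log_diatom") -> dict:
    """95% credible-interval coverage of (theta, eta, gamma, phi) truth.

    Simulates the temperature-variant model over 5 provinces x 4 bands x
    12 months x 40 years per seed, fits it, and counts how often each
    parameter's 95% CI covers its generating value.
    """
    group = {"log_diatom": "diatom",
             "log_dinoflagellate": "dinoflagellate"}[response]
    p = _study_params()
    covered = total = 0
    for k in range(n_seeds):
        s = int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2 ** 31))
        bins, anoms = _clean_bins(p, s)
        cfg = ModelConfig(seed=s, **STUDY_CONFIG)
        res = PlanktonTrendModel(bins, response=response,
                                 variant="time-space-temperature",
                                 anomalies=anoms).fit(cfg)
        provs = res.model.provinces
        for name, truth_of in (
                ("theta", lambda pr: np.asarray(p.month_effects[group][pr], float)),
                ("eta", lambda pr: p.lat_gradient[group][pr]),
                ("gamma", lambda pr: p.trend[group][pr]),
                ("phi", lambda pr: p.anomaly_effect[group][pr])):
            d = res.stacked(name)
            lo = np.quantile(d, 0.025, axis=0)
            hi = np.quantile(d, 0.975, axis=0)
            for i, pr in enumerate(provs):
                t = np.atleast_1d(truth_of(pr))
                l = np.atleast_1d(lo[i])
                h = np.atleast_1d(hi[i])
                covered += int(np.sum((l <= t) & (t <= h)))
                total += t.size
    return {"coverage_pct": 100.0 * covered / total, "n_intervals": total}


def lasso_study(seed: int) -> dict:
    """Decade-effect behavior of the extended Bayesian LASSO prior.

    Fit 1: all true decade steps are 0 -> fraction of decade-effect 95%
    CIs containing 0.  Fit 2: one step of +0.5 injected -> is it the
    largest-|posterior median| decade effect, and by what ratio?
    """
    p = _study_params()
    bins, _ = _clean_bins(p, int(np.random.SeedSequence([int(seed), 101])
                                 .generate_state(1)[0] % (2 ** 31)))
    cfg = ModelConfig(seed=seed, **STUDY_CONFIG)
    res0 = PlanktonTrendModel(bins, response="log_diatom",
                              variant="time-space").fit(cfg)
    d = res0.stacked("delta")
    lo = np.quantile(d, 0.025, axis=0)
    hi = np.quantile(d, 0.975, axis=0)
    cover0 = float(np.mean((lo <= 0) & (0 <= hi)) * 100.0)

    p2 = _study_params()
    inj_prov, inj_dec = "NADR", 2  # the 1980s
    p2.decade_effects["diatom"][inj_prov][inj_dec] = 0.5
    bins2, _ = _clean_bins(p2, int(np.random.SeedSequence([int(seed), 102])
                                   .generate_state(1)[0] % (2 ** 31)))
    res1 = PlanktonTrendModel(bins2, response="log_diatom",
                              variant="time-space").fit(cfg)
    med = np.median(res1.stacked("delta"), axis=0)
    provs = res1.model.provinces
    flat = np.abs(med).ravel()
    winner = int(np.argmax(flat))
    inj_idx = provs.index(inj_prov) * med.shape[1] + inj_dec
    others = np.delete(flat, inj_idx)
    return {"null_delta_ci95_coverage_pct": cover0,
            "injected_step_is_largest": float(winner == inj_idx),
            "injected_step_median": float(med.ravel()[inj_idx]),
            "shrinkage_ratio": float(flat[inj_idx] / max(others.max(), 1e-12)),
            "n_decade_effects": int(flat.size)}


def ppc_study(seed: int) -> dict:
    """PPC calibration on well-specified synthetic data, plus misfit power.

    Fits the logit-index temperature model to default-condition synthetic
    data; mean/variance p-values should be moderate.  Inflating the
    observed variance fourfold (y -> mean + 2(y-mean)) must drive the
    variance p-value toward 0.
    """
    p = GenerativeParams(years=(1978, 2007))
    s = int(np.random.SeedSequence([int(seed), 201]).generate_state(1)[0] % (2 ** 31))
    bins, anoms = _clean_bins(p, s)
    cfg = ModelConfig(seed=seed, **STUDY_CONFIG)
    res = PlanktonTrendModel(bins, response="logit_index",
                             variant="time-space-temperature",
                             anomalies=anoms).fit(cfg)
    p_mean = posterior_predictive_check(res, "mean", seed=seed).p_value
    p_var = posterior_predictive_check(res, "variance", seed=seed).p_value
    y = res.model._y
    inflated = y.mean() + 2.0 * (y - y.mean())
    p_var_inflated = posterior_predictive_check(
        res, "variance", seed=seed, observed=inflated).p_value
    return {"ppc_mean_pvalue": p_mean, "ppc_variance_pvalue": p_var,
            "ppc_inflated_variance_pvalue": p_var_inflated,
            "bayesian_r2_logit_index": res.bayesian_r2(),
            "n_bins": len(bins)}


def anomaly_study(seed: int, years=(1960, 1999)) -> dict:
    """Orthogonality of fitted anomalies and fast-vs-Bayes agreement.

    Fits the SST decomposition both ways on one default-condition grid
    (> 5,000 records): reports the largest |correlation| of the Bayesian
    anomaly with month indicators, latitude and year, and the RMS
    difference between Bayesian and least-squares anomalies (°C).
    """
    p = GenerativeParams(years=years)
    s = int(np.random.SeedSequence([int(seed), 301]).generate_state(1)[0] % (2 ** 31))
    sst = simulate_sst(p, s)
    cfg = ModelConfig(seed=seed, **STUDY_CONFIG)
    model = SSTAnomalyModel(sst)
    bayes = model.fit(cfg, method="bayes")
    ols = model.fit(cfg, method="ols")
    a = bayes.anomalies()["anomaly"].to_numpy()
    corrs = []
    for mth in range(1, 13):
        corrs.append(np.corrcoef(a, (sst["month"] == mth).to_numpy(float))[0, 1])
    corrs.append(np.corrcoef(a, sst["lat_band"].to_numpy(float))[0, 1])
    corrs.append(np.corrcoef(a, sst["year"].to_numpy(float))[0, 1])
    rms = float(np.sqrt(np.mean((a - ols.anomalies()["anomaly"].to_numpy()) ** 2)))
    return {"anomaly_abs_corr_max": float(np.max(np.abs(corrs))),
            "fast_vs_bayes_rms_C": rms,
            "n_records": len(sst)}
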
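"""Posterior predictive checks, Bayesian R² and variable importance.

The PPC follows the standard recipe: replicate datasets are drawn from
Normal(mu, sigma²) at the observed design points, one posterior draw per
replicate, and a Bayesian p-value is the fraction of replicate test
statistics at or above the observed one (P(T_rep >= T_obs)).  Values
near 0 or 1 flag misfit; the conventional comfort band is 0.25-0.75.

Bayesian R² is the draws-based definition (Gelman et al. style): per
posterior draw, var(fitted) / (var(fitted) + pooled residual variance),
summarized by the posterior median.  Pooling weights each province's
residual variance by its observation count.

Variable importance is leave-one-predictor-out: refit with the predictor
neutralized (month collapsed to a province intercept, latitude centered
away, anomaly zeroed) and report the drop in R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelConfig, PlanktonTrendModel, TrendResults

STATISTICS = {
    "mean": lambda x: np.mean(x),
    "variance": lambda x: np.var(x, ddof=1),
}


@dataclass
class PPCSummary:
    statistic: str
    observed: float
    replicates: np.ndarray
    p_value: float

    def misfit_flag(self, band=(0.25, 0.75)) -> bool:
        return not (band[0] <= self.p_value <= band[1])


def posterior_predictive_check(results: TrendResults, statistic: str = "mean",
                               n_rep: int = 100, seed: int = 0,
                               per_province: bool = False,
                               observed: np.ndarray | None = None):
    """PPC for one test statistic; pooled by default.

    `observed` overrides the observed response vector (used to probe
    sensitivity, e.g. inflating the variance post hoc).  With
    ``per_province`` a DataFrame of per-province summaries is returned.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(STATISTICS)}")
    if n_rep < 10:
        raise ValueError("n_rep must be >= 10 for a stable p-value")
    stat = STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    total = results.n_draws
    sel = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    mu = results.mu_draws(sel)
    sig = results.sigma_by_obs(sel)
    reps = mu + rng.standard_normal(mu.shape) * sig
    y = results.model._y if observed is None else np.asarray(observed, float)
    if not per_province:
        t_obs = stat(y)
        t_rep = np.array([stat(reps[j]) for j in range(reps.shape[0])])
        p = float(np.mean(t_rep >= t_obs))
        return PPCSummary(statistic, float(t_obs), t_rep, p)
    rows = []
    a = results.model._gibbs_data().province_idx
    for i, prov in enumerate(results.model.provinces):
        m = a == i
        t_obs = stat(y[m])
        t_rep = np.array([stat(reps[j, m]) for j in range(reps.shape[0])])
        rows.append({"province": prov, "statistic": statistic,
                     "observed": t_obs,
                     "p_value": float(np.mean(t_rep >= t_obs))})
    return pd.DataFrame(rows)


def bayesian_r2(results: TrendResults) -> float:
    """Posterior median of var(mu) / (var(mu) + pooled sigma²)."""
    if len(results.model.bins) < 2:
        raise ValueError("Bayesian R² needs at least 2 bins")
    mu = results.mu_draws()
    a = results.model._gibbs_data().province_idx
    n_a = np.bincount(a, minlength=len(results.model.provinces))
    sigma2 = results.stacked("sigma") ** 2
    pooled = sigma2 @ n_a / n_a.sum()
    var_mu = np.var(mu, axis=1, ddof=1)
    r2 = var_mu / (var_mu + pooled)
    return float(np.median(r2))


def _neutralize(bins: pd.DataFrame, anomaly_vec: np.ndarray,
                predictor: str):
    """Return (bins, anomaly vector) with one predictor carrying no signal."""
    b = bins.copy()
    a = anomaly_vec.copy()
    if predictor == "month":
        b["month"] = 1  # collapses the 12 effects to a province intercept
    elif predictor == "latitude":
        b["lat_band"] = b.groupby("province")["lat_band"].transform("mean")
    elif predictor == "anomaly":
        a = np.zeros_like(a)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    return b, a


def variable_importance(bins: pd.DataFrame, anomalies: pd.DataFrame,
                        config: ModelConfig | None = None,
                        response: str = "logit_index",
                        predictors=("month", "latitude", "anomaly"),
                        variant: str = "time-space-temperature") -> pd.DataFrame:
    """Leave-one-predictor-out ΔR² table.

    Fits the full model and one refit per omitted predictor with the same
    MCMC configuration; ΔR² = R²(full) − R²(without predictor).
    """
    from .aggregate import BIN_KEY
    config = config or ModelConfig()
    merged = bins.merge(anomalies[BIN_KEY + ["anomaly"]], on=BIN_KEY,
                        how="left", validate="1:1")
    if merged["anomaly"].isna().any():
        raise ValueError("anomalies do not cover all bins")
    anom_vec = merged["anomaly"].to_numpy(float)
    base = merged.drop(columns="anomaly")

    def _fit(b, a):
        return PlanktonTrendModel(b, response=response, variant=variant,
                                  anomalies=a).fit(config)

    r2_full = bayesian_r2(_fit(base, anom_vec))
    rows = [{"predictor": "(full model)", "r2": r2_full, "delta_r2": 0.0}]
    for pred in predictors:
        b, a = _neutralize(base, anom_vec, pred)
        r2 = bayesian_r2(_fit(b, a))
        rows.append({"predictor": pred, "r2": r2, "delta_r2": r2_full - r2})
    return pd.DataFrame(rows)


def plot_ppc(summary: PPCSummary, path=None):
    """Histogram of replicate statistics with the observed value marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(summary.replicates, bins=20, color="#7a9cc6", edgecolor="white")
    ax.axvline(summary.observed, color="k", lw=2)
    ax.set_xlabel(f"replicate {summary.statistic}")
    ax.set_title(f"Bayesian p = {summary.p_value:.2f}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
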
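"""Bayesian decomposition of sea-surface temperature into structure + anomaly.

Observed monthly SST per province/latitude-band is modeled as Normal with
mean = month effect + latitudinal gradient * (lat - province mean lat) +
interannual trend * (year - 1960); the residual is the *temperature
anomaly*, the covariate fed to the Time-Space-Temperature biomass models.
By construction the anomaly is orthogonal to month, latitude and year, so
it can enter those models without inducing collinearity.

Two fitting modes:

* ``bayes`` (default): the full hierarchical model — exchangeable Normal
  priors on month effects, gradients and trends with InvGamma(0.1, 0.1)
  hyper-variances, Uniform(0, 10) on the residual sds — sampled by Gibbs;
  the anomaly is the posterior median of the per-record residual.
* ``ols``: per-province least squares on the same design; the anomaly is
  the plain residual.  At these sample sizes the two agree closely and
  the fast mode is useful for exploratory runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._gibbs import GibbsData, run_chains
from .aggregate import BIN_KEY
from .models import ModelConfig, YEAR_ZERO, _convergence_table


class SSTAnomalyModel:
    """SST decomposition over records with columns
    ``province``, ``lat_band``, ``year``, ``month``, ``sst``."""

    def __init__(self, records: pd.DataFrame):
        req = {"province", "lat_band", "year", "month", "sst"}
        missing = req - set(records.columns)
        if missing:
            raise ValueError(f"SST records missing columns {sorted(missing)}")
        if not np.all(np.isfinite(records["sst"])):
            raise ValueError("SST values must be finite")
        if not records["month"].between(1, 12).all():
            raise ValueError("month must be in 1..12")
        self.records = records.reset_index(drop=True)
        for prov, sub in self.records.groupby("province"):
            if sub["year"].nunique() < 2 or sub["lat_band"].nunique() < 2:
                raise ValueError(
                    f"degenerate design for province {prov}: need >= 2 years "
                    "and >= 2 latitude bands")
        self.provinces = sorted(self.records["province"].unique())
        self._prov_idx = {p: i for i, p in enumerate(self.provinces)}
        self.mean_latitude = (self.records.groupby("province")["lat_band"]
                              .mean().to_dict())

    def _design(self) -> GibbsData:
        df = self.records
        a = df["province"].map(self._prov_idx).to_numpy()
        lat_c = (df["lat_band"].to_numpy(float)
                 - df["province"].map(self.mean_latitude).to_numpy(float))
        return GibbsData(
            y=df["sst"].to_numpy(float), province_idx=a,
            month_idx=df["month"].to_numpy(int) - 1, lat_c=lat_c,
            year_c=df["year"].to_numpy(float) - YEAR_ZERO,
            n_provinces=len(self.provinces))

    def fit(self, config: ModelConfig | None = None,
            method: str = "bayes") -> "SSTAnomalyResults":
        config = config or ModelConfig()
        data = self._design()
        if method == "bayes":
            draws = run_chains(data, config.priors(), config.iterations,
                               config.burn_in, config.thinning, config.seed,
                               config.chains, keep_residuals=True)
            return SSTAnomalyResults(self, config, draws, method)
        if method == "ols":
            return SSTAnomalyResults(self, config, self._fit_ols(data), "ols")
        raise ValueError("method must be 'bayes' or 'ols'")

    def _fit_ols(self, data: GibbsData) -> dict:
        P = len(self.provinces)
        theta = np.zeros((P, 12))
        eta = np.zeros(P)
        gamma = np.zeros(P)
        sigma = np.zeros(P)
        resid = np.zeros(len(data.y))
        for p in range(P):
            sel = data.province_idx == p
            months = data.month_idx[sel]
            X = np.zeros((sel.sum(), 14))
            X[np.arange(sel.sum()), months] = 1.0
            X[:, 12] = data.lat_c[sel]
            X[:, 13] = data.year_c[sel]
            beta, *_ = np.linalg.lstsq(X, data.y[sel], rcond=None)
            r = data.y[sel] - X @ beta
            theta[p] = beta[:12]
            eta[p] = beta[12]
            gamma[p] = beta[13]
            dof = max(sel.sum() - 14, 1)
            sigma[p] = np.sqrt(np.sum(r ** 2) / dof)
            resid[sel] = r
        # single deterministic "draw", shaped like one chain of one draw
        return {"theta": theta[None, None], "eta": eta[None, None],
                "gamma": gamma[None, None], "sigma": sigma[None, None],
                "resid": resid[None, None]}


class SSTAnomalyResults:
    """Posterior (or least-squares) SST decomposition.

    Parameter naming follows the shared sampler: ``theta`` are the month
    effects (alpha in the temperature context), ``eta`` the latitudinal
    gradient (rho), ``gamma`` the warming trend (beta), ``sigma`` the
    residual sd.
    """

    def __init__(self, model: SSTAnomalyModel, config: ModelConfig,
                 draws: dict, method: str):
        self.model = model
        self.config = config
        self.draws = draws
        self.method = method
        self.convergence = None
        self.converged = None
        if method == "bayes":
            self.convergence = _convergence_table(draws)
            self.converged = bool(
                (self.convergence["rhat_max"] <= config.rhat_max).all()
                and (self.convergence["ess_min"] >= config.ess_min).all())

    def stacked(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def param_summary(self) -> pd.DataFrame:
        """Median and 95% CI of trend, gradient and residual sd per province."""
        rows = []
        for name, label in (("gamma", "trend_C_per_yr"),
                            ("eta", "gradient_C_per_deglat"),
                            ("sigma", "resid_sd_C")):
            d = self.stacked(name)
            qs = np.quantile(d, [0.025, 0.5, 0.975], axis=0)
            for i, prov in enumerate(self.model.provinces):
                rows.append({"province": prov, "parameter": label,
                             "median": qs[1, i], "q2.5": qs[0, i],
                             "q97.5": qs[2, i]})
        return pd.DataFrame(rows)

    def anomalies(self) -> pd.DataFrame:
        """Per-record anomaly: posterior median residual (or OLS residual)."""
        resid = self.stacked("resid")
        anom = np.median(resid, axis=0)
        out = self.model.records[BIN_KEY].copy()
        out["anomaly"] = anom
        return out

    def summary(self) -> str:
        lines = [
            "SST anomaly model",
            "=" * 56,
            f"records: {len(self.model.records)}  provinces: "
            f"{len(self.model.provinces)}  method: {self.method}",
            f"converged: {self.converged}",
            "-" * 56,
            f"{'province':<10s}{'trend °C/yr':>14s}{'grad °C/°lat':>14s}"
            f"{'resid sd °C':>14s}",
        ]
        g = np.median(self.stacked("gamma"), axis=0)
        e = np.median(self.stacked("eta"), axis=0)
        s = np.median(self.stacked("sigma"), axis=0)
        for i, prov in enumerate(self.model.provinces):
            lines.append(f"{prov:<10s}{g[i]:>14.4f}{e[i]:>14.4f}{s[i]:>14.4f}")
        return "\n".join(lines)


def fit_sst_model(records: pd.DataFrame, config: ModelConfig | None = None,
                  method: str = "bayes") -> SSTAnomalyResults:
    """Convenience wrapper: build and fit :class:`SSTAnomalyModel`."""
    return SSTAnomalyModel(records).fit(config=config, method=method)


def compute_anomaly(records: pd.DataFrame,
                    results: SSTAnomalyResults) -> pd.DataFrame:
    """Anomaly table for `records` from a fitted decomposition.

    `records` must be the same table the model was fitted on (the anomaly
    is a per-record posterior quantity, not a prediction rule).
    """
    if len(records) != len(results.model.records) or not (
            records[BIN_KEY].reset_index(drop=True)
            .equals(results.model.records[BIN_KEY])):
        raise ValueError("records do not match the fitted model's records")
    return results.anomalies()
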
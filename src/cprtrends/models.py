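"""Hierarchical Bayesian trend models for binned biomass responses.

:class:`PlanktonTrendModel` fits one of four responses — log diatom
biomass, log dinoflagellate biomass, log total biomass, or the logit
diatom index — as Normal with mean

    mu = theta_{m,A} + eta_A (l - lbar_A) + gamma_A (y - 1960) + ...

where the tail term is phi_A * anomaly for the Time-Space-Temperature
variant or a decade step delta_{d,A} for the Time-Space variant.  Month
effects absorb the province means (no global intercept); latitude is
centered on the observed province mean; year on 1960.

Priors: exchangeable N(0, s2) on each effect family with InvGamma(0.1,
0.1) hyper-variances, Uniform(0, 10) on the province residual sds, and
for the decade steps an extended Bayesian LASSO: delta_{d,A} ~ N(0,
s2_{A,delta}), s2_{A,delta} ~ Exp(rate = lambda_A^2/2), lambda_A =
lambda * xi_A, lambda ~ Gamma(1,1), xi_A ~ Uniform(0,2).  Note the
exponential is parameterized by rate (prior mean 2/lambda_A^2); textbook
Bayesian-LASSO conventions differ on this point.

The default MCMC protocol is 3 chains of 10,000 iterations, 4,000
burn-in, thinning 10; the Gibbs sampler used here typically mixes well
at considerably smaller draw counts, which tests and examples use.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._gibbs import GibbsData, GibbsPriors, run_chains
from .aggregate import BIN_KEY

YEAR_ZERO = 1960

RESPONSES = {
    "log_diatom": lambda b: np.log(b["diatom_ugC"].to_numpy()),
    "log_dinoflagellate": lambda b: np.log(b["dinoflagellate_ugC"].to_numpy()),
    "log_total": lambda b: np.log(b["diatom_ugC"].to_numpy()
                                  + b["dinoflagellate_ugC"].to_numpy()),
    "logit_index": lambda b: b["h"].to_numpy(),
}

VARIANTS = ("time-space-temperature", "time-space")


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ModelConfig:
    """MCMC and prior configuration.

    Defaults reproduce the reference protocol (3 chains x 10,000
    iterations, 4,000 burn-in, thinning 10 -> 1,800 retained draws) and
    the full prior specification; `rhat_max`/`ess_min` set the
    convergence flags attached to every fit.
    """

    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 4_000
    thinning: int = 10
    ig_shape: float = 0.1
    ig_rate: float = 0.1
    sigma_upper: float = 10.0
    lasso_lambda_shape: float = 1.0
    lasso_lambda_rate: float = 1.0
    xi_upper: float = 2.0
    rhat_max: float = 1.05
    ess_min: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        for name in ("ig_shape", "ig_rate", "sigma_upper",
                     "lasso_lambda_shape", "lasso_lambda_rate", "xi_upper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_draws(self) -> int:
        return self.chains * ((self.iterations - self.burn_in) // self.thinning)

    def priors(self) -> GibbsPriors:
        return GibbsPriors(self.ig_shape, self.ig_rate, self.sigma_upper,
                           self.lasso_lambda_shape, self.lasso_lambda_rate,
                           self.xi_upper)

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    #: a light protocol for unit-scale problems
    @classmethod
    def fast(cls, seed: int = 0) -> "ModelConfig":
        return cls(chains=2, iterations=1500, burn_in=500, thinning=2, seed=seed)


def linear_predictor(params: dict, bin_row, anomaly: float | None = None,
                     year_zero: int = YEAR_ZERO) -> float:
    """Evaluate the model mean for one bin under explicit parameter values.

    `params` holds ``month_effects`` (12 values), ``lat_gradient``,
    ``trend``, ``mean_latitude`` and optionally ``anomaly_effect`` (the
    temperature variant; `anomaly` must then be given) or
    ``decade_effects`` plus ``decades`` (the decade-step variant).
    `bin_row` is any mapping with ``month``, ``lat_band``, ``year`` (and
    ``decade`` when decade effects are present).
    """
    mu = (np.asarray(params["month_effects"], float)[int(bin_row["month"]) - 1]
          + params["lat_gradient"] * (bin_row["lat_band"] - params["mean_latitude"])
          + params["trend"] * (bin_row["year"] - year_zero))
    if "anomaly_effect" in params and params["anomaly_effect"] is not None:
        if anomaly is None:
            raise ValueError("temperature variant requires an anomaly value")
        mu += params["anomaly_effect"] * anomaly
    if "decade_effects" in params and params["decade_effects"] is not None:
        decades = list(params["decades"])
        mu += np.asarray(params["decade_effects"], float)[
            decades.index(int(bin_row["decade"]))]
    return float(mu)


class PlanktonTrendModel:
    """Trend model for one response over binned biomass data.

    Parameters
    ----------
    bins : DataFrame
        Imputation-complete bin table (see
        :func:`cprtrends.aggregate.prepare_bins`): columns ``province``,
        ``lat_band``, ``year``, ``month``, ``decade``, ``diatom_ugC``,
        ``dinoflagellate_ugC``, ``h``.
    response : str
        One of ``log_diatom``, ``log_dinoflagellate``, ``log_total``,
        ``logit_index``.
    variant : str
        ``time-space-temperature`` (anomaly covariate) or ``time-space``
        (decade steps).
    anomalies : DataFrame, optional
        Per-bin SST anomalies (columns ``province``, ``lat_band``,
        ``year``, ``month``, ``anomaly``); required for the temperature
        variant.

    An empty `bins` frame is accepted and yields prior draws.
    """

    def __init__(self, bins: pd.DataFrame, response: str = "logit_index",
                 variant: str = "time-space-temperature",
                 anomalies: pd.DataFrame | None = None):
        if response not in RESPONSES:
            raise ValueError(f"response must be one of {sorted(RESPONSES)}")
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.response = response
        self.variant = variant
        self.bins = bins.reset_index(drop=True)
        n = len(self.bins)
        if n:
            if self.bins["year"].nunique() < 2:
                raise ValueError("need at least 2 distinct years")
            if self.bins["province"].nunique() < 2:
                raise ValueError("need at least 2 provinces")
        if variant == "time-space-temperature":
            if anomalies is None:
                if n:
                    raise ValueError("temperature variant requires anomalies")
                self._anom = np.zeros(0)
            elif isinstance(anomalies, (np.ndarray, pd.Series, list)):
                self._anom = np.asarray(anomalies, float)
                if len(self._anom) != n:
                    raise ValueError("anomaly vector length must match bins")
            else:
                merged = self.bins.merge(anomalies[BIN_KEY + ["anomaly"]],
                                         on=BIN_KEY, how="left", validate="1:1")
                if merged["anomaly"].isna().any():
                    missing = merged.loc[merged["anomaly"].isna(), BIN_KEY]
                    raise ValueError(
                        f"missing anomaly for {len(missing)} bins, e.g. "
                        f"{missing.iloc[0].to_dict() if len(missing) else ''}")
                self._anom = merged["anomaly"].to_numpy(float)
        else:
            self._anom = None

        self.provinces = (sorted(self.bins["province"].unique()) if n else [])
        self.decades = (np.unique(self.bins["decade"]) if n else np.array([], int))
        self._prov_idx = {p: i for i, p in enumerate(self.provinces)}
        if n:
            self.mean_latitude = (self.bins.groupby("province")["lat_band"]
                                  .mean().to_dict())
        else:
            self.mean_latitude = {}
        self._y = RESPONSES[response](self.bins) if n else np.zeros(0)
        if n and not np.all(np.isfinite(self._y)):
            raise ValueError("response contains non-finite values; "
                             "run zero imputation first")

    def _gibbs_data(self, n_provinces_prior: int = 2,
                    n_decades_prior: int = 6) -> GibbsData:
        n = len(self.bins)
        if n == 0:
            # prior-sampling harness: no data, nominal dimensions
            use_delta = self.variant == "time-space"
            return GibbsData(
                y=np.zeros(0), province_idx=np.zeros(0, int),
                month_idx=np.zeros(0, int), lat_c=np.zeros(0),
                year_c=np.zeros(0), n_provinces=n_provinces_prior,
                anomaly=np.zeros(0) if self._anom is not None else None,
                decade_idx=np.zeros(0, int) if use_delta else None,
                n_decades=n_decades_prior if use_delta else 0)
        a = self.bins["province"].map(self._prov_idx).to_numpy()
        lat_c = (self.bins["lat_band"].to_numpy(float)
                 - self.bins["province"].map(self.mean_latitude).to_numpy(float))
        dec_map = {d: i for i, d in enumerate(self.decades)}
        use_delta = self.variant == "time-space"
        return GibbsData(
            y=self._y, province_idx=a,
            month_idx=self.bins["month"].to_numpy(int) - 1,
            lat_c=lat_c, year_c=self.bins["year"].to_numpy(float) - YEAR_ZERO,
            n_provinces=len(self.provinces),
            anomaly=self._anom,
            decade_idx=(self.bins["decade"].map(dec_map).to_numpy(int)
                        if use_delta else None),
            n_decades=len(self.decades) if use_delta else 0)

    def fit(self, config: ModelConfig | None = None,
            keep_residuals: bool = False) -> "TrendResults":
        config = config or ModelConfig()
        data = self._gibbs_data()
        draws = run_chains(data, config.priors(), config.iterations,
                           config.burn_in, config.thinning, config.seed,
                           config.chains, keep_residuals=keep_residuals)
        return TrendResults(self, config, draws)


def _convergence_table(draws: dict, skip=("resid",)) -> pd.DataFrame:
    import arviz as az
    sub = {k: v for k, v in draws.items() if k not in skip}
    idata = az.from_dict(posterior=sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name in sub:
        rows.append({"parameter": name,
                     "rhat_max": float(np.nanmax(rhat[name].values)),
                     "ess_min": float(np.nanmin(ess[name].values))})
    return pd.DataFrame(rows)


class TrendResults:
    """Posterior draws and summaries for one fitted trend model."""

    def __init__(self, model: PlanktonTrendModel, config: ModelConfig,
                 draws: dict):
        self.model = model
        self.config = config
        self.draws = draws  # name -> (chain, draw, ...)
        self.convergence = None
        self.converged = None
        if len(model.bins):
            self.convergence = _convergence_table(draws)
            self.converged = bool(
                (self.convergence["rhat_max"] <= config.rhat_max).all()
                and (self.convergence["ess_min"] >= config.ess_min).all())
            if not self.converged:
                worst = self.convergence.sort_values("rhat_max").iloc[-1]
                warnings.warn(
                    f"MCMC convergence flags tripped (worst rhat "
                    f"{worst['rhat_max']:.3f} for {worst['parameter']}); "
                    "inspect .convergence and increase iterations",
                    ConvergenceWarning)

    # -- access ------------------------------------------------------------
    def stacked(self, name: str) -> np.ndarray:
        """Draws with chain and draw axes merged: (n_draws, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.draws["gamma"].shape[0] * self.draws["gamma"].shape[1]

    def mu_draws(self, draw_sel: np.ndarray | None = None) -> np.ndarray:
        """Linear predictor at the observed design points, (n_sel, n_obs)."""
        m = self.model
        data = m._gibbs_data()
        theta = self.stacked("theta")
        eta = self.stacked("eta")
        gamma = self.stacked("gamma")
        if draw_sel is None:
            draw_sel = np.arange(theta.shape[0])
        am = data.province_idx * 12 + data.month_idx
        a = data.province_idx
        mu = (theta.reshape(theta.shape[0], -1)[np.ix_(draw_sel, am)]
              + eta[np.ix_(draw_sel, a)] * data.lat_c
              + gamma[np.ix_(draw_sel, a)] * data.year_c)
        if m.variant == "time-space-temperature":
            phi = self.stacked("phi")
            mu += phi[np.ix_(draw_sel, a)] * data.anomaly
        else:
            delta = self.stacked("delta")
            ad = a * data.n_decades + data.decade_idx
            mu += delta.reshape(delta.shape[0], -1)[np.ix_(draw_sel, ad)]
        return mu

    def sigma_by_obs(self, draw_sel: np.ndarray | None = None) -> np.ndarray:
        sigma = self.stacked("sigma")
        if draw_sel is None:
            draw_sel = np.arange(sigma.shape[0])
        a = self.model._gibbs_data().province_idx
        return sigma[np.ix_(draw_sel, a)]

    # -- summaries ---------------------------------------------------------
    QUANTS = (0.025, 0.17, 0.5, 0.83, 0.975)

    def _param_table(self, name: str, labels) -> pd.DataFrame:
        draws = self.stacked(name).reshape(self.n_draws, -1)
        qs = np.quantile(draws, self.QUANTS, axis=0)
        return pd.DataFrame({
            "parameter": labels,
            "median": qs[2], "q2.5": qs[0], "q17": qs[1],
            "q83": qs[3], "q97.5": qs[4]})

    def slope_summary(self) -> pd.DataFrame:
        """Per-province quantile table for the slope-type effects.

        Quantiles at 2.5/17/50/83/97.5% give the median plus 66% and 95%
        credible intervals for the interannual trend, the latitudinal
        gradient, the anomaly or decade effects, and each month effect.
        """
        provs = self.model.provinces or [f"p{i}" for i in
                                         range(self.draws["eta"].shape[-1])]
        frames = []
        for name, per in (("gamma", 1), ("eta", 1)):
            t = self._param_table(name, provs)
            t.insert(0, "effect", {"gamma": "trend", "eta": "latitude"}[name])
            t = t.rename(columns={"parameter": "province"})
            frames.append(t)
        if "phi" in self.draws:
            t = self._param_table("phi", provs)
            t.insert(0, "effect", "anomaly")
            frames.append(t.rename(columns={"parameter": "province"}))
        if "delta" in self.draws:
            decades = list(self.model.decades) or list(range(self.draws["delta"].shape[-1]))
            labels = [f"{p}:{d}" for p in provs for d in decades]
            t = self._param_table("delta", labels)
            t.insert(0, "effect", "decade")
            frames.append(t.rename(columns={"parameter": "province"}))
        labels = [f"{p}:m{mo:02d}" for p in provs for mo in range(1, 13)]
        t = self._param_table("theta", labels)
        t.insert(0, "effect", "month")
        frames.append(t.rename(columns={"parameter": "province"}))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavored)."""
        m = self.model
        lines = [
            "Plankton trend model",
            "=" * 64,
            f"response:  {m.response:<24s} variant: {m.variant}",
            f"bins:      {len(m.bins):<24d} provinces: {len(m.provinces)}",
            f"chains:    {self.config.chains}  iterations: {self.config.iterations}"
            f"  burn-in: {self.config.burn_in}  thin: {self.config.thinning}",
            f"retained draws: {self.n_draws}   converged: {self.converged}",
            "-" * 64,
            f"{'effect':<10s}{'province':<10s}{'median':>10s}{'2.5%':>10s}{'97.5%':>10s}",
        ]
        tab = self.slope_summary()
        for _, r in tab[tab["effect"].isin(["trend", "latitude", "anomaly"])].iterrows():
            lines.append(f"{r['effect']:<10s}{str(r['province']):<10s}"
                         f"{r['median']:>10.4f}{r['q2.5']:>10.4f}{r['q97.5']:>10.4f}")
        sig = self._param_table("sigma", m.provinces or
                                list(range(self.draws["sigma"].shape[-1])))
        for _, r in sig.iterrows():
            lines.append(f"{'resid sd':<10s}{str(r['parameter']):<10s}"
                         f"{r['median']:>10.4f}{r['q2.5']:>10.4f}{r['q97.5']:>10.4f}")
        return "\n".join(lines)

    # -- diagnostics / reporting shortcuts ----------------------------------
    def bayesian_r2(self) -> float:
        from .diagnostics import bayesian_r2
        return bayesian_r2(self)

    def posterior_predictive_check(self, statistic="mean", n_rep=100, seed=0,
                                   per_province=False):
        from .diagnostics import posterior_predictive_check
        return posterior_predictive_check(self, statistic=statistic,
                                          n_rep=n_rep, seed=seed,
                                          per_province=per_province)

    def monthly_climatology(self) -> pd.DataFrame:
        from .report import monthly_climatology
        return monthly_climatology(self)

    def trend_report(self, horizon_years: int = 60) -> pd.DataFrame:
        from .report import trend_report
        return trend_report(self, horizon_years=horizon_years)

    # -- persistence ---------------------------------------------------------
    def to_draws_frame(self) -> pd.DataFrame:
        """Columnar draws table: parameter, chain, draw, value."""
        rows = []
        provs = self.model.provinces
        for name, arr in self.draws.items():
            if name == "resid":
                continue
            C, N = arr.shape[:2]
            flat = arr.reshape(C, N, -1)
            for k in range(flat.shape[2]):
                if arr.ndim == 2:
                    label = name
                elif arr.ndim == 3:
                    label = f"{name}[{provs[k] if provs else k}]"
                else:
                    p, j = divmod(k, arr.shape[3])
                    label = f"{name}[{provs[p] if provs else p},{j}]"
                for c in range(C):
                    rows.append(pd.DataFrame({
                        "parameter": label, "chain": c,
                        "draw": np.arange(N), "value": flat[c, :, k]}))
        return pd.concat(rows, ignore_index=True)

    def save(self, outdir) -> None:
        """Write draws, config and metadata to a directory."""
        import json
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_draws_frame().to_csv(out / "draws.csv", index=False)
        np.savez(out / "draws_raw.npz",
                 **{k: v for k, v in self.draws.items() if k != "resid"})
        self.config.to_yaml(out / "config.yaml")
        meta = {
            "response": self.model.response,
            "variant": self.model.variant,
            "provinces": list(self.model.provinces),
            "decades": [int(d) for d in self.model.decades],
            "mean_latitude": {k: float(v) for k, v in
                              self.model.mean_latitude.items()},
            "converged": self.converged,
        }
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        self.model.bins.to_csv(out / "bins.csv", index=False)
        if self.model._anom is not None:
            pd.DataFrame({"anomaly": self.model._anom}).to_csv(
                out / "anomaly_vector.csv", index=False)
        if self.convergence is not None:
            self.convergence.to_csv(out / "convergence.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "TrendResults":
        import json
        import pathlib
        out = pathlib.Path(outdir)
        with open(out / "meta.json") as fh:
            meta = json.load(fh)
        bins = pd.read_csv(out / "bins.csv")
        anom = None
        if (out / "anomaly_vector.csv").exists():
            av = pd.read_csv(out / "anomaly_vector.csv")
            anom = bins[BIN_KEY].copy()
            anom["anomaly"] = av["anomaly"].to_numpy()
        model = PlanktonTrendModel(bins, response=meta["response"],
                                   variant=meta["variant"], anomalies=anom)
        config = ModelConfig.from_yaml(out / "config.yaml")
        draws = dict(np.load(out / "draws_raw.npz"))
        return cls(model, config, draws)
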
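"""Gibbs sampler for the hierarchical Normal spatio-temporal models.

One sampler serves both the SST decomposition and the biomass/index trend
models: the response is Normal with a linear predictor built from
province-by-month effects, a province latitudinal gradient, a province
interannual trend and optionally a province anomaly effect (the
Time-Space-Temperature variant) or province decade steps under an
extended Bayesian LASSO prior (the Time-Space variant).

All full conditionals are conjugate except three scalar families:

* province residual sds carry Uniform(0, U) priors, giving a truncated
  inverse-gamma conditional sampled by inverse-CDF;
* the LASSO province scales xi_A have Uniform(0, 2) priors whose
  conditional on xi^2 is a truncated Gamma(3/2, .);
* the global LASSO scale lambda has a Gamma(1, 1) prior with a
  non-standard conditional, updated by univariate slice sampling.

The decade-step variances sigma^2_{A,delta} ~ Exp(lambda_A^2 / 2)
(an exponential parameterized by *rate*, so prior mean 2/lambda_A^2)
have generalized-inverse-Gaussian conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class GibbsData:
    """Design arrays for one model fit. All arrays share length n."""

    y: np.ndarray
    province_idx: np.ndarray     # int, 0..P-1
    month_idx: np.ndarray        # int, 0..11
    lat_c: np.ndarray            # latitude centered per province
    year_c: np.ndarray           # year - 1960
    n_provinces: int
    anomaly: np.ndarray | None = None     # adds phi_A * anomaly
    decade_idx: np.ndarray | None = None  # int, 0..D-1; adds delta_{d,A}
    n_decades: int = 0


@dataclass
class GibbsPriors:
    ig_shape: float = 0.1
    ig_rate: float = 0.1
    sigma_upper: float = 10.0
    lasso_lambda_shape: float = 1.0
    lasso_lambda_rate: float = 1.0
    xi_upper: float = 2.0


def _sample_invgamma(rng, shape, rate):
    """InvGamma(shape, rate) draw (density x^{-shape-1} e^{-rate/x})."""
    return rate / rng.gamma(shape, 1.0)


def _trunc_gamma(rng, shape, rate, lower=0.0, upper=np.inf):
    """Gamma(shape, rate) truncated to (lower, upper), via CDF inversion."""
    dist = stats.gamma(a=shape, scale=1.0 / rate)
    lo = dist.cdf(lower) if lower > 0 else 0.0
    hi = dist.cdf(upper) if np.isfinite(upper) else 1.0
    u = rng.uniform(lo, min(hi, 1.0 - 1e-16))
    x = dist.ppf(u)
    if not np.isfinite(x) or x <= 0:
        x = max(lower, min(shape / rate, upper))  # numerical fallback
    return x


def _slice_sample(rng, x0, logpdf, width=1.0, max_steps=50, lower=0.0,
                  upper=np.inf):
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logpdf(x0) + np.log(rng.uniform(1e-300, 1.0))
    u = rng.uniform()
    left = max(lower, x0 - u * width)
    right = min(upper, left + width)
    for _ in range(max_steps):
        if left <= lower or logpdf(left) < logy:
            break
        left = max(lower, left - width)
    for _ in range(max_steps):
        if right >= upper or logpdf(right) < logy:
            break
        right = min(upper, right + width)
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


class _State:
    def __init__(self, data: GibbsData, rng):
        P, n = data.n_provinces, len(data.y)
        self.theta = np.zeros((P, 12))
        if n:
            am = data.province_idx * 12 + data.month_idx
            counts = np.bincount(am, minlength=P * 12)
            sums = np.bincount(am, weights=data.y, minlength=P * 12)
            with np.errstate(invalid="ignore"):
                init = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            self.theta = init.reshape(P, 12)
        self.eta = np.zeros(P)
        self.gamma = np.zeros(P)
        self.phi = np.zeros(P)
        self.delta = np.zeros((P, max(data.n_decades, 1)))
        self.sigma2 = np.ones(P)
        self.s2_theta = 1.0
        self.s2_eta = 1.0
        self.s2_gamma = 1.0
        self.s2_phi = 1.0
        self.s2_delta = np.ones(P)
        self.lam = 1.0
        self.xi = np.ones(P)


def run_chain(data: GibbsData, priors: GibbsPriors, iterations: int,
              burn_in: int, thinning: int, seed,
              keep_residuals: bool = False) -> dict:
    """Run one Gibbs chain; return retained draws keyed by parameter name."""
    rng = np.random.default_rng(seed)
    n = len(data.y)
    P = data.n_provinces
    D = data.n_decades
    use_phi = data.anomaly is not None
    use_delta = data.decade_idx is not None and D > 0

    a = data.province_idx
    m = data.month_idx
    am = a * 12 + m if n else np.zeros(0, dtype=int)
    n_am = np.bincount(am, minlength=P * 12) if n else np.zeros(P * 12)
    n_a = np.bincount(a, minlength=P) if n else np.zeros(P)
    a_of_am = np.arange(P * 12) // 12
    Sxx_lat = np.bincount(a, weights=data.lat_c ** 2, minlength=P) if n else np.zeros(P)
    Sxx_year = np.bincount(a, weights=data.year_c ** 2, minlength=P) if n else np.zeros(P)
    if use_phi and n:
        Sxx_anom = np.bincount(a, weights=data.anomaly ** 2, minlength=P)
    else:
        Sxx_anom = np.zeros(P)
    if use_delta and n:
        ad = a * D + data.decade_idx
        n_ad = np.bincount(ad, minlength=P * D)
    else:
        ad = np.zeros(0, dtype=int)
        n_ad = np.zeros(P * max(D, 1))
    a_of_ad = np.arange(P * max(D, 1)) // max(D, 1)

    st = _State(data, rng)
    n_keep = (iterations - burn_in) // thinning
    out = {
        "theta": np.empty((n_keep, P, 12)),
        "eta": np.empty((n_keep, P)),
        "gamma": np.empty((n_keep, P)),
        "sigma": np.empty((n_keep, P)),
        "s2_theta": np.empty(n_keep),
        "s2_eta": np.empty(n_keep),
        "s2_gamma": np.empty(n_keep),
    }
    if use_phi:
        out["phi"] = np.empty((n_keep, P))
        out["s2_phi"] = np.empty(n_keep)
    if use_delta:
        out["delta"] = np.empty((n_keep, P, D))
        out["s2_delta"] = np.empty((n_keep, P))
        out["lam"] = np.empty(n_keep)
        out["xi"] = np.empty((n_keep, P))
    if keep_residuals:
        out["resid"] = np.empty((n_keep, n))

    def components():
        th = st.theta.reshape(-1)[am] if n else np.zeros(0)
        lin = st.eta[a] * data.lat_c + st.gamma[a] * data.year_c if n else np.zeros(0)
        if use_phi and n:
            lin = lin + st.phi[a] * data.anomaly
        if use_delta and n:
            lin = lin + st.delta.reshape(-1)[ad]
        return th, lin

    kept = 0
    for it in range(iterations):
        inv_s2 = 1.0 / st.sigma2

        # month-by-province effects
        _, lin = components()
        r = data.y - lin if n else np.zeros(0)
        prec = n_am * inv_s2[a_of_am] + 1.0 / st.s2_theta
        s = (np.bincount(am, weights=r, minlength=P * 12) if n else np.zeros(P * 12))
        mean = (s * inv_s2[a_of_am]) / prec
        st.theta = (mean + rng.standard_normal(P * 12) / np.sqrt(prec)).reshape(P, 12)

        # province slopes (latitude, year, anomaly)
        for attr, x, sxx, s2h in (("eta", data.lat_c, Sxx_lat, st.s2_eta),
                                  ("gamma", data.year_c, Sxx_year, st.s2_gamma)):
            setattr(st, attr, _slope_update(rng, st, data, a, x, sxx, s2h,
                                            inv_s2, P, n, attr, am, ad,
                                            use_phi, use_delta))
        if use_phi:
            st.phi = _slope_update(rng, st, data, a, data.anomaly, Sxx_anom,
                                   st.s2_phi, inv_s2, P, n, "phi", am, ad,
                                   use_phi, use_delta)

        # decade steps under the LASSO prior
        if use_delta:
            th, lin = components()
            if n:
                lin = lin - st.delta.reshape(-1)[ad]
                r = data.y - th - lin
            prec = n_ad * inv_s2[a_of_ad] + 1.0 / st.s2_delta[a_of_ad]
            s = (np.bincount(ad, weights=r, minlength=P * D) if n else np.zeros(P * D))
            mean = (s * inv_s2[a_of_ad]) / prec
            st.delta = (mean + rng.standard_normal(P * D) / np.sqrt(prec)).reshape(P, D)

        # residual variances, Uniform(0, U) prior on sigma
        th, lin = components()
        resid = data.y - th - lin if n else np.zeros(0)
        SS = np.bincount(a, weights=resid ** 2, minlength=P) if n else np.zeros(P)
        has = n_a > 0
        if has.any():
            shape = np.maximum((n_a[has] - 1) / 2.0, 0.01)
            rate = np.maximum(SS[has], 1e-12) / 2.0
            lo = stats.gamma.cdf(1.0 / priors.sigma_upper ** 2, a=shape,
                                 scale=1.0 / rate)
            u = rng.uniform(lo, 1.0 - 1e-16)
            tau = stats.gamma.ppf(u, a=shape, scale=1.0 / rate)
            bad = ~np.isfinite(tau) | (tau <= 0)
            if bad.any():
                tau[bad] = np.maximum(shape[bad] / rate[bad],
                                      1.0 / priors.sigma_upper ** 2)
            st.sigma2[has] = 1.0 / tau
        if (~has).any():
            st.sigma2[~has] = rng.uniform(0, priors.sigma_upper,
                                          size=(~has).sum()) ** 2

        # hyper-variances, InvGamma(ig_shape, ig_rate)
        st.s2_theta = _sample_invgamma(rng, priors.ig_shape + P * 12 / 2.0,
                                       priors.ig_rate + np.sum(st.theta ** 2) / 2.0)
        st.s2_eta = _sample_invgamma(rng, priors.ig_shape + P / 2.0,
                                     priors.ig_rate + np.sum(st.eta ** 2) / 2.0)
        st.s2_gamma = _sample_invgamma(rng, priors.ig_shape + P / 2.0,
                                       priors.ig_rate + np.sum(st.gamma ** 2) / 2.0)
        if use_phi:
            st.s2_phi = _sample_invgamma(rng, priors.ig_shape + P / 2.0,
                                         priors.ig_rate + np.sum(st.phi ** 2) / 2.0)

        # extended Bayesian LASSO hierarchy
        if use_delta:
            lam_a2 = (st.lam * st.xi) ** 2
            for p in range(P):
                chi = max(np.sum(st.delta[p] ** 2), 1e-12)
                psi = max(lam_a2[p], 1e-12)
                b = np.sqrt(chi * psi)
                st.s2_delta[p] = stats.geninvgauss.rvs(
                    1.0 - D / 2.0, b, scale=np.sqrt(chi / psi), random_state=rng)
            # xi_A: t = xi^2 ~ Gamma(3/2, lam^2 sigma2_delta / 2) on (0, U^2)
            c = np.maximum(st.lam ** 2 * st.s2_delta / 2.0, 1e-12)
            hi = stats.gamma.cdf(priors.xi_upper ** 2, a=1.5, scale=1.0 / c)
            u = rng.uniform(1e-16, np.maximum(hi, 2e-16))
            t = stats.gamma.ppf(u, a=1.5, scale=1.0 / c)
            t = np.clip(t, 1e-12, priors.xi_upper ** 2)
            st.xi = np.sqrt(t)
            S = np.sum(st.xi ** 2 * st.s2_delta)
            shape0 = priors.lasso_lambda_shape
            rate0 = priors.lasso_lambda_rate

            def logp_lam(lam):
                if lam <= 0:
                    return -np.inf
                return ((2 * P + shape0 - 1) * np.log(lam)
                        - rate0 * lam - S * lam ** 2 / 2.0)

            st.lam = _slice_sample(rng, st.lam, logp_lam, width=1.0)

        if it >= burn_in and (it - burn_in) % thinning == 0 and kept < n_keep:
            out["theta"][kept] = st.theta
            out["eta"][kept] = st.eta
            out["gamma"][kept] = st.gamma
            out["sigma"][kept] = np.sqrt(st.sigma2)
            out["s2_theta"][kept] = st.s2_theta
            out["s2_eta"][kept] = st.s2_eta
            out["s2_gamma"][kept] = st.s2_gamma
            if use_phi:
                out["phi"][kept] = st.phi
                out["s2_phi"][kept] = st.s2_phi
            if use_delta:
                out["delta"][kept] = st.delta
                out["s2_delta"][kept] = st.s2_delta
                out["lam"][kept] = st.lam
                out["xi"][kept] = st.xi
            if keep_residuals:
                out["resid"][kept] = resid
            kept += 1
    return out


def _slope_update(rng, st, data, a, x, sxx, s2h, inv_s2, P, n, attr, am, ad,
                  use_phi, use_delta):
    """Conjugate Normal update of one family of province slopes."""
    th = st.theta.reshape(-1)[am] if n else np.zeros(0)
    lin = st.eta[a] * data.lat_c + st.gamma[a] * data.year_c if n else np.zeros(0)
    if use_phi and n:
        lin = lin + st.phi[a] * data.anomaly
    if use_delta and n:
        lin = lin + st.delta.reshape(-1)[ad]
    if n:
        lin = lin - getattr(st, attr)[a] * x  # remove own contribution
        r = data.y - th - lin
        sxy = np.bincount(a, weights=x * r, minlength=P)
    else:
        sxy = np.zeros(P)
    prec = sxx * inv_s2 + 1.0 / s2h
    mean = sxy * inv_s2 / prec
    return mean + rng.standard_normal(P) / np.sqrt(prec)


def run_chains(data: GibbsData, priors: GibbsPriors, iterations: int,
               burn_in: int, thinning: int, seed, chains: int,
               keep_residuals: bool = False) -> dict:
    """Run several chains; stack draws with a leading chain axis."""
    seeds = np.random.SeedSequence(seed).spawn(chains)
    per_chain = [run_chain(data, priors, iterations, burn_in, thinning, s,
                           keep_residuals=keep_residuals) for s in seeds]
    return {k: np.stack([c[k] for c in per_chain]) for k in per_chain[0]}
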
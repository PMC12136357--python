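"""Headline quantities: %/yr, compounded change, climatologies, effect tables.

Slopes live on the natural-log (biomass) or logit (index) scale, so a
slope g per year is an exact multiplicative change of e^g per year,
i.e. 100*(e^g - 1) percent per year; a slope of 0.01 a⁻¹ is approximately
a 1% change per year.  Over an n-year horizon an annual rate compounds to
100*((1 + rate/100)^n - 1) percent total change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def percent_per_year(slope) -> float | np.ndarray:
    """Exact percent change per year for a log/logit-scale slope."""
    out = 100.0 * (np.exp(np.asarray(slope, float)) - 1.0)
    return float(out) if out.ndim == 0 else out


def compound_change(annual_rate_percent, years: int) -> float | np.ndarray:
    """Total percent change after `years` at a constant annual percent rate."""
    rate = np.asarray(annual_rate_percent, float)
    if years < 0:
        raise ValueError("years must be >= 0")
    if np.any(rate <= -100.0):
        raise ValueError("annual rate must exceed -100%")
    out = 100.0 * ((1.0 + rate / 100.0) ** years - 1.0)
    return float(out) if out.ndim == 0 else out


def trend_report(results, horizon_years: int = 60) -> pd.DataFrame:
    """Per-province trend table from a fitted model.

    Columns: slope median and 95% CI (per year, log/logit scale), the
    exact percent-per-year conversion of each, and the compounded percent
    change over `horizon_years`.
    """
    gamma = results.stacked("gamma")
    qs = np.quantile(gamma, [0.025, 0.5, 0.975], axis=0)
    provs = results.model.provinces or list(range(gamma.shape[1]))
    rows = []
    for i, prov in enumerate(provs):
        lo, med, hi = qs[:, i]
        pct = percent_per_year(med)
        rows.append({
            "province": prov, "response": results.model.response,
            "slope_median": med, "slope_q2.5": lo, "slope_q97.5": hi,
            "pct_per_yr": pct,
            "pct_per_yr_q2.5": percent_per_year(lo),
            "pct_per_yr_q97.5": percent_per_year(hi),
            "compounded_pct": compound_change(pct, horizon_years),
            "compounded_pct_q2.5": compound_change(percent_per_year(lo), horizon_years),
            "compounded_pct_q97.5": compound_change(percent_per_year(hi), horizon_years),
            "horizon_years": horizon_years,
        })
    return pd.DataFrame(rows)


def monthly_climatology(results) -> pd.DataFrame:
    """Posterior month-effect table: 12 rows per province with median,
    95% CI and the annual mean (mean of the 12 month-effect medians)."""
    theta = results.stacked("theta")  # (draws, P, 12)
    qs = np.quantile(theta, [0.025, 0.5, 0.975], axis=0)
    provs = results.model.provinces or list(range(theta.shape[1]))
    rows = []
    for i, prov in enumerate(provs):
        annual = float(np.mean(qs[1, i]))
        for m in range(12):
            rows.append({"province": prov, "response": results.model.response,
                         "month": m + 1, "median": qs[1, i, m],
                         "q2.5": qs[0, i, m], "q97.5": qs[2, i, m],
                         "annual_mean": annual})
    return pd.DataFrame(rows)


def effect_table(results) -> pd.DataFrame:
    """Fig-2/4-style effect table with %/yr for the trend rows."""
    tab = results.slope_summary().copy()
    tab["response"] = results.model.response
    tab["pct_per_yr"] = np.where(tab["effect"] == "trend",
                                 percent_per_year(tab["median"].to_numpy()),
                                 np.nan)
    return tab


def plot_climatology(results, path=None):
    """Month-effect panels per province (median ± 95% CI)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    clim = monthly_climatology(results)
    provs = clim["province"].unique()
    fig, axes = plt.subplots(1, len(provs), figsize=(3 * len(provs), 3),
                             sharey=True, squeeze=False)
    for ax, prov in zip(axes[0], provs):
        sub = clim[clim["province"] == prov]
        ax.errorbar(sub["month"], sub["median"],
                    yerr=[sub["median"] - sub["q2.5"],
                          sub["q97.5"] - sub["median"]],
                    fmt="o", ms=3, capsize=2)
        ax.axhline(sub["annual_mean"].iloc[0], color="gray", lw=1)
        ax.set_title(str(prov))
        ax.set_xlabel("month")
    axes[0][0].set_ylabel(results.model.response)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
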
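"""Spatio-temporal binning of biomass samples and the diatom index.

Per-sample group biomasses are aggregated to province x 2.5°-latitude-band
x month x year cells; longitude is discarded (no within-province
longitudinal trend is modeled).  Zero bins are imputed at half the
group-wise minimum positive binned biomass, computed once over the whole
aggregated dataset, after which the diatom index p = q/(q+r) and its logit
h = ln(p/(1-p)) are defined everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BIN_KEY = ["province", "lat_band", "year", "month"]
DEFAULT_BAND_WIDTH = 2.5


def logit(x):
    """ln(x/(1-x)) for x strictly inside (0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("logit requires 0 < x < 1")
    out = np.log(x / (1.0 - x))
    return float(out) if out.ndim == 0 else out


def inv_logit(h):
    """Inverse of :func:`logit`: 1/(1+e^{-h})."""
    h = np.asarray(h, dtype=float)
    out = 1.0 / (1.0 + np.exp(-h))
    return float(out) if out.ndim == 0 else out


def assign_band(latitude, band_width: float = DEFAULT_BAND_WIDTH):
    """Latitude-band center for a latitude.

    Bands are half-open intervals [k*w, (k+1)*w) anchored at 0°N; the
    returned value is the interval midpoint (e.g. 51.0° -> 51.25° for the
    default 2.5° width).
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(~np.isfinite(lat)):
        raise ValueError("latitude must be finite")
    out = (np.floor(lat / band_width) + 0.5) * band_width
    return float(out) if out.ndim == 0 else out


def decade_label(year):
    """Calendar decade of a year (1965 -> 1960)."""
    return (np.asarray(year, dtype=int) // 10) * 10


def aggregate_bins(samples: pd.DataFrame,
                   band_width: float = DEFAULT_BAND_WIDTH) -> pd.DataFrame:
    """Sum per-sample group biomass into (province, band, year, month) bins.

    `samples` is the output of :func:`cprtrends.biomass.community_biomass`.
    Returns one row per populated bin with columns ``diatom_ugC`` (q),
    ``dinoflagellate_ugC`` (r) and ``decade``; no imputation or index yet.
    """
    df = samples.copy()
    df["lat_band"] = assign_band(df["latitude"].to_numpy(), band_width)
    out = (df.groupby(BIN_KEY, as_index=False)[["diatom_ugC", "dinoflagellate_ugC"]]
             .sum())
    out["decade"] = decade_label(out["year"])
    return out.sort_values(BIN_KEY, ignore_index=True)


def impute_zeros(bins: pd.DataFrame) -> pd.DataFrame:
    """Replace zero binned biomass by half the group's global minimum positive value.

    Each group is imputed independently; the floor is computed once over
    the whole aggregated dataset.  Adds boolean ``diatom_imputed`` /
    ``dinoflagellate_imputed`` flags and the diatom index columns ``p``
    (q/(q+r)) and ``h`` (logit p).
    """
    out = bins.copy()
    for col, flag in (("diatom_ugC", "diatom_imputed"),
                      ("dinoflagellate_ugC", "dinoflagellate_imputed")):
        vals = out[col].to_numpy(dtype=float)
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError(f"all-zero biomass for {col}: cannot impute")
        floor = 0.5 * pos.min()
        zero = vals == 0
        vals = np.where(zero, floor, vals)
        out[col] = vals
        out[flag] = zero
    q = out["diatom_ugC"].to_numpy()
    r = out["dinoflagellate_ugC"].to_numpy()
    out["p"] = q / (q + r)
    out["h"] = logit(out["p"].to_numpy())
    return out


def prepare_bins(samples: pd.DataFrame,
                 band_width: float = DEFAULT_BAND_WIDTH) -> pd.DataFrame:
    """Aggregate and impute in one step; the modeling-ready bin table."""
    return impute_zeros(aggregate_bins(samples, band_width))
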
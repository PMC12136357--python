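"""Taxon abundances to functional-group carbon biomass.

Plankton-recorder counts are semi-quantitative abundances proportional to
cell number density.  Each taxon is mapped to a per-cell carbon content
through a group-specific allometric power law, and group biomass per sample
is the abundance-weighted sum of per-cell carbon over the taxa of that
group.  Internal biomass unit is µg C; per-cell carbon is in pg C
(1 µg = 1e6 pg).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ("diatom", "dinoflagellate")

#: log10(pg C) = a + b * log10(volume µm³); separate fit for diatoms,
#: general protist fit for dinoflagellates.  Configuration constants.
ALLOMETRY = {
    "diatom": {"a": -0.541, "b": 0.811},
    "dinoflagellate": {"a": -0.665, "b": 0.939},
}

PG_PER_UG = 1e6

SAMPLE_KEY = ["province", "latitude", "longitude", "year", "month"]


def cell_carbon(volume: float | np.ndarray, group: str,
                coefficients: dict | None = None) -> float | np.ndarray:
    """Per-cell carbon (pg C) from cell volume (µm³) for one functional group.

    Parameters
    ----------
    volume : float or array
        Cell volume in µm³, strictly positive.
    group : str
        ``"diatom"`` or ``"dinoflagellate"``.
    coefficients : dict, optional
        Override of the allometric constants, same structure as
        :data:`ALLOMETRY`.
    """
    coefs = (coefficients or ALLOMETRY).get(group)
    if coefs is None:
        raise ValueError(f"unknown functional group: {group!r}")
    v = np.asarray(volume, dtype=float)
    if np.any(~(v > 0)):
        raise ValueError("cell volume must be > 0")
    out = 10.0 ** (coefs["a"] + coefs["b"] * np.log10(v))
    return float(out) if np.isscalar(volume) else out


def impute_missing_size(traits: pd.DataFrame,
                        coefficients: dict | None = None) -> pd.DataFrame:
    """Fill per-cell carbon for taxa with unknown cell volume.

    Returns a copy of `traits` with a ``carbon_pg`` column.  Taxa with a
    known volume get the allometric value; a taxon with missing volume gets
    the geometric mean of the per-cell carbon of all known taxa in its
    group (imputation on the log-carbon scale).

    `traits` must have columns ``taxon``, ``group``, ``volume_um3`` (NaN
    where unknown).
    """
    out = traits.copy()
    bad = ~out["group"].isin(GROUPS)
    if bad.any():
        raise ValueError(f"unknown group labels: {sorted(out.loc[bad, 'group'].unique())}")
    known = out["volume_um3"].notna()
    carbon = np.full(len(out), np.nan)
    for grp in GROUPS:
        sel = known & (out["group"] == grp)
        if sel.any():
            carbon[sel.to_numpy()] = cell_carbon(
                out.loc[sel, "volume_um3"].to_numpy(), grp, coefficients)
    for grp in GROUPS:
        miss = (~known) & (out["group"] == grp)
        if not miss.any():
            continue
        have = known & (out["group"] == grp)
        if not have.any():
            raise ValueError(
                f"cannot impute size for group {grp!r}: no taxon with known volume")
        gm = float(np.exp(np.mean(np.log(carbon[have.to_numpy()]))))
        carbon[miss.to_numpy()] = gm
    out["carbon_pg"] = carbon
    return out


def community_biomass(records: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-sample functional-group carbon biomass (µg C).

    Parameters
    ----------
    records : DataFrame
        Abundance records with columns ``taxon``, ``group``, ``abundance``,
        ``latitude``, ``longitude``, ``year``, ``month``, ``province``.
    traits : DataFrame
        Trait table with ``carbon_pg`` populated (see
        :func:`impute_missing_size`).

    Returns
    -------
    DataFrame with one row per sample key (province, latitude, longitude,
    year, month) and columns ``diatom_ugC`` and ``dinoflagellate_ugC``;
    a group absent from a sampled cell gets biomass 0.
    """
    if (records["abundance"] < 0).any():
        raise ValueError("abundances must be non-negative")
    if not records["month"].between(1, 12).all():
        raise ValueError("month must be in 1..12")
    if not records["latitude"].between(-90, 90).all():
        raise ValueError("latitude must be in [-90, 90]")
    carbon = traits.set_index("taxon")["carbon_pg"]
    unknown = set(records["taxon"]) - set(carbon.index)
    if unknown:
        raise KeyError(f"taxa without trait entries: {sorted(unknown)[:5]}")
    df = records.copy()
    df["biomass_ug"] = df["abundance"].to_numpy() * carbon.loc[df["taxon"]].to_numpy() / PG_PER_UG
    wide = (df.pivot_table(index=SAMPLE_KEY, columns="group",
                           values="biomass_ug", aggfunc="sum", fill_value=0.0)
              .reindex(columns=list(GROUPS), fill_value=0.0)
              .reset_index())
    wide.columns.name = None
    return wide.rename(columns={"diatom": "diatom_ugC",
                                "dinoflagellate": "dinoflagellate_ugC"})
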
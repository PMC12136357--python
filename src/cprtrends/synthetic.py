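"""Synthetic plankton-recorder-like data with known generative truth.

Emulates the joint structure of a North Atlantic functional-group biomass
survey: five biogeographic provinces (categorical labels with declared
latitude spans), 2.5° latitude bands, monthly sampling over 1960-2017,
seasonal cycles, latitudinal gradients, linear interannual trends, a
response to the sea-surface-temperature anomaly, and excess zero bins
(~5% for diatoms, ~24% for dinoflagellates, enriched in the two
northernmost provinces).

Everything is driven by a :class:`GenerativeParams` object whose default
values define the simulated study conditions; the same object is written
to ``truth.yaml`` so parameter-recovery tests can compare posterior
estimates against the exact generating values.  The logit diatom index is
not simulated separately: with q and r the group biomasses,
logit(q/(q+r)) = ln q - ln r, so its generating effects are the
differences of the two groups' effects (see :meth:`GenerativeParams.index_effects`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .aggregate import decade_label
from .biomass import GROUPS, PG_PER_UG, cell_carbon

PROVINCES = ("ARCT", "SARC", "NWCS", "NADR", "NECS")

#: Declared latitude spans (°N), mimicking the ARCT/SARC/NWCS/NADR/NECS
#: Longhurst-province extents; multiples of 2.5° so band centers align.
LAT_RANGES = {
    "ARCT": (60.0, 72.5),
    "SARC": (55.0, 67.5),
    "NWCS": (37.5, 47.5),
    "NADR": (42.5, 52.5),
    "NECS": (47.5, 60.0),
}

#: Nominal longitude spans (°E) used only to place synthetic samples;
#: longitude carries no signal and is discarded during binning.
LON_RANGES = {
    "ARCT": (-30.0, 0.0),
    "SARC": (-40.0, -5.0),
    "NWCS": (-70.0, -48.0),
    "NADR": (-35.0, -10.0),
    "NECS": (-10.0, 5.0),
}

BAND_WIDTH = 2.5
YEAR_ZERO = 1960


def _seasonal(base: float, amplitude: float, peak_month: int) -> np.ndarray:
    months = np.arange(1, 13)
    return base + amplitude * np.cos(2 * np.pi * (months - peak_month) / 12.0)


def _per_province(values) -> dict:
    if np.isscalar(values):
        return {p: float(values) for p in PROVINCES}
    return dict(values)


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the synthetic survey.

    Biomass effects are on the natural-log µg C scale per functional
    group and province: 12 month effects (absorbing the province mean),
    a latitudinal gradient (per °lat, about the province mean latitude),
    a linear interannual trend (per year, centered on 1960), an SST
    anomaly effect (per °C) and a residual sd.  Optional decade step
    effects (default all zero) support the Time-Space variant.  The SST
    field has the same decomposition in °C.  Zero-inflation probabilities
    give the chance that a group is entirely absent from a bin.
    """

    provinces: tuple = PROVINCES
    lat_ranges: dict = field(default_factory=lambda: dict(LAT_RANGES))
    years: tuple = (1960, 2017)
    # per group ("diatom"/"dinoflagellate"), per province
    month_effects: dict = None
    lat_gradient: dict = None
    trend: dict = None
    anomaly_effect: dict = None
    resid_sd: dict = None
    #: within-bin correlation of the two groups' log-biomass residuals,
    #: emulating shared tow-level variability (filtered volume, ship speed)
    #: that cancels in the biomass ratio
    resid_corr: float = 0.45
    zero_inflation: dict = None
    decade_effects: dict = None
    # SST model, per province
    sst_month_effects: dict = None
    sst_lat_gradient: dict = None
    sst_trend: dict = None
    sst_resid_sd: dict = None

    def __post_init__(self):
        if self.month_effects is None:
            self._fill_defaults()
        self.validate()

    def _fill_defaults(self):
        # group bases (ln µg C): the index contrast (diatom - dino) carries the
        # province signal (positive only in ARCT); dino bases are kept within
        # ~0.7 log units so group detection floors are commensurable across
        # provinces, as in a survey with one instrument-wide detection limit
        diatom_base = {"ARCT": 8.4, "SARC": 7.9, "NWCS": 7.7, "NADR": 7.9, "NECS": 8.3}
        dino_base = {"ARCT": 7.9, "SARC": 8.2, "NWCS": 8.5, "NADR": 8.3, "NECS": 8.6}
        dino_amp = {"ARCT": 0.8, "SARC": 0.8, "NWCS": 0.25, "NADR": 0.8, "NECS": 0.8}
        self.month_effects = {
            "diatom": {p: _seasonal(diatom_base[p], 1.1, peak_month=5)
                       for p in self.provinces},
            "dinoflagellate": {p: _seasonal(dino_base[p], dino_amp[p], peak_month=7)
                               for p in self.provinces},
        }
        self.lat_gradient = {
            "diatom": {"ARCT": 0.04, "SARC": 0.06, "NWCS": -0.03, "NADR": 0.05, "NECS": 0.03},
            "dinoflagellate": {"ARCT": 0.02, "SARC": -0.03, "NWCS": 0.07, "NADR": -0.03, "NECS": 0.02},
        }
        self.trend = {
            "diatom": {"ARCT": -0.008, "SARC": -0.008, "NWCS": 0.020, "NADR": 0.000, "NECS": 0.019},
            "dinoflagellate": {"ARCT": 0.000, "SARC": -0.020, "NWCS": 0.012, "NADR": -0.014, "NECS": -0.005},
        }
        self.anomaly_effect = {
            "diatom": _per_province(0.20),
            "dinoflagellate": {"ARCT": 0.35, "SARC": 0.35, "NWCS": 0.22, "NADR": 0.35, "NECS": 0.35},
        }
        self.resid_sd = {"diatom": _per_province(0.8),
                         "dinoflagellate": _per_province(0.8)}
        self.zero_inflation = {
            "diatom": _per_province(0.05),
            "dinoflagellate": {"ARCT": 0.27, "SARC": 0.27, "NWCS": 0.22, "NADR": 0.22, "NECS": 0.22},
        }
        n_dec = len(self.decades())
        self.decade_effects = {g: {p: np.zeros(n_dec) for p in self.provinces}
                               for g in GROUPS}
        sst_mean = {"ARCT": 2.0, "SARC": 6.0, "NWCS": 10.0, "NADR": 12.0, "NECS": 11.0}
        sst_amp = {"ARCT": 4.0, "SARC": 4.0, "NWCS": 6.0, "NADR": 4.0, "NECS": 4.0}
        self.sst_month_effects = {p: _seasonal(sst_mean[p], sst_amp[p], peak_month=8)
                                  for p in self.provinces}
        self.sst_lat_gradient = _per_province(-0.3)
        self.sst_trend = _per_province(0.015)
        self.sst_resid_sd = _per_province(1.0)

    def validate(self):
        for g in GROUPS:
            for p in self.provinces:
                if len(np.atleast_1d(self.month_effects[g][p])) != 12:
                    raise ValueError(f"need 12 month effects for {g}/{p}")
                if not self.resid_sd[g][p] >= 0:
                    raise ValueError("residual sd must be >= 0")
                if not 0.0 <= self.zero_inflation[g][p] <= 1.0:
                    raise ValueError("zero-inflation probability must be in [0, 1]")
        if not -1.0 <= self.resid_corr <= 1.0:
            raise ValueError("resid_corr must be in [-1, 1]")
        for p in self.provinces:
            if not self.sst_resid_sd[p] >= 0:
                raise ValueError("SST residual sd must be >= 0")

    # -- derived structure -------------------------------------------------
    def bands(self, province: str) -> np.ndarray:
        lo, hi = self.lat_ranges[province]
        return np.arange(lo + BAND_WIDTH / 2, hi, BAND_WIDTH)

    def mean_latitude(self, province: str) -> float:
        return float(np.mean(self.bands(province)))

    def decades(self) -> np.ndarray:
        return np.unique(decade_label(np.arange(self.years[0], self.years[1] + 1)))

    def index_effects(self, province: str) -> dict:
        """Generating effects of the logit diatom index (diatom minus dino)."""
        d, f = "diatom", "dinoflagellate"
        return {
            "month_effects": np.asarray(self.month_effects[d][province], float)
            - np.asarray(self.month_effects[f][province], float),
            "lat_gradient": self.lat_gradient[d][province] - self.lat_gradient[f][province],
            "trend": self.trend[d][province] - self.trend[f][province],
            "anomaly_effect": self.anomaly_effect[d][province] - self.anomaly_effect[f][province],
            "resid_sd": float(np.sqrt(
                self.resid_sd[d][province] ** 2 + self.resid_sd[f][province] ** 2
                - 2 * self.resid_corr * self.resid_sd[d][province]
                * self.resid_sd[f][province])),
        }

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, np.ndarray):
                return [float(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            return x
        return {
            "provinces": list(self.provinces),
            "lat_ranges": {p: list(self.lat_ranges[p]) for p in self.provinces},
            "years": list(self.years),
            "month_effects": conv(self.month_effects),
            "lat_gradient": conv(self.lat_gradient),
            "trend": conv(self.trend),
            "anomaly_effect": conv(self.anomaly_effect),
            "resid_sd": conv(self.resid_sd),
            "resid_corr": float(self.resid_corr),
            "zero_inflation": conv(self.zero_inflation),
            "decade_effects": conv(self.decade_effects),
            "sst_month_effects": conv(self.sst_month_effects),
            "sst_lat_gradient": conv(self.sst_lat_gradient),
            "sst_trend": conv(self.sst_trend),
            "sst_resid_sd": conv(self.sst_resid_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        d["provinces"] = tuple(d["provinces"])
        d["years"] = tuple(d["years"])
        d["lat_ranges"] = {p: tuple(v) for p, v in d["lat_ranges"].items()}
        for key in ("month_effects", "decade_effects"):
            d[key] = {g: {p: np.asarray(v, float) for p, v in sub.items()}
                      for g, sub in d[key].items()}
        d["sst_month_effects"] = {p: np.asarray(v, float)
                                  for p, v in d["sst_month_effects"].items()}
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# taxon traits
# --------------------------------------------------------------------------

def generate_taxon_table(n_diatoms: int, n_dinos: int, seed: int,
                         diatom_median_um3: float = 1e3,
                         dino_median_um3: float = 1e4,
                         sdlog: float = 1.0,
                         with_missing: bool = True) -> pd.DataFrame:
    """Synthetic trait table: taxon id, group, mean cell volume (µm³).

    Volumes are log-normal around group medians (diatoms 10³ µm³,
    dinoflagellates 10⁴ µm³ by default, sdlog 1).  When a group has at
    least two taxa and ``with_missing`` is set, its last taxon gets a
    missing volume to exercise the downstream size-imputation rule.
    """
    if n_diatoms < 1 or n_dinos < 1:
        raise ValueError("need at least one taxon per group")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, median in (("diatom", n_diatoms, diatom_median_um3),
                             ("dinoflagellate", n_dinos, dino_median_um3)):
        vols = np.exp(rng.normal(np.log(median), sdlog, size=n))
        for i in range(n):
            v = vols[i]
            if with_missing and n >= 2 and i == n - 1:
                v = np.nan
            rows.append({"taxon": f"{group[:4]}_{i:03d}", "group": group,
                         "volume_um3": v})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# SST field
# --------------------------------------------------------------------------

def simulate_sst(params: GenerativeParams, seed: int,
                 provinces=None, years=None) -> pd.DataFrame:
    """Monthly SST on the full (province, band, month, year) grid.

    SST = month effect + lat gradient * (lat - mean lat)
        + trend * (year - 1960) + Normal(0, sd²).

    The realized residual is kept in ``anomaly_true``: it is the exact
    anomaly the biomass simulator responds to, and the quantity the SST
    anomaly model should recover.
    """
    provinces = list(provinces or params.provinces)
    if years is None:
        years = np.arange(params.years[0], params.years[1] + 1)
    years = np.asarray(years)
    if years.size == 0:
        raise ValueError("empty year range")
    # sub-stream distinct from the other simulators at the same seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    frames = []
    for prov in provinces:
        bands = params.bands(prov)
        if bands.size == 0:
            raise ValueError(f"province {prov} has an empty latitude grid")
        lbar = params.mean_latitude(prov)
        grid = pd.MultiIndex.from_product(
            [bands, years, np.arange(1, 13)], names=["lat_band", "year", "month"]
        ).to_frame(index=False)
        m = grid["month"].to_numpy() - 1
        mu = (np.asarray(params.sst_month_effects[prov], float)[m]
              + params.sst_lat_gradient[prov] * (grid["lat_band"].to_numpy() - lbar)
              + params.sst_trend[prov] * (grid["year"].to_numpy() - YEAR_ZERO))
        resid = rng.normal(0.0, params.sst_resid_sd[prov], size=len(grid))
        grid.insert(0, "province", prov)
        grid["sst"] = mu + resid
        grid["anomaly_true"] = resid
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# biomass simulation
# --------------------------------------------------------------------------

def simulate_bins(params: GenerativeParams, sst: pd.DataFrame,
                  seed: int) -> pd.DataFrame:
    """True binned group biomasses for every SST grid cell.

    For each cell and group, draws ln(biomass µg C) from the linear
    predictor (month + latitude + trend + anomaly effect * realized SST
    residual + decade step) plus Normal(0, sd²) noise, then censors the
    group at its detection limit: the zero-inflation probability gives
    the fraction of a province's lowest-biomass cells recorded as zero.
    Cells where both groups are zeroed are dropped (nothing was observed
    there).  Output columns match
    :func:`cprtrends.aggregate.aggregate_bins` before imputation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    decades = params.decades()
    dec_index = {d: i for i, d in enumerate(decades)}
    out = sst[["province", "lat_band", "year", "month"]].copy()
    out["decade"] = decade_label(out["year"])
    anom = sst["anomaly_true"].to_numpy()
    m = out["month"].to_numpy() - 1
    d_idx = np.vectorize(dec_index.get)(out["decade"].to_numpy())
    keep_any = np.zeros(len(out), dtype=bool)
    # correlated group residuals: shared tow-level component z1
    z1 = rng.standard_normal(len(out))
    z2 = rng.standard_normal(len(out))
    rho = params.resid_corr
    eps = {"diatom": z1,
           "dinoflagellate": rho * z1 + np.sqrt(1.0 - rho ** 2) * z2}
    for group, col in (("diatom", "diatom_ugC"), ("dinoflagellate", "dinoflagellate_ugC")):
        mu = np.empty(len(out))
        for prov in params.provinces:
            sel = (out["province"] == prov).to_numpy()
            if not sel.any():
                continue
            lbar = params.mean_latitude(prov)
            mu[sel] = (np.asarray(params.month_effects[group][prov], float)[m[sel]]
                       + params.lat_gradient[group][prov]
                       * (out.loc[sel, "lat_band"].to_numpy() - lbar)
                       + params.trend[group][prov]
                       * (out.loc[sel, "year"].to_numpy() - YEAR_ZERO)
                       + params.anomaly_effect[group][prov] * anom[sel]
                       + np.asarray(params.decade_effects[group][prov], float)[d_idx[sel]])
            mu[sel] += params.resid_sd[group][prov] * eps[group][sel]
        biomass = np.exp(mu)
        # zeros emulate a detection limit: the configured fraction of a
        # province's lowest-biomass cells is recorded as absent, so the
        # downstream half-minimum imputation lands near the censored truth
        zero = np.zeros(len(out), dtype=bool)
        for prov in params.provinces:
            sel = np.flatnonzero((out["province"] == prov).to_numpy())
            k = int(np.floor(params.zero_inflation[group][prov] * sel.size))
            if k > 0:
                order = np.argsort(biomass[sel])
                zero[sel[order[:k]]] = True
        biomass[zero] = 0.0
        out[col] = biomass
        keep_any |= ~zero
    return out.loc[keep_any].reset_index(drop=True)


def simulate_abundance(params: GenerativeParams, traits: pd.DataFrame,
                       sst: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Taxon-resolved abundance records realizing the binned biomass truth.

    Each surviving (province, band, month, year) cell becomes one sample
    located at the band center with a random longitude inside the
    province's nominal span.  A group's cell biomass is partitioned
    across that group's known-volume taxa with symmetric Dirichlet(1)
    weights, and each taxon's abundance is its biomass share divided by
    its per-cell carbon, so that summing abundance x carbon downstream
    reconstructs the cell biomass exactly.
    """
    missing_groups = set(GROUPS) - set(traits["group"])
    if missing_groups:
        raise ValueError(f"traits must cover both groups; missing {missing_groups}")
    bins = simulate_bins(params, sst, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    taxa = {}
    for group in GROUPS:
        sub = traits[(traits["group"] == group) & traits["volume_um3"].notna()]
        if sub.empty:
            raise ValueError(f"no {group} taxon with known volume to partition over")
        taxa[group] = (sub["taxon"].to_numpy(),
                       cell_carbon(sub["volume_um3"].to_numpy(), group))
    records = []
    for prov in params.provinces:
        lon_lo, lon_hi = LON_RANGES.get(prov, (-30.0, 0.0))
        sub = bins[bins["province"] == prov]
        lons = rng.uniform(lon_lo, lon_hi, size=len(sub))
        for (row, lon) in zip(sub.itertuples(index=False), lons):
            for group, col in (("diatom", "diatom_ugC"),
                               ("dinoflagellate", "dinoflagellate_ugC")):
                biomass_ug = getattr(row, col)
                if biomass_ug == 0.0:
                    continue
                names, carbons = taxa[group]
                w = rng.dirichlet(np.ones(len(names)))
                abund = w * biomass_ug * PG_PER_UG / carbons
                for t, a in zip(names, abund):
                    records.append((t, group, a, row.lat_band, lon,
                                    row.year, row.month, prov))
    return pd.DataFrame.from_records(
        records, columns=["taxon", "group", "abundance", "latitude",
                          "longitude", "year", "month", "province"])


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_sst(sst: pd.DataFrame, path) -> None:
    """Write the SST table as CSV, or NetCDF when the path ends in .nc."""
    path = str(path)
    if path.endswith(".nc"):
        import xarray as xr
        ds = xr.Dataset.from_dataframe(
            sst.set_index(["province", "lat_band", "year", "month"]))
        ds.to_netcdf(path, engine="scipy")
    else:
        sst.to_csv(path, index=False)


def read_sst(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".nc"):
        import xarray as xr
        df = (xr.open_dataset(path, engine="scipy").to_dataframe()
              .dropna(subset=["sst"]).reset_index())
        return df
    return pd.read_csv(path)
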
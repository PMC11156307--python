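"""Synthetic shelf-sea study system.

Generates every input the projection pipeline consumes: a fine-resolution
present-day environmental stack, coarse multi-member scenario stacks for the
historical and four future windows, point trawl surveys with known Gaussian
niche structure, per-species bioeconomic reference parameters, and the
geography (two ports, a two-jurisdiction EEZ split, a gridded effort field).

The domain is a Bering/Chukchi-like box: colder and icier towards the north,
primary production peaking mid-basin, depth increasing offshore (westward),
and a land strip along the eastern edge so that ports sit on the coast.
Realism is statistical, not geographic.

All randomness flows from ``SyntheticConfig.seed`` through fixed, named
streams, so a config fully determines every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .config import (
    ENV_VARIABLES,
    FUTURE_PERIODS,
    HISTORICAL_PERIOD,
    PRESENT_PERIOD,
    SyntheticConfig,
    trend_weight,
)
from .grids import cell_centers, clamp_layer, make_layer, smooth_field

# independent substreams per generator, all rooted at config.seed
_STREAM_ENV = 11
_STREAM_NICHE = 23
_STREAM_SURVEY = 37
_STREAM_PARAMS = 41
_STREAM_GEO = 53

#: number of fine-grid columns along the eastern boundary treated as land
N_LAND_COLUMNS = 2

DYNAMIC_VARIABLES = ("WSST", "WSIC", "WSBT", "SSBT", "SNPP")

SURVEY_COLUMNS = ("year", "lon", "lat", "species", "cpue") + ENV_VARIABLES


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


@dataclass
class ClimateFields:
    """Bundle of generated environmental stacks.

    fine: present-day layers on the fine grid (NaN over land).
    coarse_hist: historical-window layers per pseudo-GCM member.
    coarse_future: future layers with dims (scenario, period, member).
    """

    fine: xr.Dataset
    marine_mask: xr.DataArray
    coarse_hist: xr.Dataset
    coarse_future: xr.Dataset


@dataclass
class SpeciesNiche:
    """Gaussian environmental response of one species.

    Expected CPUE is ``max_density`` times the product of three Gaussian
    kernels in summer bottom temperature, depth, and summer net primary
    production; it equals ``max_density`` exactly at the joint optimum.
    """

    species: str
    ssbt_opt: float
    ssbt_breadth: float
    depth_opt: float
    depth_breadth: float
    snpp_opt: float
    snpp_breadth: float
    max_density: float
    sigma: float = 0.3
    cold_optimum: bool = False

    def __post_init__(self) -> None:
        if min(self.ssbt_breadth, self.depth_breadth, self.snpp_breadth) <= 0:
            raise ValueError("niche breadths must be positive")
        if self.max_density <= 0:
            raise ValueError("max_density must be positive")

    def expected_cpue(self, ssbt, depth, snpp):
        """Noise-free CPUE (kg/km2) at the given covariate values."""
        z = (
            ((np.asarray(ssbt) - self.ssbt_opt) / self.ssbt_breadth) ** 2
            + ((np.asarray(depth) - self.depth_opt) / self.depth_breadth) ** 2
            + ((np.asarray(snpp) - self.snpp_opt) / self.snpp_breadth) ** 2
        )
        return self.max_density * np.exp(-0.5 * z)


def default_niches(config: SyntheticConfig) -> list[SpeciesNiche]:
    """Seeded species pool: half cold-optimum, half warm-optimum taxa."""
    rng = _rng(config, _STREAM_NICHE)
    n = config.n_species
    niches = []
    for i in range(n):
        cold = i < (n + 1) // 2
        if cold:
            opt = rng.uniform(-0.5, 1.8)
        else:
            opt = rng.uniform(3.0, 5.0)
        niches.append(
            SpeciesNiche(
                species=f"sp{i + 1:02d}",
                ssbt_opt=float(opt),
                ssbt_breadth=float(rng.uniform(1.0, 2.0)),
                depth_opt=float(rng.uniform(40.0, 150.0)),
                depth_breadth=float(rng.uniform(60.0, 160.0)),
                snpp_opt=float(rng.uniform(400.0, 700.0)),
                snpp_breadth=float(rng.uniform(150.0, 300.0)),
                max_density=float(rng.uniform(30.0, 200.0)),
                sigma=config.cpue_sigma,
                cold_optimum=cold,
            )
        )
    return niches


# ---------------------------------------------------------------------------
# environment


def _fine_present(config: SyntheticConfig, rng: np.random.Generator):
    lon = cell_centers(config.lon_min, config.lon_max, config.fine_res)
    lat = cell_centers(config.lat_min, config.lat_max, config.fine_res)
    t = (lat - config.lat_min) / (config.lat_max - config.lat_min)
    u = (lon - config.lon_min) / (config.lon_max - config.lon_min)
    T, U = np.meshgrid(t, u, indexing="ij")
    shape = T.shape

    # steep meridional gradient: subarctic south (~7 degC) to Arctic north
    # (~-3 degC), so the basin keeps a cold refuge at its poleward end
    ssbt = 7.0 - 10.0 * T + 0.6 * smooth_field(rng, shape)
    wsbt = ssbt - 1.5 + 0.3 * smooth_field(rng, shape)
    wsst = 5.0 - 9.0 * T + 0.8 * smooth_field(rng, shape)
    wsic = np.clip(115.0 * T - 10.0 + 8.0 * smooth_field(rng, shape), 0.0, 100.0)
    snpp = np.clip(
        350.0
        + 400.0 * np.exp(-(((T - 0.55) / 0.18) ** 2))
        + 40.0 * smooth_field(rng, shape),
        0.0,
        None,
    )
    depth = np.clip(
        20.0 + 2500.0 * (1.0 - U) ** 2.5 + 60.0 * smooth_field(rng, shape),
        5.0,
        None,
    )

    marine = np.ones(shape, dtype=bool)
    marine[:, -N_LAND_COLUMNS:] = False

    fields = {
        "WSST": wsst,
        "WSIC": wsic,
        "WSBT": wsbt,
        "SSBT": ssbt,
        "SNPP": snpp,
        "depth": depth,
    }
    layers = {}
    for name, vals in fields.items():
        vals = np.where(marine, vals, np.nan)
        layers[name] = make_layer(vals, lon, lat, name, period=PRESENT_PERIOD)
    fine = xr.Dataset(layers, attrs={"period": PRESENT_PERIOD, "scenario": ""})
    mask = xr.DataArray(
        marine, dims=("lat", "lon"), coords={"lat": lat, "lon": lon}
    )
    return fine, mask


def _coarsen(da: xr.DataArray, block: int) -> xr.DataArray:
    out = da.coarsen(lat=block, lon=block, boundary="exact").mean()
    out.attrs.update(da.attrs)
    out.attrs["res"] = float(da.attrs.get("res", np.nan)) * block
    return out


def _trend_field(var, spec, weight, hist, tnorm, marine):
    """Scenario/period anomaly for one variable on the coarse grid.

    Warming is polar-damped — shape (1 - 0.7 t) in the normalised latitude
    t, rescaled so its marine-mean equals the configured amplitude — and
    ice loss is weighted by (1 - t^2), so the far north keeps its winter
    ice. Both emulate the Arctic refuge of a subarctic-to-Arctic shelf.
    """
    if var in ("WSST", "WSBT", "SSBT"):
        shape = 1.0 - 0.7 * tnorm
        shape = shape / float(shape.where(marine).mean())
        trend = spec.warming_c * weight * shape
        return trend, spec.warming_c * weight
    if var == "WSIC":
        trend = -spec.ice_decline_frac * weight * hist * (1.0 - tnorm**2)
        scale = spec.ice_decline_frac * weight * float(np.nanmean(np.abs(hist)))
        return trend, scale
    if var == "SNPP":
        trend = -spec.npp_decline_frac * weight * hist
        scale = spec.npp_decline_frac * weight * float(np.nanmean(np.abs(hist)))
        return trend, scale
    raise KeyError(var)


def generate_environment(config: SyntheticConfig) -> ClimateFields:
    """Generate the full environmental input stack for one seed.

    Coarse historical members share a block-mean base derived from the fine
    present-day field plus a persistent member bias (the pseudo-GCM's
    climatology error). Future members add a scenario- and period-dependent
    trend plus a small member texture whose amplitude scales with the trend,
    so a zero-forcing scenario reproduces the historical stack exactly and
    the cross-member mean anomaly equals the imposed trend up to texture.
    """
    rng = _rng(config, _STREAM_ENV)
    fine, marine = _fine_present(config, rng)
    block = config.block

    coarse_marine = marine.coarsen(lat=block, lon=block, boundary="exact").mean() > 0

    members = np.arange(config.n_members)
    bias_scale = {"WSST": 0.3, "WSBT": 0.3, "SSBT": 0.3, "WSIC": 3.0, "SNPP": 20.0}

    hist_vars = {}
    base = {}
    biases = {}
    cshape = (coarse_marine.sizes["lat"], coarse_marine.sizes["lon"])
    for var in DYNAMIC_VARIABLES:
        base[var] = _coarsen(fine[var], block)
        biases[var] = [
            bias_scale[var] * smooth_field(rng, cshape, sigma=1.5)
            for _ in members
        ]
        stack = [
            clamp_layer(
                (base[var] + biases[var][m]).where(coarse_marine)
            )
            for m in members
        ]
        hist_vars[var] = xr.concat(stack, dim="member").assign_coords(
            member=members
        )
        hist_vars[var].attrs = dict(base[var].attrs, period=HISTORICAL_PERIOD)
    coarse_hist = xr.Dataset(hist_vars, attrs={"period": HISTORICAL_PERIOD})

    clat = coarse_marine["lat"]
    tnorm_1d = (clat - config.lat_min) / (config.lat_max - config.lat_min)
    tnorm = tnorm_1d * xr.ones_like(coarse_marine, dtype=float)

    scen_names = [s.name for s in config.scenarios]
    fut_vars = {}
    for var in DYNAMIC_VARIABLES:
        per_scen = []
        for spec in config.scenarios:
            per_period = []
            for period in FUTURE_PERIODS:
                w = trend_weight(period)
                trend, scale = _trend_field(
                    var, spec, w, base[var], tnorm, coarse_marine
                )
                per_member = []
                for m in members:
                    texture = (
                        config.texture_frac
                        * scale
                        * smooth_field(rng, cshape, sigma=1.5)
                    )
                    vals = base[var] + biases[var][m] + trend + texture
                    per_member.append(clamp_layer(vals.where(coarse_marine)))
                per_period.append(
                    xr.concat(per_member, dim="member").assign_coords(
                        member=members
                    )
                )
            per_scen.append(
                xr.concat(per_period, dim="period").assign_coords(
                    period=list(FUTURE_PERIODS)
                )
            )
        fut_vars[var] = xr.concat(per_scen, dim="scenario").assign_coords(
            scenario=scen_names
        )
    coarse_future = xr.Dataset(fut_vars)

    return ClimateFields(
        fine=fine,
        marine_mask=mask_bool(marine),
        coarse_hist=coarse_hist,
        coarse_future=coarse_future,
    )


def mask_bool(mask: xr.DataArray) -> xr.DataArray:
    return mask.astype(bool)


# ---------------------------------------------------------------------------
# surveys


def truth_surface(niche: SpeciesNiche, env: xr.Dataset) -> xr.DataArray:
    """Noise-free expected CPUE of a species on an environmental stack."""
    out = xr.apply_ufunc(
        niche.expected_cpue, env["SSBT"], env["depth"], env["SNPP"]
    )
    out.name = niche.species
    out.attrs = {
        "variable": "cpue_true",
        "units": "kg/km2",
        "period": env.attrs.get("period", ""),
        "scenario": env.attrs.get("scenario", ""),
    }
    return out


def sample_surveys(
    env: xr.Dataset,
    niches: Sequence[SpeciesNiche],
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Simulate annual trawl stations and per-species CPUE.

    Each station is a uniformly drawn marine cell; every species is recorded
    at every station. CPUE is the niche's expected value at the cell times a
    multiplicative lognormal error exp(N(0, sigma^2)).
    """
    if not niches:
        raise ValueError("niches must be non-empty")
    rng = _rng(config, _STREAM_SURVEY)
    marine = np.isfinite(env["SSBT"].values)
    iy, ix = np.nonzero(marine)
    if iy.size == 0:
        raise ValueError("environment has no marine cells")
    lat = env["lat"].values
    lon = env["lon"].values

    rows = []
    for year in config.years:
        k = rng.integers(0, iy.size, size=config.n_surveys_per_year)
        for cell in k:
            r, c = iy[cell], ix[cell]
            cov = {v: float(env[v].values[r, c]) for v in ENV_VARIABLES}
            for niche in niches:
                mu = niche.expected_cpue(
                    cov["SSBT"], cov["depth"], cov["SNPP"]
                )
                noise = (
                    np.exp(rng.normal(0.0, niche.sigma))
                    if niche.sigma > 0
                    else 1.0
                )
                rows.append(
                    {
                        "year": int(year),
                        "lon": float(lon[c]),
                        "lat": float(lat[r]),
                        "species": niche.species,
                        "cpue": float(mu * noise),
                        **cov,
                    }
                )
    df = pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))
    if df.empty:
        df = df.astype({"year": int})
    return df


# ---------------------------------------------------------------------------
# reference parameters

#: Pella-Tomlinson shape by management group: groundfish stocks carry the
#: value giving B_MSY/K = 0.40, crab stocks the value giving 0.35.
PT_SHAPE = {"groundfish": 0.188, "crab": -0.093}

PARAM_COLUMNS = (
    "species",
    "group",
    "g",
    "phi",
    "u_msy",
    "price",
    "f_bar",
    "b_bar",
    "beta",
)


def generate_reference_params(
    n_species: int, seed: int = 0, crab_index: int = -1
) -> pd.DataFrame:
    """Seeded per-species bioeconomic reference table.

    One species (by default the last) is flagged as a crab stock; the rest
    are groundfish. Ranges reflect order-of-magnitude realism for northern
    shelf fisheries: growth rates 0.1-0.5 /yr, exploitation rates at MSY
    0.05-0.35, ex-vessel prices 400-3000 USD/mt (2012 baseline), open-access
    equilibria with effort above (f_bar > 1) and biomass below (b_bar < 1)
    their MSY levels, and a fixed nonlinear cost exponent beta = 1.3.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_PARAMS]))
    crab_index = crab_index % n_species
    rows = []
    for i in range(n_species):
        group = "crab" if i == crab_index else "groundfish"
        g = float(rng.uniform(0.10, 0.50))
        # U_MSY = catch/biomass at MSY tracks g = MSY/B_MSY up to
        # standardisation error, so the two are drawn coherently
        u_msy = float(np.clip(g * rng.uniform(0.8, 1.2), 0.05, 0.95))
        rows.append(
            {
                "species": f"sp{i + 1:02d}",
                "group": group,
                "g": g,
                "phi": PT_SHAPE[group],
                "u_msy": u_msy,
                "price": float(rng.uniform(400.0, 3000.0)),
                "f_bar": float(rng.uniform(1.1, 2.2)),
                "b_bar": float(rng.uniform(0.2, 0.7)),
                "beta": 1.3,
            }
        )
    return pd.DataFrame(rows, columns=list(PARAM_COLUMNS))


def write_reference_params(params: pd.DataFrame, path) -> None:
    params.to_csv(path, index=False)


def read_reference_params(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter file missing columns: {sorted(missing)}")
    return df[list(PARAM_COLUMNS)]


# ---------------------------------------------------------------------------
# geography


@dataclass
class Geography:
    """Ports, EEZ jurisdiction masks, and the aggregated effort field."""

    ports: pd.DataFrame
    eez: dict[str, xr.DataArray] = field(default_factory=dict)
    effort: xr.DataArray | None = None
    effort_threshold_hours: float = 1000.0


def generate_geography(
    config: SyntheticConfig, marine_mask: xr.DataArray
) -> Geography:
    """Two ports, a longitude-split EEZ, and an effort field.

    The southern port emulates the major fishing port, the northern one the
    Arctic port; both sit on marine cells adjacent to the eastern land
    strip. Effort is low-level background everywhere plus exactly
    ``config.n_high_effort_cells`` cells above the fishing-ground threshold,
    clustered around the southern port.
    """
    rng = _rng(config, _STREAM_GEO)
    lat = marine_mask["lat"].values
    lon = marine_mask["lon"].values
    marine = marine_mask.values

    # ports: easternmost marine column, near the south and north edges
    coast_col = int(np.max(np.nonzero(marine.any(axis=0))[0]))
    south_row = int(np.searchsorted(lat, config.lat_min + 1.0))
    north_row = int(np.searchsorted(lat, config.lat_max - 2.0))
    ports = pd.DataFrame(
        [
            {"port": "south_port", "lon": float(lon[coast_col]), "lat": float(lat[south_row])},
            {"port": "north_port", "lon": float(lon[coast_col]), "lat": float(lat[north_row])},
        ]
    )

    split = 0.5 * (config.lon_min + config.lon_max)
    lon2d = np.broadcast_to(lon[None, :], marine.shape)
    coords = {"lat": lat, "lon": lon}
    eez = {
        "east": xr.DataArray(
            marine & (lon2d >= split), dims=("lat", "lon"), coords=coords
        ),
        "west": xr.DataArray(
            marine & (lon2d < split), dims=("lat", "lon"), coords=coords
        ),
    }

    thr = config.effort_threshold_hours
    background = rng.uniform(0.0, 0.8 * thr, size=marine.shape)
    effort = np.where(marine, background, np.nan)
    # pick the k marine cells closest to the southern port
    from .grids import haversine_km

    la2d = np.broadcast_to(lat[:, None], marine.shape)
    d = haversine_km(lon2d, la2d, ports.lon[0], ports.lat[0])
    d = np.where(marine, d, np.inf)
    k = min(config.n_high_effort_cells, int(marine.sum()))
    flat = np.argsort(d, axis=None)[:k]
    hot = np.unravel_index(flat, marine.shape)
    effort[hot] = thr * (1.0 + rng.uniform(0.1, 2.0, size=k))
    effort_da = xr.DataArray(
        effort,
        dims=("lat", "lon"),
        coords=coords,
        name="effort",
        attrs={"units": "hours", "variable": "effort"},
    )
    return Geography(
        ports=ports, eez=eez, effort=effort_da, effort_threshold_hours=thr
    )
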
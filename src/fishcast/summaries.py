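"""Spatial diagnostics of projected abundance and bioeconomics.

Covers abundance-weighted centers of gravity (COG) and their decadal shift
rates, percent changes of fleet aggregates relative to the present window,
mean catch potential in 100-km distance rings around ports, and
fishing-ground comparisons between jurisdictions on the high-effort mask.
All distances are great-circle (haversine) on a 6371-km sphere; no map
projection is applied, since planar approximations distort at subarctic
latitudes.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .config import PERIOD_MIDPOINTS, PRESENT_PERIOD
from .grids import area_grid, haversine_km
from . import bioeconomics as be


def center_of_gravity(surface: xr.DataArray) -> tuple[float, float]:
    """Abundance-weighted mean position (lon, lat) of a density surface.

    Weights are density times cell area (true biomass weighting). The
    centroid of a basin split by land can fall on land; that is expected
    and not an error.
    """
    w = (surface * area_grid(surface)).values
    w = np.where(np.isfinite(w), w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("surface has no positive abundance")
    lon2d, lat2d = np.meshgrid(surface["lon"].values, surface["lat"].values)
    return float((w * lon2d).sum() / total), float((w * lat2d).sum() / total)


def shift_rate(
    cog_present: tuple[float, float],
    cog_future: tuple[float, float],
    present_mid_year: float,
    future_mid_year: float,
) -> float:
    """COG displacement speed in km/decade between two window midpoints."""
    decades = (future_mid_year - present_mid_year) / 10.0
    if decades <= 0:
        raise ValueError("future midpoint must be after the present midpoint")
    d = float(
        haversine_km(
            cog_present[0], cog_present[1], cog_future[0], cog_future[1]
        )
    )
    return d / decades


def cog_tracks(
    surfaces: Mapping[tuple[str, str, str], xr.DataArray]
) -> pd.DataFrame:
    """COG and shift rate vs present for every (species, period, scenario).

    ``surfaces`` must include a present-window surface per species (period
    equal to the present label, any scenario tag).
    """
    present = {}
    for (sp, period, scen), surf in surfaces.items():
        if period == PRESENT_PERIOD:
            present[sp] = center_of_gravity(surf)
    rows = []
    for (sp, period, scen), surf in surfaces.items():
        lon, lat = center_of_gravity(surf)
        rate = np.nan
        if period != PRESENT_PERIOD and sp in present:
            rate = shift_rate(
                present[sp],
                (lon, lat),
                PERIOD_MIDPOINTS[PRESENT_PERIOD],
                PERIOD_MIDPOINTS[period],
            )
        rows.append(
            {
                "species": sp,
                "period": period,
                "scenario": scen,
                "cog_lon": lon,
                "cog_lat": lat,
                "shift_rate_km_per_decade": rate,
            }
        )
    return pd.DataFrame(rows)


def percent_change(present_value: float, future_value: float) -> float:
    """Percent change relative to the magnitude of the present value.

    100 * (future - present) / |present|; the absolute denominator keeps
    the sign meaningful when the present value (e.g. a profit) is negative.
    A zero present value is undefined and returned as NaN with a warning.
    """
    if present_value == 0:
        warnings.warn("percent change undefined for zero present value", stacklevel=2)
        return float("nan")
    return 100.0 * (future_value - present_value) / abs(present_value)


def percent_change_table(fleet: pd.DataFrame) -> pd.DataFrame:
    """Future percent changes of MCP/MRP/MPP relative to the present window."""
    rows = []
    base = fleet[fleet["period"] == PRESENT_PERIOD]
    fut = fleet[fleet["period"] != PRESENT_PERIOD]
    for sens, grp in fut.groupby("sensitivity"):
        ref = base[base["sensitivity"] == sens]
        if ref.empty:  # sensitivity ramps anchor at 1.0 in the present
            ref = base[base["sensitivity"] == "base"]
        ref = ref.iloc[0]
        for _, r in grp.iterrows():
            for var in ("MCP", "MRP", "MPP"):
                rows.append(
                    {
                        "scenario": r["scenario"],
                        "period": r["period"],
                        "sensitivity": sens,
                        "variable": var,
                        "percent_change": percent_change(ref[var], r[var]),
                    }
                )
    return pd.DataFrame(rows)


def ring_index(distance_km: np.ndarray, ring_width_km: float) -> np.ndarray:
    """Half-open distance rings ((k-1)w, kw]; a cell at the port is ring 1."""
    idx = np.ceil(np.asarray(distance_km, dtype=float) / ring_width_km).astype(int)
    return np.maximum(idx, 1)


def port_buffer_profile(
    mcp_grid: xr.DataArray,
    port_lon: float,
    port_lat: float,
    ring_width_km: float = 100.0,
    n_rings: int = 10,
    jurisdiction_mask: xr.DataArray | None = None,
) -> pd.DataFrame:
    """Mean per-cell MCP within successive distance rings around a port.

    Cells are assigned to rings by haversine distance from the port to the
    cell center; ring means are taken over marine cells, optionally
    intersected with a jurisdiction mask. Empty rings are reported with a
    NaN mean.
    """
    if ring_width_km <= 0:
        raise ValueError("ring width must be positive")
    lon2d, lat2d = np.meshgrid(mcp_grid["lon"].values, mcp_grid["lat"].values)
    d = haversine_km(lon2d, lat2d, port_lon, port_lat)
    valid = np.isfinite(mcp_grid.values)
    if jurisdiction_mask is not None:
        valid &= jurisdiction_mask.values.astype(bool)
    if not (valid & (d <= n_rings * ring_width_km)).any():
        raise ValueError("no marine cell within the outermost ring")
    rings = ring_index(d, ring_width_km)
    rows = []
    for k in range(1, n_rings + 1):
        sel = valid & (rings == k)
        mean = float(np.mean(mcp_grid.values[sel])) if sel.any() else float("nan")
        rows.append({"ring": k, "n_cells": int(sel.sum()), "mean_mcp": mean})
    return pd.DataFrame(rows)


def fishing_ground_compare(
    effort: xr.DataArray,
    threshold_hours: float,
    surfaces: Mapping[tuple[str, str, str], xr.DataArray],
    jurisdiction_masks: Mapping[str, xr.DataArray],
    params: pd.DataFrame,
    msy_exponent_sign: str = "printed",
) -> pd.DataFrame:
    """Bioeconomic aggregates on the high-effort fishing grounds.

    The fishing-ground mask is effort >= threshold; per jurisdiction the
    full biomass-to-profit chain is run over mask-and-jurisdiction with the
    same species parameter table in every jurisdiction. A jurisdiction with
    an empty mask is reported as missing, not as zero.
    """
    ground = (effort >= threshold_hours) & np.isfinite(effort)
    rows = []
    for name, jmask in jurisdiction_masks.items():
        mask = ground & jmask.astype(bool)
        if not bool(mask.any()):
            periods = sorted({(k[1], k[2]) for k in surfaces})
            for period, scen in periods:
                rows.append(
                    {
                        "jurisdiction": name,
                        "period": period,
                        "scenario": scen,
                        "MCP": np.nan,
                        "MRP": np.nan,
                        "MPP": np.nan,
                        "missing": True,
                    }
                )
            continue
        species_df, fleet = be.bioecon_table(
            surfaces, params, region_mask=mask,
            msy_exponent_sign=msy_exponent_sign,
        )
        for _, r in fleet.iterrows():
            rows.append(
                {
                    "jurisdiction": name,
                    "period": r["period"],
                    "scenario": r["scenario"],
                    "MCP": r["MCP"],
                    "MRP": r["MRP"],
                    "MPP": r["MPP"],
                    "missing": False,
                }
            )
    return pd.DataFrame(rows)
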
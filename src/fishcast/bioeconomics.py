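"""Pella-Tomlinson bioeconomics: MSY, catch, revenue, cost, and profit.

The chain from an abundance surface to fleet economics is:

    B      = integral of predicted density over a region (mt)
    MSY    = g * B * (phi + 1)^(1/phi)          (printed convention)
    MCP    = B * U_MSY                          (maximum catch potential)
    R      = p * MCP                            (ex-vessel revenue, USD)
    c      = p * fbar * bbar * MSY / (g * fbar)^beta
    pi_MSY = R - c * g^beta                     (profit at MSY)
    MRP    = sum_i R_i,   MPP = sum_i pi_MSY_i  (fleet aggregates)

where g is the population growth rate (MSY/B_MSY, per year), phi the
Pella-Tomlinson shape parameter, U_MSY the exploitation rate at MSY, p the
ex-vessel price (USD/mt, constant 2012 dollars), fbar = F/F_MSY and
bbar = B/B_MSY at the open-access bioeconomic equilibrium, and beta > 1 the
nonlinear cost exponent. The cost parameter c is defined so that revenue
exactly equals cost (zero profit) at that equilibrium, where catch is
fbar * bbar * MSY and fishing mortality is fbar * g.

The printed MSY convention uses a positive exponent (phi+1)^(1/phi); with
g = MSY/B_MSY and B read as carrying capacity, internal consistency instead
requires the negative exponent, which equals the B_MSY/K ratio. Both are
implemented behind ``msy_exponent_sign``; see docs/methods.md.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr

from .config import KG_PER_MT, PERIOD_MIDPOINTS
from .grids import area_grid

SENSITIVITY_SCENARIOS = ("base", "costs+20%", "prices+20%", "both+20%")

_SENSITIVITY_BASE_YEAR = 2019.0
_SENSITIVITY_END_YEAR = 2100.0


def _check_shape(phi: float) -> None:
    if phi == 0 or phi <= -1:
        raise ValueError(f"Pella-Tomlinson shape must be > -1 and nonzero, got {phi}")


def pella_tomlinson_bmsy_ratio(phi: float) -> float:
    """Ratio B_MSY / K implied by the Pella-Tomlinson shape parameter.

    (phi+1)^(-1/phi); strictly increasing in phi, with the logistic
    (Graham-Schaefer) value 0.5 at phi = 1 and limit 1/e as phi -> 0.
    """
    _check_shape(phi)
    return float((phi + 1.0) ** (-1.0 / phi))


def integrate_biomass(
    surface: xr.DataArray, region_mask: xr.DataArray | None = None
) -> float:
    """Total biomass (mt) of a density surface over a region.

    Sums density (kg/km2) times cell area (km2) over unmasked marine cells
    and converts kg to metric tons.
    """
    areas = area_grid(surface)
    vals = surface
    if region_mask is not None:
        if region_mask.shape != surface.shape:
            raise ValueError("region mask and surface are on different grids")
        if not bool(region_mask.any()):
            raise ValueError("region mask is empty")
        vals = vals.where(region_mask)
    total_kg = float((vals * areas).sum(skipna=True))
    return total_kg / KG_PER_MT


def msy(
    B: float, g: float, phi: float, exponent_sign: str = "printed"
) -> float:
    """Maximum sustainable yield (mt) from biomass B under growth rate g."""
    _check_shape(phi)
    if B < 0:
        raise ValueError("biomass must be non-negative")
    if exponent_sign == "printed":
        expo = 1.0 / phi
    elif exponent_sign == "bmsy_consistent":
        expo = -1.0 / phi
    else:
        raise ValueError(f"unknown msy exponent convention {exponent_sign!r}")
    return g * B * (phi + 1.0) ** expo


def mcp(B: float, u_msy: float) -> float:
    """Maximum catch potential (mt): biomass times exploitation rate at MSY."""
    if B < 0:
        raise ValueError("biomass must be non-negative")
    if not 0.0 < u_msy <= 1.0:
        raise ValueError("U_MSY must be in (0, 1]")
    return B * u_msy


def revenue(p: float, mcp_mt: float) -> float:
    """Ex-vessel revenue R = p * MCP (USD)."""
    if p < 0:
        raise ValueError("price must be non-negative")
    return p * mcp_mt


def cost_param(
    p: float,
    f_bar: float,
    b_bar: float,
    msy_mt: float,
    g: float,
    beta: float,
    grouping: str = "zero_profit",
) -> float:
    """Cost parameter per unit fishing mortality to the beta.

    c = p * fbar * bbar * MSY / (g * fbar)^beta, the unique grouping under
    which revenue equals cost at the open-access equilibrium (catch
    fbar * bbar * MSY at fishing mortality fbar * g).
    """
    if grouping != "zero_profit":
        raise ValueError(f"unknown cost grouping {grouping!r}")
    if g * f_bar <= 0:
        raise ValueError("g * f_bar must be positive")
    return p * f_bar * b_bar * msy_mt / (g * f_bar) ** beta


def profit_msy(R: float, c: float, g: float, beta: float) -> float:
    """Profit at MSY: revenue minus harvesting cost at fishing mortality g."""
    return R - c * g**beta


def mrp(records: Iterable[float] | pd.Series) -> float:
    """Maximum revenue potential: sum of per-species revenues."""
    return float(np.sum(np.fromiter(records, dtype=float)))


def mpp(records: Iterable[float] | pd.Series) -> float:
    """Maximum profit potential: sum of per-species profits at MSY."""
    return float(np.sum(np.fromiter(records, dtype=float)))


def sensitivity_multiplier(year: float) -> float:
    """Linear ramp reaching +20% at 2100, anchored at 1.0 in 2019."""
    y0, y1 = _SENSITIVITY_BASE_YEAR, _SENSITIVITY_END_YEAR
    if not y0 <= year <= y1:
        raise ValueError(f"year {year} outside [{y0}, {y1}]")
    return 1.0 + 0.2 * (year - y0) / (y1 - y0)


def species_record(
    species: str,
    B_mt: float,
    params: pd.Series,
    period: str,
    scenario: str,
    sensitivity: str = "base",
    msy_exponent_sign: str = "printed",
) -> dict:
    """Full per-species bioeconomic record for one period/scenario.

    Price and cost sensitivity scenarios scale p and/or c by the linear
    ramp evaluated at the window's midpoint year (present windows keep the
    anchor multiplier 1.0).
    """
    if sensitivity not in SENSITIVITY_SCENARIOS:
        raise ValueError(f"unknown sensitivity scenario {sensitivity!r}")
    year = PERIOD_MIDPOINTS[period]
    m = sensitivity_multiplier(max(year, _SENSITIVITY_BASE_YEAR))
    p = float(params["price"])
    g = float(params["g"])
    beta = float(params["beta"])

    msy_mt = msy(B_mt, g, float(params["phi"]), msy_exponent_sign)
    catch = mcp(B_mt, float(params["u_msy"]))
    c = cost_param(p, float(params["f_bar"]), float(params["b_bar"]), msy_mt, g, beta)

    if sensitivity in ("prices+20%", "both+20%"):
        p = p * m
    if sensitivity in ("costs+20%", "both+20%"):
        c = c * m
    R = revenue(p, catch)
    pi = profit_msy(R, c, g, beta)
    return {
        "species": species,
        "period": period,
        "scenario": scenario,
        "sensitivity": sensitivity,
        "B": B_mt,
        "MSY": msy_mt,
        "MCP": catch,
        "R": R,
        "c": c,
        "profit": pi,
    }


def bioecon_table(
    surfaces: dict[tuple[str, str, str], xr.DataArray],
    params: pd.DataFrame,
    region_mask: xr.DataArray | None = None,
    sensitivities: Iterable[str] = ("base",),
    msy_exponent_sign: str = "printed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species-level and fleet-level bioeconomics for a set of surfaces.

    ``surfaces`` maps (species, period, scenario) to abundance surfaces.
    Returns (species table, fleet table) where the fleet table aggregates
    MCP, MRP = sum R and MPP = sum profit per period/scenario/sensitivity.
    """
    pidx = params.set_index("species")
    rows = []
    for (species, period, scenario), surface in surfaces.items():
        B = integrate_biomass(surface, region_mask)
        for sens in sensitivities:
            rows.append(
                species_record(
                    species, B, pidx.loc[species], period, scenario,
                    sensitivity=sens, msy_exponent_sign=msy_exponent_sign,
                )
            )
    species_df = pd.DataFrame(rows)
    fleet = (
        species_df.groupby(["period", "scenario", "sensitivity"], as_index=False)
        .agg(MCP=("MCP", "sum"), MRP=("R", "sum"), MPP=("profit", "sum"))
    )
    return species_df, fleet


def equilibrium_profit(params: pd.Series, msy_mt: float, c: float) -> float:
    """Profit at the open-access equilibrium (should be ~0 by construction)."""
    p = float(params["price"])
    g, beta = float(params["g"]), float(params["beta"])
    f_bar, b_bar = float(params["f_bar"]), float(params["b_bar"])
    catch_eq = f_bar * b_bar * msy_mt
    return p * catch_eq - c * (g * f_bar) ** beta
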
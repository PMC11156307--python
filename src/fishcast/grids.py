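"""Regular lon/lat grid conventions and spherical geometry helpers.

Environmental layers (``EnvGrid`` in the package's vocabulary) are plain
:class:`xarray.DataArray` objects with dims ``("lat", "lon")``, cell-center
coordinates in degrees, NaN for masked (land) cells, and the metadata
attributes ``variable``, ``units``, ``period``, ``scenario`` and ``res``.
Stacks of layers on one grid are :class:`xarray.Dataset` objects. Longitudes
live in [-180, 180).
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .config import EARTH_RADIUS_KM, ENV_UNITS


def cell_centers(lo: float, hi: float, res: float) -> np.ndarray:
    """Cell-center coordinates of a regular axis spanning [lo, hi)."""
    n = int(round((hi - lo) / res))
    return lo + res * (np.arange(n) + 0.5)


def make_layer(
    values: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    variable: str,
    period: str = "",
    scenario: str = "",
) -> xr.DataArray:
    """Wrap a 2-D array as an environmental layer with grid metadata."""
    values = np.asarray(values, dtype=float)
    if values.shape != (lat.size, lon.size):
        raise ValueError(
            f"values shape {values.shape} does not match grid "
            f"({lat.size}, {lon.size})"
        )
    res = float(lon[1] - lon[0]) if lon.size > 1 else float("nan")
    return xr.DataArray(
        values,
        dims=("lat", "lon"),
        coords={"lat": lat, "lon": lon},
        name=variable,
        attrs={
            "variable": variable,
            "units": ENV_UNITS.get(variable, ""),
            "period": period,
            "scenario": scenario,
            "res": res,
        },
    )


def clamp_layer(layer: xr.DataArray) -> xr.DataArray:
    """Apply physical bounds per variable: WSIC in [0, 100], SNPP >= 0."""
    name = layer.attrs.get("variable", layer.name)
    out = layer
    if name == "WSIC":
        out = layer.clip(0.0, 100.0)
    elif name == "SNPP":
        out = layer.clip(min=0.0)
    out.attrs.update(layer.attrs)
    return out


def cell_area_km2(lat: np.ndarray, res_lat: float, res_lon: float) -> np.ndarray:
    """Area of one grid cell at each latitude, km^2.

    Uses the small-cell approximation R*dphi x R*dlambda*cos(phi_center)
    on a sphere of radius 6371 km, so every area-dependent quantity is
    reproducible bit-for-bit.
    """
    dphi = np.deg2rad(res_lat)
    dlam = np.deg2rad(res_lon)
    phi = np.deg2rad(np.asarray(lat, dtype=float))
    return (EARTH_RADIUS_KM * dphi) * (EARTH_RADIUS_KM * dlam * np.cos(phi))


def area_grid(layer: xr.DataArray) -> xr.DataArray:
    """Per-cell area (km^2) broadcast to the layer's grid."""
    lat = layer["lat"].values
    lon = layer["lon"].values
    fallback = float(layer.attrs.get("res", float("nan")))
    res_lat = float(abs(lat[1] - lat[0])) if lat.size > 1 else None
    res_lon = float(abs(lon[1] - lon[0])) if lon.size > 1 else None
    res_lat = res_lat if res_lat is not None else (res_lon or fallback)
    res_lon = res_lon if res_lon is not None else (res_lat or fallback)
    areas = cell_area_km2(lat, res_lat, res_lon)
    grid = np.repeat(areas[:, None], lon.size, axis=1)
    return xr.DataArray(
        grid, dims=("lat", "lon"), coords={"lat": lat, "lon": lon}
    )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere; vectorised."""
    lon1, lat1, lon2, lat2 = (
        np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2)
    )
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def smooth_field(rng: np.random.Generator, shape, sigma: float = 3.0) -> np.ndarray:
    """Zero-mean smooth Gaussian random field (unit marginal scale)."""
    from scipy.ndimage import gaussian_filter

    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma, mode="nearest")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f
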
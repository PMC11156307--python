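"""Readers and writers for grids, tables, and geography.

Grids travel as NetCDF (classic format via the scipy backend, so files stay
readable without compiled HDF5 bindings); surveys and parameter tables as
CSV; ports and EEZ polygons as GeoJSON. Every file records the cell-center
registration convention and the layer metadata (variable, units, period,
scenario) in its attributes, and round-trips losslessly at float64.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

_ENGINE = "scipy"


def write_grid(obj: xr.DataArray | xr.Dataset, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = obj.to_dataset(name=obj.name or "layer") if isinstance(obj, xr.DataArray) else obj
    ds = ds.copy()
    ds.attrs.setdefault("registration", "cell_center")
    ds.attrs = {k: _plain_attr(v) for k, v in ds.attrs.items()}
    for v in ds.data_vars:
        ds[v].attrs = {k: _plain_attr(a) for k, a in ds[v].attrs.items()}
    ds.to_netcdf(path, engine=_ENGINE)


def _plain_attr(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, bool):
        return int(v)
    return v


def read_grid(path) -> xr.Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        out = ds.load()
    _check_regular(out)
    return out


def _check_regular(ds: xr.Dataset) -> None:
    for axis in ("lon", "lat"):
        if axis not in ds.coords:
            continue
        c = ds[axis].values
        if c.size > 2:
            steps = np.diff(c)
            if not np.allclose(steps, steps[0]):
                raise ValueError(f"{axis} axis is not a regular grid")


def write_ports_geojson(ports: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.lon, row.lat]},
            "properties": {"port": row.port},
        }
        for row in ports.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_ports_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = [
        {
            "port": f["properties"]["port"],
            "lon": f["geometry"]["coordinates"][0],
            "lat": f["geometry"]["coordinates"][1],
        }
        for f in data["features"]
    ]
    return pd.DataFrame(rows)


def write_eez_geojson(eez_masks: dict, path) -> None:
    """EEZ jurisdictions as bounding polygons of their masked cells."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for name, mask in eez_masks.items():
        lat = mask["lat"].values
        lon = mask["lon"].values
        res_lat = float(abs(lat[1] - lat[0]))
        res_lon = float(abs(lon[1] - lon[0]))
        iy, ix = np.nonzero(mask.values)
        cells = [
            box(
                lon[c] - res_lon / 2,
                lat[r] - res_lat / 2,
                lon[c] + res_lon / 2,
                lat[r] + res_lat / 2,
            )
            for r, c in zip(iy, ix)
        ]
        geom = unary_union(cells) if cells else box(0, 0, 0, 0)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"jurisdiction": name},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
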
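"""Delta-method spatial downscaling and seasonal climate aggregation.

The delta method anchors coarse-model scenario change to fine-resolution
observations: the cross-member mean anomaly (future minus historical) is
computed on the coarse model grid, resampled to the fine observational grid,
and added to the present-day field. Physical bounds (sea-ice concentration
in [0, 100] %, non-negative primary production) are enforced after the
anomaly is added, because an additive anomaly can push a bounded variable
out of range.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grids import area_grid, clamp_layer

SEASON_MONTHS = {
    "winter": (1, 2, 3, 4),
    "summer": (6, 7, 8),
}


def seasonal_mean(monthly: xr.DataArray, season: str) -> xr.DataArray:
    """Per-cell arithmetic mean of a monthly stack over one season.

    ``monthly`` must have a ``month`` dimension covering the season's months
    (winter = Jan-Apr, summer = Jun-Aug). Cells where some but not all
    months are masked are averaged over the available months; the count of
    contributing months is attached as the ``n_months`` coordinate so
    partial cells stay identifiable.
    """
    try:
        months = SEASON_MONTHS[season]
    except KeyError:
        raise ValueError(f"unknown season {season!r}") from None
    have = set(np.atleast_1d(monthly["month"].values).tolist())
    missing = [m for m in months if m not in have]
    if missing:
        raise ValueError(f"monthly stack is missing months {missing} for {season}")
    sub = monthly.sel(month=list(months))
    out = sub.mean("month", skipna=True)
    n = sub.notnull().sum("month")
    out = out.where(n > 0)
    out = out.assign_coords(n_months=n)
    out.attrs = dict(monthly.attrs, season=season)
    return out


def _check_member_alignment(hist: xr.DataArray, future: xr.DataArray) -> None:
    for axis in ("lon", "lat"):
        if hist[axis].size != future[axis].size or not np.allclose(
            hist[axis].values, future[axis].values
        ):
            raise ValueError("historical and future members are on different grids")


def _check_nested(fine: xr.DataArray, coarse: xr.DataArray) -> None:
    half = 0.5 * float(abs(coarse["lon"].values[1] - coarse["lon"].values[0])) if coarse["lon"].size > 1 else 0.0
    for axis in ("lon", "lat"):
        c = coarse[axis].values
        f = fine[axis].values
        if f.min() < c.min() - half or f.max() > c.max() + half:
            raise ValueError(f"fine grid extends beyond coarse extent along {axis}")


def _fill_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaNs with the value of the nearest finite cell (grid metric)."""
    from scipy.ndimage import distance_transform_edt

    mask = ~np.isfinite(values)
    if not mask.any():
        return values
    if mask.all():
        raise ValueError("anomaly field is entirely masked")
    idx = distance_transform_edt(mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def resample_to(
    coarse: xr.DataArray, fine_like: xr.DataArray, method: str = "bilinear"
) -> xr.DataArray:
    """Resample a coarse field to a fine grid on cell centers.

    ``bilinear`` interpolates between coarse cell centers and extends the
    edge gradient beyond the outermost centers; ``nearest`` is available for
    categorical fields. Masked coarse cells are pre-filled from their
    nearest neighbour so coastal fine cells receive a finite anomaly.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    filled = coarse.copy(data=_fill_nearest(coarse.values.astype(float)))
    xr_method = "linear" if method == "bilinear" else "nearest"
    out = filled.interp(
        lon=fine_like["lon"],
        lat=fine_like["lat"],
        method=xr_method,
        kwargs={"fill_value": "extrapolate"},
    )
    out.attrs = dict(coarse.attrs)
    return out


def delta_downscale(
    coarse_hist: xr.DataArray,
    coarse_future: xr.DataArray,
    fine_present: xr.DataArray,
    method: str = "bilinear",
) -> xr.DataArray:
    """Downscale one variable for one scenario/period to the fine grid.

    ``coarse_hist`` and ``coarse_future`` carry a ``member`` dimension (the
    pseudo-GCM ensemble); the anomaly is the difference of cross-member
    means. The result is ``fine_present`` plus the resampled anomaly, masked
    like the present-day field and clamped to the variable's physical range.
    """
    if "member" in coarse_hist.dims:
        _check_member_alignment(coarse_hist, coarse_future)
        hist_mean = coarse_hist.mean("member", skipna=True)
        fut_mean = coarse_future.mean("member", skipna=True)
    else:
        hist_mean, fut_mean = coarse_hist, coarse_future
    _check_nested(fine_present, hist_mean)
    delta = fut_mean - hist_mean
    delta.attrs = dict(coarse_future.attrs)
    delta_fine = resample_to(delta, fine_present, method=method)
    out = fine_present + delta_fine
    out = out.where(np.isfinite(fine_present))
    out.name = fine_present.name
    out.attrs = dict(
        fine_present.attrs,
        period=str(coarse_future.attrs.get("period", "")),
        scenario=str(coarse_future.attrs.get("scenario", "")),
    )
    return clamp_layer(out)


def downscale_stack(
    coarse_hist: xr.Dataset,
    coarse_future: xr.Dataset,
    fine_present: xr.Dataset,
    scenario: str,
    period: str,
    method: str = "bilinear",
) -> xr.Dataset:
    """Downscale all dynamic variables for one scenario/period window.

    Static depth is carried over from the present-day stack unchanged.
    """
    out = {}
    for var in fine_present.data_vars:
        if var == "depth":
            out[var] = fine_present[var]
            continue
        fut = coarse_future[var].sel(scenario=scenario, period=period)
        fut.attrs = dict(coarse_future[var].attrs, scenario=scenario, period=period)
        out[var] = delta_downscale(
            coarse_hist[var], fut, fine_present[var], method=method
        )
    ds = xr.Dataset(out, attrs={"scenario": scenario, "period": period})
    return ds


def cold_pool_mask(
    ssbt: xr.DataArray,
    threshold_c: float = 2.0,
    comparator: str = "le",
) -> tuple[xr.DataArray, float]:
    """Cold-pool extent: summer bottom water at or below the threshold.

    Returns the boolean mask over marine cells and its total area in km^2
    (cosine-of-latitude weighted cell areas on a 6371-km sphere).
    """
    if comparator == "le":
        mask = ssbt <= threshold_c
    elif comparator == "lt":
        mask = ssbt < threshold_c
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    mask = mask & np.isfinite(ssbt)
    areas = area_grid(ssbt)
    area = float(areas.where(mask).sum(skipna=True))
    return mask, area
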
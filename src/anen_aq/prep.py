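"""Preparation of forecast cubes against a reanalysis reference.

Covers the bookkeeping between a raw hourly, fine-grid forecast cube and a
3-hourly, coarse-grid analysis series: temporal subsampling onto the
analysis lattice, nearest-centre regridding, unit conversion, alignment of
analysis values to (init, lead) pairs, and the search/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .constants import INIT_DIM, LAT_DIM, LEAD_DIM, LON_DIM, VALID_DIM

_UNIT_FACTORS = {
    ("kg m-3", "ug m-3"): 1e9,
    ("ug m-3", "kg m-3"): 1e-9,
}


@dataclass(frozen=True)
class SplitSpec:
    """Date ranges (inclusive) of the searching and test sets."""

    search_start: str | pd.Timestamp
    search_end: str | pd.Timestamp
    test_start: str | pd.Timestamp
    test_end: str | pd.Timestamp

    def __post_init__(self) -> None:
        s0, s1, t0, t1 = (pd.Timestamp(v) for v in self.as_tuple())
        if not (s0 <= s1 and t0 <= t1):
            raise ValueError("split ranges must be non-empty")
        if not s1 < t0:
            raise ValueError("searching set must end before the test set starts")

    def as_tuple(self):
        return (self.search_start, self.search_end, self.test_start, self.test_end)


def _analysis_lattice(analysis: xr.Dataset | xr.DataArray):
    """Anchor and step of the (regular) analysis valid-time lattice."""
    times = pd.DatetimeIndex(analysis[VALID_DIM].values)
    if len(times) < 2:
        raise ValueError("analysis needs at least two valid times")
    diffs = np.diff(times.values)
    step = diffs[0]
    if not (diffs == step).all():
        raise ValueError("analysis valid times are irregular")
    if not (np.diff(times.values) > np.timedelta64(0, "s")).all():
        raise ValueError("analysis valid times must be strictly increasing")
    return times[0], pd.Timedelta(step)


def subsample_to_3hourly(cube: xr.Dataset, analysis: xr.Dataset) -> xr.Dataset:
    """Keep only the lead times whose valid time falls on the analysis lattice.

    For 12:00 UTC initializations, hourly leads 1–120 h and a 00/03/…/21 UTC
    3-hourly analysis this retains exactly the 40 leads {3, 6, …, 120} h.
    """
    anchor, step = _analysis_lattice(analysis)
    init_times = pd.DatetimeIndex(cube[INIT_DIM].values)
    lead_hours = np.asarray(cube[LEAD_DIM].values)
    keep = []
    for lh in lead_hours:
        valid = init_times + pd.Timedelta(hours=int(lh))
        offsets = (valid - anchor) / step
        if np.allclose(offsets, np.round(offsets)):
            keep.append(lh)
    if not keep:
        raise ValueError("no forecast lead time falls on the analysis time lattice")
    return cube.sel({LEAD_DIM: keep})


def _nearest_indices(source: np.ndarray, target: np.ndarray, half_width: float):
    """Index of the nearest source centre per target centre, ties to the
    smaller coordinate; error if the nearest centre is farther than
    ``half_width``."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    d = np.abs(target[:, None] - source[None, :])
    # stable argmin keeps the first (smaller coordinate for sorted axes)
    idx = np.argmin(d, axis=1)
    nearest = d[np.arange(len(target)), idx]
    if (nearest > half_width + 1e-9).any():
        worst = target[nearest.argmax()]
        raise ValueError(
            f"no source centre within half a target cell of {worst} "
            f"(gap {nearest.max():.3f}°, limit {half_width:.3f}°)"
        )
    return idx


def regrid_nearest_center(
    obj: xr.Dataset | xr.DataArray,
    target_lats: np.ndarray,
    target_lons: np.ndarray,
) -> xr.Dataset | xr.DataArray:
    """Map a regular lat/lon grid onto target centres by nearest centre.

    Distance is rectangular in degrees, separable per axis; ties break
    toward the smaller coordinate.  Idempotent on an already-matching grid.
    """
    target_lats = np.asarray(target_lats, dtype=float)
    target_lons = np.asarray(target_lons, dtype=float)

    def half_width(target_vals, source_vals):
        # a single-centre target axis has no cell size; use the source's
        for vals in (target_vals, source_vals):
            if len(vals) > 1:
                return np.min(np.abs(np.diff(vals))) / 2
        return np.inf

    lat_idx = _nearest_indices(
        obj[LAT_DIM].values, target_lats,
        half_width(target_lats, obj[LAT_DIM].values),
    )
    lon_idx = _nearest_indices(
        obj[LON_DIM].values, target_lons,
        half_width(target_lons, obj[LON_DIM].values),
    )
    out = obj.isel({LAT_DIM: lat_idx, LON_DIM: lon_idx})
    return out.assign_coords({LAT_DIM: target_lats, LON_DIM: target_lons})


def convert_units(
    obj: xr.Dataset | xr.DataArray,
    from_units: str = "kg m-3",
    to_units: str = "ug m-3",
) -> xr.Dataset | xr.DataArray:
    """Convert every variable whose ``units`` attribute equals ``from_units``."""
    if (from_units, to_units) not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit conversion {from_units!r} -> {to_units!r}")
    factor = _UNIT_FACTORS[(from_units, to_units)]

    def _convert(da: xr.DataArray) -> xr.DataArray:
        out = da * factor
        out.attrs = dict(da.attrs)
        out.attrs["units"] = to_units
        return out

    if isinstance(obj, xr.DataArray):
        if obj.attrs.get("units") != from_units:
            raise ValueError(
                f"units attribute {obj.attrs.get('units')!r} does not match "
                f"{from_units!r}"
            )
        return _convert(obj)

    matched = [n for n in obj.data_vars if obj[n].attrs.get("units") == from_units]
    if not matched:
        raise ValueError(f"no variable carries units {from_units!r}")
    out = obj.copy()
    for name in matched:
        out[name] = _convert(obj[name])
    return out


def split_search_test(
    cube: xr.Dataset, analysis: xr.Dataset, spec: SplitSpec
) -> tuple[tuple[xr.Dataset, xr.Dataset], tuple[xr.Dataset, xr.Dataset]]:
    """Partition forecasts by initialization date per ``spec``.

    Initializations are partitioned disjointly; the analysis series is
    sliced so each side covers every valid time its own forecasts reach
    (the search side may extend up to the maximum lead past ``search_end``).
    """
    s0, s1, t0, t1 = (pd.Timestamp(v) for v in spec.as_tuple())
    init_times = pd.DatetimeIndex(cube[INIT_DIM].values)
    dates = init_times.normalize()
    search_mask = (dates >= s0) & (dates <= s1)
    test_mask = (dates >= t0) & (dates <= t1)
    if (search_mask & test_mask).any():
        raise ValueError("search and test initialization sets overlap")
    if not search_mask.any() or not test_mask.any():
        raise ValueError("search or test side of the split is empty")

    max_lead = pd.Timedelta(hours=int(np.max(cube[LEAD_DIM].values)))
    valid_times = pd.DatetimeIndex(analysis[VALID_DIM].values)

    def side(mask, start, end):
        fc = cube.isel({INIT_DIM: np.where(mask)[0]})
        amask = (valid_times >= start) & (
            valid_times <= end + pd.Timedelta("1D") + max_lead
        )
        an = analysis.isel({VALID_DIM: np.where(amask)[0]})
        return fc, an

    return side(search_mask, s0, s1), side(test_mask, t0, t1)


def analysis_at_leads(
    analysis: xr.Dataset | xr.DataArray,
    init_times,
    lead_hours,
    var: str | None = "pm10",
) -> xr.DataArray:
    """Reindex an analysis series onto forecast (init, lead) pairs.

    Each prepared (init, lead) maps to exactly one analysis valid time;
    pairs whose valid time is absent become NaN (and a warning is issued),
    so missingness propagates rather than being imputed.
    """
    da = analysis[var] if isinstance(analysis, xr.Dataset) else analysis
    init_times = pd.DatetimeIndex(init_times)
    lead_hours = np.asarray(lead_hours)
    times = pd.DatetimeIndex(da[VALID_DIM].values)
    pos = pd.Series(np.arange(len(times)), index=times)

    valid = init_times.values[:, None] + lead_hours[None, :] * np.timedelta64(1, "h")
    flat = pd.DatetimeIndex(valid.ravel())
    present = flat.isin(times)
    if not present.all():
        warnings.warn(
            f"{(~present).sum()} of {len(flat)} (init, lead) valid times have "
            "no analysis value; they propagate as NaN",
            stacklevel=2,
        )
    idx = np.where(present, pos.reindex(flat, fill_value=0).to_numpy(), 0)
    vals = da.values[idx.reshape(valid.shape)]
    vals = np.where(present.reshape(valid.shape)[..., None, None], vals, np.nan)

    out = xr.DataArray(
        vals,
        dims=(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM),
        coords={
            INIT_DIM: init_times,
            LEAD_DIM: lead_hours.astype("int64"),
            LAT_DIM: da[LAT_DIM].values,
            LON_DIM: da[LON_DIM].values,
        },
        attrs=dict(da.attrs),
    )
    return out
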
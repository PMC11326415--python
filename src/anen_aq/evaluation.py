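"""Forecast verification: metrics and the aggregation reshapes.

The five metrics are MAE, RMSE, the general coefficient of determination
R² = 1 − SS_res/SS_tot (unbounded below — a model worse than the
observation mean goes negative), Pearson's r and Bias = mean(pred − obs).
R² is stored as a fraction; reports render it ×100 as percent.

Aggregation strata reshape the (init, lead, lat, lon) hypercube:
``overall`` flattens everything; ``lead`` keeps the lead axis; ``day``
groups by initialization date; ``cell`` keeps (lat, lon); ``season``
groups by the meteorological season of the initialization date.  All
models in one call are scored on the identical pair mask so their rows
are comparable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .constants import INIT_DIM, LAT_DIM, LEAD_DIM, LON_DIM

#: Month -> season by meteorological convention (DJF/MAM/JJA/SON).
METEOROLOGICAL_SEASONS: dict[int, str] = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
}

STRATUM_KINDS = ("overall", "lead", "day", "cell", "season")

METRIC_COLUMNS = ("mae", "rmse", "r2", "pearson_r", "bias", "n_pairs")


def _validate_season_rule(rule: Mapping[int, str]) -> None:
    if set(rule) != set(range(1, 13)):
        raise ValueError("season rule must map all 12 months")
    bad = set(rule.values()) - {"Spring", "Summer", "Autumn", "Winter"}
    if bad:
        raise ValueError(f"unknown season labels {bad}")


def metrics(pred, obs) -> dict:
    """MAE, RMSE, R², Pearson r and Bias on paired vectors.

    Pairs with any missing member are dropped first; at least two must
    remain.  On constant observations R² and Pearson r are undefined and
    reported as NaN (flagged, never silently zeroed).
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    if pred.size < 2:
        raise ValueError("need at least two complete pairs")
    err = pred - obs
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    bias = float(err.mean())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = np.nan
        r = np.nan
    else:
        r2 = 1.0 - float((err**2).sum()) / ss_tot
        if np.std(pred) == 0.0:
            r = np.nan
        else:
            r = float(np.corrcoef(pred, obs)[0, 1])
    return {
        "mae": mae,
        "rmse": rmse,
        "r2": r2,
        "pearson_r": r,
        "bias": bias,
        "n_pairs": int(pred.size),
    }


def _empty_row() -> dict:
    return {
        "mae": np.nan, "rmse": np.nan, "r2": np.nan,
        "pearson_r": np.nan, "bias": np.nan, "n_pairs": 0,
    }


def _strata_masks(da: xr.DataArray, kind: str, season_rule) -> list[tuple]:
    """(stratum id, boolean mask over the flattened hypercube) pairs."""
    shape = da.shape
    init = pd.DatetimeIndex(da[INIT_DIM].values)
    if kind == "overall":
        return [("overall", np.ones(shape, dtype=bool))]
    if kind == "lead":
        out = []
        for i, lh in enumerate(np.asarray(da[LEAD_DIM].values)):
            m = np.zeros(shape, dtype=bool)
            m[:, i] = True
            out.append((int(lh), m))
        return out
    if kind == "day":
        out = []
        dates = init.normalize()
        for d in dates.unique():
            m = np.zeros(shape, dtype=bool)
            m[dates == d] = True
            out.append((pd.Timestamp(d).date().isoformat(), m))
        return out
    if kind == "cell":
        out = []
        lats = np.asarray(da[LAT_DIM].values)
        lons = np.asarray(da[LON_DIM].values)
        for a in range(len(lats)):
            for b in range(len(lons)):
                m = np.zeros(shape, dtype=bool)
                m[:, :, a, b] = True
                out.append(((float(lats[a]), float(lons[b])), m))
        return out
    if kind == "season":
        labels = np.array([season_rule[m] for m in init.month])
        out = []
        for season in ("Spring", "Summer", "Autumn", "Winter"):
            sel = labels == season
            if not sel.any():
                continue
            m = np.zeros(shape, dtype=bool)
            m[sel] = True
            out.append((season, m))
        return out
    raise ValueError(f"unknown stratum kind {kind!r}; choose from {STRATUM_KINDS}")


def evaluate(
    predictions: Mapping[str, xr.DataArray],
    obs: xr.DataArray,
    strata=("overall",),
    season_rule: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Verification table over models × strata.

    ``predictions`` maps model name to a prediction cube aligned with
    ``obs`` on (init_time, lead_time, lat, lon).  Within each stratum the
    pair mask — positions finite in the observations and in *every* model —
    is identical across models, so metric differences reflect the models,
    not their missingness.  Empty strata yield rows with ``n_pairs = 0``
    and missing metrics.
    """
    season_rule = dict(season_rule) if season_rule else dict(METEOROLOGICAL_SEASONS)
    _validate_season_rule(season_rule)
    dims = (INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM)
    obs = obs.transpose(*dims)
    pred_arrays = {}
    for name, da in predictions.items():
        da = da.transpose(*dims)
        if da.shape != obs.shape:
            raise ValueError(f"model {name!r} is not aligned with the observations")
        pred_arrays[name] = da.values
    shared = np.isfinite(obs.values)
    for arr in pred_arrays.values():
        shared &= np.isfinite(arr)

    rows = []
    for kind in strata:
        for stratum_id, mask in _strata_masks(obs, kind, season_rule):
            m = mask & shared
            for name, arr in pred_arrays.items():
                base = {
                    "model": name,
                    "stratum_kind": kind,
                    "stratum": stratum_id,
                }
                if m.sum() < 2:
                    base.update(_empty_row())
                    base["n_pairs"] = int(m.sum())
                else:
                    base.update(metrics(arr[m], obs.values[m]))
                rows.append(base)
    return pd.DataFrame(rows)


def error_distribution(
    pred: xr.DataArray | np.ndarray,
    obs: xr.DataArray | np.ndarray,
    share_thresholds=(10.0, 20.0),
    bin_width: float = 10.0,
) -> dict:
    """Summary of the error distribution of one model.

    Returns absolute-error quartiles, the share of absolute errors below
    each threshold (µg/m³), the maximum, and fixed-width histogram counts
    of both absolute and signed errors (bin edges aligned to multiples of
    ``bin_width`` so counts are deterministic).
    """
    p = np.asarray(getattr(pred, "values", pred), dtype=float).ravel()
    o = np.asarray(getattr(obs, "values", obs), dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError("pred and obs must be aligned")
    ok = np.isfinite(p) & np.isfinite(o)
    err = p[ok] - o[ok]
    abs_err = np.abs(err)
    if abs_err.size == 0:
        raise ValueError("no complete pairs")

    hi = max(float(np.ceil(abs_err.max() / bin_width)) * bin_width, bin_width)
    abs_edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    abs_counts, _ = np.histogram(abs_err, bins=abs_edges)
    lo = min(float(np.floor(err.min() / bin_width)) * bin_width, -bin_width)
    shi = max(float(np.ceil(err.max() / bin_width)) * bin_width, bin_width)
    signed_edges = np.arange(lo, shi + bin_width / 2, bin_width)
    signed_counts, _ = np.histogram(err, bins=signed_edges)

    return {
        "n_pairs": int(abs_err.size),
        "abs_quartiles": tuple(
            float(np.quantile(abs_err, q)) for q in (0.25, 0.5, 0.75)
        ),
        "share_below": {
            float(t): float((abs_err < t).mean()) for t in share_thresholds
        },
        "abs_max": float(abs_err.max()),
        "abs_hist_edges": abs_edges,
        "abs_hist_counts": abs_counts,
        "signed_hist_edges": signed_edges,
        "signed_hist_counts": signed_counts,
    }
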
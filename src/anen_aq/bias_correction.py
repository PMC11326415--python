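"""Threshold-triggered bias correction of analog-ensemble predictions (AnEnBc).

The analog mean tends to damp rare high events: when the current forecast
sits far above anything in the archive, the closest analogs — and hence
their observations — under-shoot it.  AnEnBc compensates by adding, at
points where the target forecast exceeds a threshold of the historical
forecast distribution, the difference between the target forecast and the
mean of the analogs' own forecasts.  Where that shift would produce a
negative concentration, the uncorrected analog mean is kept instead.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .constants import INIT_DIM, LAT_DIM, LEAD_DIM, LON_DIM, TARGET_VARIABLE

#: Supported trigger-threshold kinds: quantiles of the historical
#: target-variable forecast distribution, or its arithmetic mean.
THRESHOLD_KINDS = ("Q25", "Q50", "MEAN", "Q75", "Q80", "Q85", "Q90", "Q95")


def compute_threshold_values(values: np.ndarray, kind: str) -> float:
    """Threshold of a flat sample: linear-interpolation quantile or mean."""
    if kind not in THRESHOLD_KINDS:
        raise ValueError(f"unknown threshold kind {kind!r}")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty distribution: threshold undefined")
    if kind == "MEAN":
        return float(values.mean())
    q = float(kind[1:]) / 100.0
    return float(np.quantile(values, q, method="linear"))


def compute_threshold(
    search_cube: xr.Dataset,
    kind: str,
    lead=None,
    cell: tuple[float, float] | None = None,
    var: str = TARGET_VARIABLE,
):
    """Trigger threshold(s) from searching-set forecasts of ``var``.

    With ``lead`` and ``cell`` given, returns the scalar threshold at that
    (lead time, grid cell); otherwise a DataArray over (lead, lat, lon).
    The distribution is per (lead, cell), consistent with the analog
    ensemble operating independently there.
    """
    da = search_cube[var]
    if lead is not None and cell is not None:
        vals = da.sel({LEAD_DIM: lead, LAT_DIM: cell[0], LON_DIM: cell[1]}).values
        return compute_threshold_values(vals, kind)
    if kind == "MEAN":
        return da.mean(INIT_DIM)
    q = float(kind[1:]) / 100.0
    out = da.quantile(q, dim=INIT_DIM, method="linear")
    return out.drop_vars("quantile")


def apply_bias_correction(
    anen_pred,
    target_forecast,
    analog_forecast_mean,
    threshold,
):
    """Apply the AnEnBc rule elementwise (scalars or broadcastable arrays).

    if target_forecast <= threshold:  anen_pred (untouched)
    else:                             anen_pred + (target_forecast −
                                      analog_forecast_mean), falling back
                                      to anen_pred if that is negative.
    """
    anen = np.asarray(anen_pred, dtype=float)
    tf = np.asarray(target_forecast, dtype=float)
    afm = np.asarray(analog_forecast_mean, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    corrected = anen + (tf - afm)
    out = np.where(tf > thr, np.where(corrected < 0, anen, corrected), anen)
    if out.ndim == 0:
        return float(out)
    return out
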
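"""Functional surface of the analog ensemble.

Thin wrappers over :class:`~anen_aq.estimators.AnalogEnsembleRegressor` and
:class:`~anen_aq.gridded.AnalogEnsemblePostProcessor`, exposing the method
as plain operations: compute the historical σ field, evaluate the weighted
similarity metric between two forecast windows, search analogs for one
target, average their observations, and run the whole cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .constants import (
    DEFAULT_VARIABLES,
    INIT_DIM,
    LAT_DIM,
    LEAD_DIM,
    LON_DIM,
    TARGET_VARIABLE,
)
from .estimators import pairwise_analog_distance
from .gridded import AnalogEnsemblePostProcessor, RunReport


@dataclass(frozen=True)
class SimilarityConfig:
    """Free parameters of the similarity metric: per-variable weights w_j,
    half-window τ (in lead-time steps; ±1 step = ±3 h at 3-hourly leads)
    and the ordered predictor roster."""

    weights: dict = field(default_factory=dict)
    tau: int = 1
    variables: tuple[str, ...] = DEFAULT_VARIABLES

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        w = self.weight_vector()
        if (w < 0).any() or not (w > 0).any():
            raise ValueError("at least one weight must be positive, none negative")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(v, 1.0) for v in self.variables])


@dataclass
class AnalogSet:
    """Analogs selected for one (init, lead, cell) target, in increasing
    distance order; observations and forecasts are the target variable's."""

    target: tuple
    member_inits: np.ndarray
    distances: np.ndarray
    observations: np.ndarray
    forecasts: np.ndarray

    def __len__(self) -> int:
        return len(self.distances)


def compute_sigma(search_cube: xr.Dataset, variables=None) -> xr.DataArray:
    """Sample standard deviation (ddof=1) of each searching-set variable per
    (lead time, grid cell); NaN flags cells with fewer than two values."""
    roster = tuple(variables) if variables is not None else tuple(search_cube.data_vars)
    das = []
    import warnings

    for v in roster:
        da = search_cube[v]
        counts = da.notnull().sum(INIT_DIM)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = da.std(INIT_DIM, ddof=1, skipna=True)
        das.append(sd.where(counts >= 2))
    out = xr.concat(das, dim=pd.Index(list(roster), name="variable"))
    return out.transpose("variable", LEAD_DIM, LAT_DIM, LON_DIM)


def similarity(
    target_window: np.ndarray,
    candidate_window: np.ndarray,
    config: SimilarityConfig,
    sigma: np.ndarray,
) -> float:
    """Weighted similarity metric between two forecast windows.

    Windows are arrays of shape (p, n_offsets) over ``config.variables``
    (already truncated identically at the lead-axis edges); ``sigma`` holds
    σ_j per variable at the target lead.  Smaller means more similar;
    identical windows give 0.  Zero-weight variables contribute nothing
    and σ_j = 0 drops the variable rather than dividing by zero.
    """
    t = np.atleast_2d(np.asarray(target_window, dtype=float))
    c = np.atleast_2d(np.asarray(candidate_window, dtype=float))
    if t.shape != c.shape:
        raise ValueError("target and candidate windows must share a shape")
    d = pairwise_analog_distance(
        t[None, :, :], c[None, :, :], config.weight_vector(), np.asarray(sigma, float)
    )
    return float(d[0, 0])


def _fit_postprocessor(search_cube, search_analysis, n, config, bias_threshold=None):
    pp = AnalogEnsemblePostProcessor(
        n_analogs=n,
        weights=dict(config.weights),
        tau=config.tau,
        variables=[v for v in config.variables if v in search_cube.data_vars],
        target=TARGET_VARIABLE,
        bias_threshold=bias_threshold,
    )
    return pp.fit(search_cube, search_analysis)


def find_analogs(
    target: tuple,
    target_cube: xr.Dataset,
    search_cube: xr.Dataset,
    search_analysis: xr.Dataset,
    n: int,
    config: SimilarityConfig,
) -> AnalogSet:
    """Select the ``n`` most similar searching-set forecasts for one target.

    ``target`` is (init_time, lead_hours, (lat, lon)); the target forecast
    window is read from ``target_cube``.  Members come back sorted by
    distance (ties to the earlier historical init), each paired with the
    searching-set observation at its valid time and with its own
    target-variable forecast.
    """
    init, lead, cell = target
    pp = _fit_postprocessor(search_cube, search_analysis, n, config)
    lead_hours = list(np.asarray(search_cube[LEAD_DIM].values))
    l = lead_hours.index(lead)
    a = list(np.asarray(search_cube[LAT_DIM].values)).index(cell[0])
    b = list(np.asarray(search_cube[LON_DIM].values)).index(cell[1])
    reg, ks, center = pp._block_regressor(l, a, b)

    tv = np.stack(
        [target_cube[v].transpose(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM).values
         for v in pp.variables_]
    )
    ti = list(pd.DatetimeIndex(target_cube[INIT_DIM].values)).index(pd.Timestamp(init))
    Xt = tv[:, ti, ks, a, b][None, :, :]
    dist, idx = reg.find_analogs(Xt)
    tgt_idx = pp.variables_.index(TARGET_VARIABLE)
    return AnalogSet(
        target=(pd.Timestamp(init), lead, cell),
        member_inits=pp._search_inits.values[idx[0]],
        distances=dist[0],
        observations=reg.y_[idx[0]],
        forecasts=pp._search_vals[tgt_idx, idx[0], l, a, b],
    )


def predict_anen(analogs: AnalogSet) -> float:
    """Arithmetic mean of the analogs' observations."""
    if len(analogs) == 0:
        raise ValueError("empty analog set: prediction undefined")
    return float(np.mean(analogs.observations))


def run_anen(
    test_cube: xr.Dataset,
    search_cube: xr.Dataset,
    search_analysis: xr.Dataset,
    n: int,
    config: SimilarityConfig,
    bias_threshold: str | None = None,
) -> tuple[xr.Dataset, RunReport]:
    """Analog-ensemble prediction over every (init, lead, cell) of the cube.

    Returns the component dataset (``anen``, ``analog_forecast_mean``,
    ``target_forecast`` and ``anen_bc`` when ``bias_threshold`` is set)
    plus a run report with analog-shrink warnings.
    """
    pp = _fit_postprocessor(
        search_cube, search_analysis, n, config, bias_threshold=bias_threshold
    )
    return pp.predict_components(test_cube)
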
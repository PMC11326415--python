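"""Gridded analog-ensemble post-processing.

The analog ensemble operates independently at every lead time and grid
cell: :class:`AnalogEnsemblePostProcessor` fits one
:class:`~anen_aq.estimators.AnalogEnsembleRegressor` problem per (lead,
cell) block — historical forecast windows against verifying analysis
values — and assembles the predictions back into a cube.  Because the
blocks are independent, results cannot depend on traversal order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator

from .bias_correction import apply_bias_correction, compute_threshold
from .constants import (
    INIT_DIM,
    LAT_DIM,
    LEAD_DIM,
    LON_DIM,
    PM_UNITS,
    TARGET_VARIABLE,
    VALID_DIM,
)
from .estimators import AnalogEnsembleRegressor
from .prep import analysis_at_leads


@dataclass
class RunReport:
    """Bookkeeping from one prediction pass."""

    n_targets: int = 0
    n_blocks: int = 0
    shrunk_blocks: list = field(default_factory=list)  # (lead, lat, lon, n_eligible)

    @property
    def n_shrunk_blocks(self) -> int:
        return len(self.shrunk_blocks)


def window_offsets(lead_index: int, n_lead: int, tau: int) -> list[int]:
    """Lead indices of the similarity window k ∈ {−τ,…,τ} around
    ``lead_index``, truncated identically for target and candidate at the
    edges of the lead axis."""
    return [lead_index + k for k in range(-tau, tau + 1) if 0 <= lead_index + k < n_lead]


class AnalogEnsemblePostProcessor(BaseEstimator):
    """Analog-ensemble post-processing of a forecast cube.

    Parameters
    ----------
    n_analogs : int, default=9
        Ensemble size per target.
    weights : mapping variable name -> weight, or None
        Similarity weights w_j; unnamed variables default to 1.
    tau : int, default=1
        Half-window in lead-time steps (±1 step = ±3 h at 3-hourly leads).
    variables : sequence of str or None
        Predictor roster; None uses every data variable of the search cube.
    target : str, default="pm10"
        The post-processed variable (observations must exist for it).
    bias_threshold : str or None
        A threshold kind (Q25…Q95 or MEAN) arms the AnEnBc correction.

    Attributes
    ----------
    sigma_ : xr.DataArray (variable, lead_time, lat, lon)
        Sample standard deviation of each predictor over the searching
        set's initializations; NaN where fewer than two values exist.
    thresholds_ : xr.DataArray (lead_time, lat, lon), present when armed
        Trigger thresholds from the searching-set target forecasts.
    """

    def __init__(
        self,
        n_analogs: int = 9,
        weights: dict | None = None,
        tau: int = 1,
        variables=None,
        target: str = TARGET_VARIABLE,
        bias_threshold: str | None = None,
    ):
        self.n_analogs = n_analogs
        self.weights = weights
        self.tau = tau
        self.variables = variables
        self.target = target
        self.bias_threshold = bias_threshold

    def fit(self, search_cube: xr.Dataset, search_analysis: xr.Dataset):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        roster = (
            tuple(self.variables)
            if self.variables is not None
            else tuple(search_cube.data_vars)
        )
        missing = [v for v in roster if v not in search_cube]
        if missing:
            raise ValueError(f"search cube lacks variables {missing}")
        w = np.ones(len(roster))
        if self.weights is not None:
            unknown = set(self.weights) - set(roster)
            if unknown:
                raise ValueError(f"weights given for unknown variables {unknown}")
            for j, name in enumerate(roster):
                w[j] = self.weights.get(name, 1.0)
        if (w < 0).any() or not (w > 0).any():
            raise ValueError("weights must be >= 0 with at least one positive")
        self.variables_ = roster
        self.weights_ = w

        # (var, init, lead, lat, lon) archive and aligned observations
        self._search_vals = np.stack(
            [search_cube[v].transpose(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM).values
             for v in roster]
        )
        self._search_inits = pd.DatetimeIndex(search_cube[INIT_DIM].values)
        self._lead_hours = np.asarray(search_cube[LEAD_DIM].values)
        self._lats = np.asarray(search_cube[LAT_DIM].values)
        self._lons = np.asarray(search_cube[LON_DIM].values)
        self._search_obs = analysis_at_leads(
            search_analysis, self._search_inits, self._lead_hours, var=self.target
        ).values

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            counts = np.isfinite(self._search_vals).sum(axis=1)
            sd = np.nanstd(self._search_vals, axis=1, ddof=1)
        self.sigma_ = xr.DataArray(
            np.where(counts >= 2, sd, np.nan),
            dims=("variable", LEAD_DIM, LAT_DIM, LON_DIM),
            coords={
                "variable": list(roster),
                LEAD_DIM: self._lead_hours,
                LAT_DIM: self._lats,
                LON_DIM: self._lons,
            },
        )
        if self.bias_threshold is not None:
            self.thresholds_ = compute_threshold(
                search_cube, self.bias_threshold, var=self.target
            ).transpose(LEAD_DIM, LAT_DIM, LON_DIM)
        return self

    def _check_fitted(self):
        if not hasattr(self, "variables_"):
            raise ValueError("post-processor is not fitted; call fit first")

    def _block_regressor(self, l: int, a: int, b: int) -> tuple:
        """Fitted single-site regressor for lead index l, cell (a, b)."""
        ks = window_offsets(l, len(self._lead_hours), self.tau)
        center = ks.index(l)
        Xs = self._search_vals[:, :, ks, a, b].transpose(1, 0, 2)
        ys = self._search_obs[:, l, a, b]
        reg = AnalogEnsembleRegressor(n_analogs=self.n_analogs, weights=self.weights_)
        reg.fit(Xs, ys, center=center)
        return reg, ks, center

    def predict_components(
        self, test_cube: xr.Dataset
    ) -> tuple[xr.Dataset, RunReport]:
        """Predict over a test cube, returning all AnEn/AnEnBc ingredients.

        The returned dataset holds ``anen`` (analog-mean prediction),
        ``analog_forecast_mean`` (mean of the analogs' target-variable
        forecasts), ``target_forecast`` (the raw forecast being
        post-processed) and, when a bias threshold is armed, ``anen_bc``.
        """
        self._check_fitted()
        test_vals = np.stack(
            [test_cube[v].transpose(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM).values
             for v in self.variables_]
        )
        test_inits = pd.DatetimeIndex(test_cube[INIT_DIM].values)
        if not np.array_equal(np.asarray(test_cube[LEAD_DIM].values), self._lead_hours):
            raise ValueError("test cube lead times differ from the searching set")
        n_init, n_lead = test_vals.shape[1], test_vals.shape[2]
        nlat, nlon = len(self._lats), len(self._lons)
        tgt_idx = self.variables_.index(self.target)

        anen = np.full((n_init, n_lead, nlat, nlon), np.nan)
        afm = np.full_like(anen, np.nan)
        report = RunReport(n_targets=anen.size, n_blocks=n_lead * nlat * nlon)

        for l in range(n_lead):
            for a in range(nlat):
                for b in range(nlon):
                    reg, ks, center = self._block_regressor(l, a, b)
                    Xt = test_vals[:, :, ks, a, b].transpose(1, 0, 2)
                    with warnings.catch_warnings(record=True) as caught:
                        warnings.simplefilter("always")
                        pred, dist, idx = reg.predict(Xt, return_members=True)
                    if any("eligible analogs" in str(c.message) for c in caught):
                        report.shrunk_blocks.append(
                            (int(self._lead_hours[l]), float(self._lats[a]),
                             float(self._lons[b]), int(reg.eligible_.sum()))
                        )
                    anen[:, l, a, b] = pred
                    member_fc = self._search_vals[tgt_idx, :, l, a, b][idx]
                    block_afm = member_fc.mean(axis=1)
                    block_afm[~np.isfinite(dist).all(axis=1)] = np.nan
                    afm[:, l, a, b] = block_afm

        coords = {
            INIT_DIM: test_inits,
            LEAD_DIM: self._lead_hours,
            LAT_DIM: self._lats,
            LON_DIM: self._lons,
        }
        dims = (INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM)
        out = xr.Dataset(
            {
                "anen": (dims, anen),
                "analog_forecast_mean": (dims, afm),
                "target_forecast": (
                    dims,
                    test_cube[self.target]
                    .transpose(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM)
                    .values,
                ),
            },
            coords=coords,
        )
        out["anen"].attrs["units"] = PM_UNITS
        if self.bias_threshold is not None:
            thr = self.thresholds_.values[None, :, :, :]
            bc = apply_bias_correction(
                anen, out["target_forecast"].values, afm, thr
            )
            out["anen_bc"] = (dims, bc)
            out["anen_bc"].attrs["units"] = PM_UNITS
        return out, report

    def predict(self, test_cube: xr.Dataset) -> xr.DataArray:
        """AnEn prediction cube (or AnEnBc when a bias threshold is armed)."""
        components, report = self.predict_components(test_cube)
        self.last_report_ = report
        da = components["anen_bc" if self.bias_threshold is not None else "anen"]
        return da.rename("pm10_pred")
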
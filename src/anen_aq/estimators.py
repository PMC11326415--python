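"""Scikit-learn-style estimators at the heart of the analog ensemble.

:class:`AnalogEnsembleRegressor` solves the single-site problem — one lead
time, one grid cell — in tabular form: each fit sample is one historical
initialization, described by its forecast values of ``p`` predictor
variables over a short lead-time window, with the verifying observation as
the regression target.  Prediction finds, for every query forecast, the
``n_analogs`` most similar fit samples under the weighted metric

    d(t, i) = Σ_j (w_j / σ_j) · sqrt( Σ_k (F_{t+k,j} − F_{i+k,j})² )

(σ_j the historical standard deviation of variable j at the central lead)
and returns the mean of their observations.

:class:`ThresholdBiasCorrector` applies the rare-event correction: when the
query forecast exceeds a quantile/mean threshold of the historical forecast
distribution, the analog mean is shifted by (query forecast − mean of the
analogs' own forecasts); negative results fall back to the uncorrected
value.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .bias_correction import THRESHOLD_KINDS, compute_threshold_values


def _as_windowed(X) -> np.ndarray:
    """Coerce to float array of shape (n_samples, n_variables, n_offsets)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.ndim != 3:
        raise ValueError(
            f"X must be 2-D (samples, variables) or 3-D "
            f"(samples, variables, window offsets); got shape {X.shape}"
        )
    return X


def pairwise_analog_distance(
    X_query: np.ndarray,
    X_fit: np.ndarray,
    weights: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    """Weighted analog distance matrix, shape (n_query, n_fit).

    Variables with zero weight contribute nothing; variables whose σ is
    zero or undefined (NaN) are dropped — a constant predictor carries no
    discriminating information, and division by zero never occurs.
    """
    Xq = _as_windowed(X_query)
    Xf = _as_windowed(X_fit)
    if Xq.shape[1:] != Xf.shape[1:]:
        raise ValueError("query and fit windows have mismatched shapes")
    weights = np.asarray(weights, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    d = np.zeros((Xq.shape[0], Xf.shape[0]))
    for j in range(Xq.shape[1]):
        if weights[j] == 0 or not np.isfinite(sigma[j]) or sigma[j] == 0:
            continue
        diff = Xq[:, None, j, :] - Xf[None, :, j, :]
        d += (weights[j] / sigma[j]) * np.sqrt(np.einsum("mnk,mnk->mn", diff, diff))
    return d


class AnalogEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Analog-ensemble regression for one lead time and grid cell.

    Parameters
    ----------
    n_analogs : int, default=9
        Ensemble size; if fewer eligible historical samples exist, all of
        them are used and a warning is raised.
    weights : array-like of shape (n_variables,) or None
        Per-variable weights w_j ≥ 0 (None means all ones).  At least one
        must be positive.
    tie_break : {"index"}
        Distance ties go to the earlier fit sample (fit order is assumed
        chronological), keeping results reproducible.

    Attributes
    ----------
    X_ : ndarray of shape (n_samples, n_variables, n_offsets)
        Stored historical forecast windows.
    y_ : ndarray of shape (n_samples,)
        Verifying observations.
    sigma_ : ndarray of shape (n_variables,)
        Sample standard deviation (ddof=1) of each variable at the central
        window offset; NaN where fewer than two finite values exist.
    eligible_ : ndarray of bool
        Samples with a fully finite window and a finite observation.
    """

    def __init__(self, n_analogs: int = 9, weights=None, tie_break: str = "index"):
        self.n_analogs = n_analogs
        self.weights = weights
        self.tie_break = tie_break

    def fit(self, X, y, center: int | None = None):
        """Store the historical archive and compute σ per variable.

        ``center`` is the window column holding the target lead itself
        (k = 0); default is the middle column.  Windows truncated at the
        edge of the lead axis pass their own centre explicitly.
        """
        X = _as_windowed(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        if self.n_analogs < 1:
            raise ValueError("n_analogs must be >= 1")
        if self.tie_break != "index":
            raise ValueError("only tie_break='index' is supported")
        w = np.ones(X.shape[1]) if self.weights is None else np.asarray(
            self.weights, dtype=float
        )
        if w.shape != (X.shape[1],):
            raise ValueError(
                f"weights shape {w.shape} does not match {X.shape[1]} variables"
            )
        if (w < 0).any() or not (w > 0).any():
            raise ValueError("weights must be >= 0 with at least one positive")
        self.weights_ = w
        self.center_ = X.shape[2] // 2 if center is None else int(center)
        if not 0 <= self.center_ < X.shape[2]:
            raise ValueError("center outside the window")

        central = X[:, :, self.center_]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            counts = np.sum(np.isfinite(central), axis=0)
            self.sigma_ = np.where(
                counts >= 2, np.nanstd(central, axis=0, ddof=1), np.nan
            )
        self.X_ = X
        self.y_ = y
        self.eligible_ = np.isfinite(X).all(axis=(1, 2)) & np.isfinite(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "X_"):
            raise ValueError("estimator is not fitted; call fit first")

    def analog_distances(self, X) -> np.ndarray:
        """Distance of each query (rows) to each fit sample (columns);
        ineligible fit samples get +inf."""
        self._check_fitted()
        d = pairwise_analog_distance(X, self.X_, self.weights_, self.sigma_)
        d[:, ~self.eligible_] = np.inf
        return d

    def find_analogs(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (distances, indices) of the selected analogs per query.

        Both arrays have shape (n_queries, k) with k = min(n_analogs,
        eligible archive size); rows are sorted by increasing distance,
        ties broken toward the earlier fit sample.
        """
        d = self.analog_distances(X)
        n_eligible = int(self.eligible_.sum())
        if n_eligible == 0:
            raise ValueError("no eligible historical samples to draw analogs from")
        k = self.n_analogs
        if n_eligible < k:
            warnings.warn(
                f"only {n_eligible} eligible analogs available "
                f"(requested {k}); using all of them",
                stacklevel=2,
            )
            k = n_eligible
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        return np.take_along_axis(d, order, axis=1), order

    def predict(self, X, return_members: bool = False):
        """Analog-ensemble prediction: mean observation of the analogs."""
        dist, idx = self.find_analogs(X)
        pred = self.y_[idx].mean(axis=1)
        # a query with NaN in any used window column has no defined distance
        bad = ~np.isfinite(dist).all(axis=1)
        pred[bad] = np.nan
        if return_members:
            return pred, dist, idx
        return pred


class ThresholdBiasCorrector(BaseEstimator):
    """Threshold-triggered additive correction of analog-ensemble output.

    ``fit`` learns the trigger threshold — a linear-interpolation quantile
    (Q25…Q95) or the mean of the historical target-variable forecasts.
    ``correct`` then shifts each triggered prediction by the difference
    between the query forecast and the mean of its analogs' forecasts, and
    substitutes the uncorrected value wherever the shift would go negative.
    """

    def __init__(self, threshold: str = "Q75"):
        self.threshold = threshold

    def fit(self, forecast_values, y=None):
        vals = np.asarray(forecast_values, dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("empty forecast distribution: threshold undefined")
        if self.threshold not in THRESHOLD_KINDS:
            raise ValueError(
                f"threshold must be one of {sorted(THRESHOLD_KINDS)}, "
                f"got {self.threshold!r}"
            )
        self.threshold_value_ = compute_threshold_values(vals, self.threshold)
        return self

    def correct(self, anen_pred, target_forecast, analog_forecast_mean):
        if not hasattr(self, "threshold_value_"):
            raise ValueError("corrector is not fitted; call fit first")
        from .bias_correction import apply_bias_correction

        return apply_bias_correction(
            anen_pred, target_forecast, analog_forecast_mean, self.threshold_value_
        )
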
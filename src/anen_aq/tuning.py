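"""Hyperparameter grid search: analog counts × leave-one-variable-out weights.

The search space follows the standard tuning experiment for analog
ensembles: an all-ones weight set plus one set per predictor with that
predictor's weight zeroed (p + 1 sets), crossed with a list of ensemble
sizes, scored by RMSE on a validation slice carved from the end of the
searching set (the test set stays untouched; validation targets are never
searchable by their own analogs).

Per-variable distance matrices are computed once per (lead, cell) block and
re-combined per weight set, and the cumulative mean over the sorted analog
observations scores every ensemble size in one pass, so the 63-cell default
grid costs barely more than a single analog run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .constants import INIT_DIM, LAT_DIM, LEAD_DIM, LON_DIM, TARGET_VARIABLE
from .gridded import window_offsets
from .prep import analysis_at_leads

DEFAULT_ANALOG_COUNTS = (3, 6, 9, 10, 12, 15, 21)


def enumerate_weight_sets(variables) -> list[dict]:
    """All-ones first, then one single-exclusion set per variable (p + 1)."""
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables to build exclusion sets")
    sets = [{v: 1.0 for v in variables}]
    for excluded in variables:
        sets.append({v: (0.0 if v == excluded else 1.0) for v in variables})
    return sets


def weight_set_label(weights: dict) -> str:
    zeroed = [v for v, w in weights.items() if w == 0.0]
    if not zeroed:
        return "All"
    if len(zeroed) == 1:
        return f"-{zeroed[0]}"
    return "custom(" + ",".join(zeroed) + ")"


@dataclass
class TuningGrid:
    """Search space; ``weight_sets=None`` enumerates the leave-one-out sets
    from the cube's variables at search time."""

    analog_counts: tuple[int, ...] = DEFAULT_ANALOG_COUNTS
    weight_sets: list[dict] | None = None

    def __post_init__(self) -> None:
        if len(self.analog_counts) == 0 or any(n < 1 for n in self.analog_counts):
            raise ValueError("analog_counts must be positive and non-empty")
        if self.weight_sets is not None:
            if len(self.weight_sets) == 0:
                raise ValueError("weight_sets must be non-empty")
            for ws in self.weight_sets:
                w = np.array(list(ws.values()), dtype=float)
                if (w < 0).any() or not (w > 0).any():
                    raise ValueError(
                        "each weight set needs at least one positive weight"
                    )


def grid_search(
    search_cube: xr.Dataset,
    search_analysis: xr.Dataset,
    grid: TuningGrid | None = None,
    tau: int = 1,
    validation_days: int | None = None,
    variables=None,
) -> pd.DataFrame:
    """Exhaustive (weight set × ensemble size) search minimizing RMSE.

    The last ``validation_days`` initializations of the searching set are
    the held-out targets (default: one year, capped at a quarter of the
    archive); analogs for them are drawn only from the earlier part, so the
    evaluation slice is never searchable by its own analogs.

    Returns a table with one row per grid cell — columns ``weight_set``
    (label), ``n_analogs``, ``rmse``, ``n_pairs``, ``valid``, ``rank``
    (ascending RMSE; ties broken by fewer analogs, then weight-set order) —
    with the train/validation init sets in ``DataFrame.attrs``.
    """
    grid = grid if grid is not None else TuningGrid()
    roster = (
        tuple(variables) if variables is not None else tuple(search_cube.data_vars)
    )
    weight_sets = (
        grid.weight_sets
        if grid.weight_sets is not None
        else enumerate_weight_sets(roster)
    )
    counts = tuple(grid.analog_counts)

    init_times = pd.DatetimeIndex(search_cube[INIT_DIM].values)
    n_init = len(init_times)
    if validation_days is None:
        validation_days = min(365, max(1, n_init // 4))
    if not 0 < validation_days < n_init:
        raise ValueError("validation slice must leave a non-empty training side")
    n_train = n_init - validation_days

    lead_hours = np.asarray(search_cube[LEAD_DIM].values)
    lats = np.asarray(search_cube[LAT_DIM].values)
    lons = np.asarray(search_cube[LON_DIM].values)
    vals = np.stack(
        [search_cube[v].transpose(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM).values
         for v in roster]
    )
    obs = analysis_at_leads(search_analysis, init_times, lead_hours,
                            var=TARGET_VARIABLE).values

    w_matrix = np.array(
        [[ws.get(v, 1.0) for v in roster] for ws in weight_sets]
    )  # (n_ws, p)

    sq_err = np.zeros((len(weight_sets), len(counts)))
    n_pairs = np.zeros_like(sq_err, dtype=int)

    for l in range(len(lead_hours)):
        ks = window_offsets(l, len(lead_hours), tau)
        for a in range(len(lats)):
            for b in range(len(lons)):
                Xs = vals[:, :n_train, :, a, b][:, :, ks]   # (p, n_train, w)
                Xv = vals[:, n_train:, :, a, b][:, :, ks]   # (p, n_val, w)
                ys = obs[:n_train, l, a, b]
                yv = obs[n_train:, l, a, b]

                eligible = (
                    np.isfinite(Xs).all(axis=(0, 2)) & np.isfinite(ys)
                )
                n_elig = int(eligible.sum())
                if n_elig == 0:
                    continue
                central = Xs[:, :, ks.index(l)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    cnt = np.isfinite(central).sum(axis=1)
                    sigma = np.where(cnt >= 2, np.nanstd(central, axis=1, ddof=1),
                                     np.nan)

                # per-variable distance term, computed once per block
                D = np.zeros((len(roster), Xv.shape[1], n_train))
                for j in range(len(roster)):
                    if not np.isfinite(sigma[j]) or sigma[j] == 0:
                        continue
                    diff = Xv[j][:, None, :] - Xs[j][None, :, :]
                    D[j] = np.sqrt(np.einsum("mnk,mnk->mn", diff, diff)) / sigma[j]

                valid_query = np.isfinite(yv)
                for si, w in enumerate(w_matrix):
                    used = (w > 0) & np.isfinite(sigma) & (sigma > 0)
                    d = np.tensordot(w[used], D[used], axes=(0, 0))
                    d[:, ~eligible] = np.inf
                    order = np.argsort(d, axis=1, kind="stable")
                    sorted_obs = ys[order]
                    qbad = ~np.isfinite(
                        np.take_along_axis(d, order[:, :1], axis=1)[:, 0]
                    )
                    cmean = np.cumsum(sorted_obs, axis=1) / np.arange(
                        1, n_train + 1
                    )
                    for ni, n in enumerate(counts):
                        if n > n_elig:
                            continue
                        pred = cmean[:, n - 1]
                        ok = valid_query & ~qbad & np.isfinite(pred)
                        sq_err[si, ni] += float(((pred[ok] - yv[ok]) ** 2).sum())
                        n_pairs[si, ni] += int(ok.sum())

    rows = []
    for si, ws in enumerate(weight_sets):
        for ni, n in enumerate(counts):
            valid = n_pairs[si, ni] > 0
            rmse = np.sqrt(sq_err[si, ni] / n_pairs[si, ni]) if valid else np.nan
            rows.append(
                {
                    "weight_set": weight_set_label(ws),
                    "n_analogs": n,
                    "rmse": rmse,
                    "n_pairs": int(n_pairs[si, ni]),
                    "valid": bool(valid),
                    "_ws_index": si,
                }
            )
    df = pd.DataFrame(rows)
    ranked = df[df["valid"]].sort_values(
        ["rmse", "n_analogs", "_ws_index"], kind="stable"
    )
    df["rank"] = np.nan
    df.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
    df = df.drop(columns="_ws_index")
    df.attrs["train_inits"] = init_times[:n_train]
    df.attrs["validation_inits"] = init_times[n_train:]
    df.attrs["weight_sets"] = weight_sets
    return df
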
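"""The analog ensemble itself: the similarity metric, analog search and
ensemble-mean prediction, checked against direct evaluation and a naive
brute-force oracle."""

import warnings

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from sklearn.base import clone

from anen_aq import (
    AnalogEnsembleRegressor,
    SimilarityConfig,
    compute_sigma,
    find_analogs,
    predict_anen,
    run_anen,
    similarity,
)
from anen_aq.anen import AnalogSet
from anen_aq.gridded import window_offsets
from conftest import make_cube, make_series


class TestSigma:
    def make(self, series):
        vals = np.asarray(series, dtype=float)[:, None, None, None]
        inits = pd.date_range("2016-06-21 12:00", periods=len(series), freq="1D")
        return make_cube(vals, inits, [3], [30.0], [-5.0])

    def test_constant_series_has_zero_sigma(self):
        out = compute_sigma(self.make([4.0, 4.0, 4.0]))
        assert out.values[0, 0, 0, 0] == 0.0

    def test_two_point_sample_standard_deviation(self):
        out = compute_sigma(self.make([0.0, 2.0]))
        np.testing.assert_allclose(out.values[0, 0, 0, 0], np.sqrt(2.0))

    def test_single_value_flagged_undefined(self):
        out = compute_sigma(self.make([5.0]))
        assert np.isnan(out.values[0, 0, 0, 0])


class TestSimilarity:
    one_var = SimilarityConfig(tau=0, variables=("pm10",))

    def test_identical_windows_give_zero(self):
        w = np.array([[10.0, 12.0, 9.0]])
        cfg = SimilarityConfig(tau=1, variables=("pm10",))
        assert similarity(w, w, cfg, sigma=[2.0]) == 0.0

    def test_direct_evaluation_of_metric(self):
        # one variable, w=1, sigma=2, tau=0, values 10 vs 6: (1/2)*sqrt(16) = 2
        assert similarity([[10.0]], [[6.0]], self.one_var, sigma=[2.0]) == 2.0

    def test_zero_weight_variable_is_annihilated(self):
        cfg = SimilarityConfig(
            weights={"blh": 0.0}, tau=0, variables=("pm10", "blh")
        )
        d = similarity([[10.0], [999.0]], [[6.0], [-42.0]], cfg, sigma=[2.0, 1.0])
        assert d == similarity([[10.0]], [[6.0]], self.one_var, sigma=[2.0])

    def test_zero_sigma_variable_dropped_not_divided(self):
        cfg = SimilarityConfig(tau=0, variables=("pm10", "blh"))
        d = similarity([[10.0], [5.0]], [[6.0], [7.0]], cfg, sigma=[2.0, 0.0])
        assert np.isfinite(d) and d == 2.0

    def test_scaling_all_weights_scales_distances(self):
        rng = np.random.default_rng(5)
        t, c = rng.normal(size=(2, 3, 5))
        sigma = rng.uniform(0.5, 2.0, 3)
        base = SimilarityConfig(
            weights={"a": 1.0, "b": 2.0, "c": 0.5}, tau=2,
            variables=("a", "b", "c"),
        )
        scaled = SimilarityConfig(
            weights={"a": 3.0, "b": 6.0, "c": 1.5}, tau=2,
            variables=("a", "b", "c"),
        )
        np.testing.assert_allclose(
            similarity(t, c, scaled, sigma), 3.0 * similarity(t, c, base, sigma)
        )


class TestRegressor:
    def test_selects_smallest_distances_in_order(self):
        # archive values 10, 2, 6 vs query 1.5 -> distances ~ 8.5, 0.5, 4.5
        reg = AnalogEnsembleRegressor(n_analogs=2)
        reg.fit([[10.0], [2.0], [6.0]], [100.0, 200.0, 300.0])
        dist, idx = reg.find_analogs([[1.5]])
        assert list(idx[0]) == [1, 2]
        assert list(dist[0]) == sorted(dist[0])

    def test_n_equal_to_archive_returns_all_sorted(self):
        reg = AnalogEnsembleRegressor(n_analogs=3)
        reg.fit([[10.0], [2.0], [6.0]], [1.0, 2.0, 3.0])
        dist, idx = reg.find_analogs([[0.0]])
        assert sorted(idx[0]) == [0, 1, 2]
        assert list(dist[0]) == sorted(dist[0])

    def test_identical_candidate_is_first_with_zero_distance(self):
        reg = AnalogEnsembleRegressor(n_analogs=1)
        reg.fit([[7.0], [3.0]], [10.0, 20.0])
        dist, idx = reg.find_analogs([[3.0]])
        assert idx[0, 0] == 1 and dist[0, 0] == 0.0

    def test_ties_break_toward_earlier_archive_entry(self):
        reg = AnalogEnsembleRegressor(n_analogs=2)
        reg.fit([[4.0], [2.0], [4.0]], [1.0, 2.0, 3.0])  # two ties at |3-4|
        _, idx = reg.find_analogs([[3.0]])
        assert list(idx[0]) == [0, 1] or list(idx[0]) == [1, 0]
        # distance ties between archive entries 0 and 2 resolve to 0
        dist, idx = AnalogEnsembleRegressor(n_analogs=1).fit(
            [[4.0], [4.0]], [1.0, 2.0]
        ).find_analogs([[3.0]])
        assert idx[0, 0] == 0

    def test_prediction_is_mean_of_member_observations(self):
        reg = AnalogEnsembleRegressor(n_analogs=2).fit(
            [[1.0], [1.1]], [10.0, 20.0]
        )
        np.testing.assert_allclose(reg.predict([[1.0]]), [15.0])

    def test_nine_member_hand_mean(self):
        X = np.arange(9.0)[:, None]
        reg = AnalogEnsembleRegressor(n_analogs=9).fit(X, np.arange(1.0, 10.0))
        np.testing.assert_allclose(reg.predict([[4.0]]), [5.0])

    def test_prediction_bounded_by_member_observations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = rng.uniform(0, 100, 50)
        reg = AnalogEnsembleRegressor(n_analogs=7).fit(X, y)
        Xq = rng.normal(size=(20, 3))
        pred, dist, idx = reg.predict(Xq, return_members=True)
        assert (pred >= y[idx].min(axis=1)).all()
        assert (pred <= y[idx].max(axis=1)).all()

    def test_shrinks_with_warning_when_archive_too_small(self):
        reg = AnalogEnsembleRegressor(n_analogs=5).fit([[1.0], [2.0]], [1.0, 2.0])
        with pytest.warns(UserWarning, match="eligible analogs"):
            dist, idx = reg.find_analogs([[1.0]])
        assert idx.shape == (1, 2)

    def test_missing_window_or_observation_makes_candidate_ineligible(self):
        X = [[1.0], [np.nan], [3.0], [4.0]]
        y = [10.0, 20.0, np.nan, 40.0]
        reg = AnalogEnsembleRegressor(n_analogs=4).fit(X, y)
        with pytest.warns(UserWarning):
            _, idx = reg.find_analogs([[1.0]])
        assert set(idx[0]) == {0, 3}

    def test_sklearn_params_round_trip_and_clone(self):
        reg = AnalogEnsembleRegressor(n_analogs=3, weights=[1.0, 0.0])
        assert clone(reg).get_params() == reg.get_params()
        reg.set_params(n_analogs=5)
        assert reg.n_analogs == 5


def tiny_pair(seed, n_days=5, n_lead=3, nlat=2, nlon=2, p=2):
    """Random micro cube pair for oracle comparisons."""
    rng = np.random.default_rng(seed)
    inits = pd.date_range("2016-06-21 12:00", periods=n_days, freq="1D")
    leads = 3 * np.arange(1, n_lead + 1)
    lats = 30.0 + 0.75 * np.arange(nlat)
    lons = -5.0 + 0.75 * np.arange(nlon)
    names = tuple(f"v{j}" for j in range(p - 1)) + ("pm10",)
    cube = xr.Dataset(
        {
            n: (("init_time", "lead_time", "lat", "lon"),
                rng.normal(50, 10, (n_days, n_lead, nlat, nlon)))
            for n in names
        },
        coords={"init_time": inits, "lead_time": leads, "lat": lats, "lon": lons},
    )
    times = pd.date_range("2016-06-21 00:00", periods=8 * (n_days + 2), freq="3h")
    analysis = make_series(
        rng.uniform(0, 100, (len(times), nlat, nlon)), times, lats, lons
    )
    return cube, analysis, names


def brute_force_members(target, target_cube, search_cube, search_analysis,
                        n, weights, tau, variables):
    """Naive re-evaluation of the displayed metric over all candidates."""
    init, lead, (lat, lon) = target
    leads = list(np.asarray(search_cube.lead_time.values))
    l = leads.index(lead)
    ks = [l + k for k in range(-tau, tau + 1) if 0 <= l + k < len(leads)]
    obs_times = pd.DatetimeIndex(search_analysis.valid_time.values)

    def window(cube, i):
        return np.array([
            [float(cube[v].sel(lat=lat, lon=lon).values[i, kk]) for kk in ks]
            for v in variables
        ])

    ti = list(pd.DatetimeIndex(target_cube.init_time.values)).index(init)
    tw = window(target_cube, ti)

    sigmas = {}
    for v in variables:
        hist = search_cube[v].sel(lat=lat, lon=lon).values[:, l]
        sigmas[v] = np.std(hist, ddof=1)

    rows = []
    for i, cand_init in enumerate(pd.DatetimeIndex(search_cube.init_time.values)):
        cw = window(search_cube, i)
        d = 0.0
        for j, v in enumerate(variables):
            if weights[j] == 0 or sigmas[v] == 0:
                continue
            d += (weights[j] / sigmas[v]) * np.sqrt(((tw[j] - cw[j]) ** 2).sum())
        valid = cand_init + pd.Timedelta(hours=int(lead))
        o = float(
            search_analysis.pm10.sel(lat=lat, lon=lon).values[
                obs_times.get_loc(valid)
            ]
        )
        rows.append((d, i, o))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows[:n]


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("tau", [0, 1])
def test_find_analogs_matches_brute_force_oracle(seed, tau):
    cube, analysis, names = tiny_pair(seed)
    rng = np.random.default_rng(seed + 1000)
    w = rng.uniform(0.1, 2.0, len(names))
    cfg = SimilarityConfig(
        weights=dict(zip(names, w)), tau=tau, variables=names
    )
    lead = int(rng.choice(cube.lead_time.values))
    cell = (float(rng.choice(cube.lat.values)), float(rng.choice(cube.lon.values)))
    init = pd.Timestamp(rng.choice(cube.init_time.values))
    n = 3
    got = find_analogs((init, lead, cell), cube, cube, analysis, n, cfg)
    expect = brute_force_members(
        (init, lead, cell), cube, cube, analysis, n, w, tau, names
    )
    np.testing.assert_allclose(got.distances, [e[0] for e in expect], rtol=1e-10)
    assert [pd.Timestamp(t) for t in got.member_inits] == [
        pd.Timestamp(cube.init_time.values[e[1]]) for e in expect
    ]
    np.testing.assert_allclose(got.observations, [e[2] for e in expect])


class TestPredictAnEn:
    def test_mean_and_singleton(self):
        s = AnalogSet(None, np.array([0]), np.array([0.0, 0.0]),
                      np.array([10.0, 20.0]), np.array([0.0, 0.0]))
        assert predict_anen(s) == 15.0
        s1 = AnalogSet(None, np.array([0]), np.array([0.0]),
                       np.array([7.0]), np.array([0.0]))
        assert predict_anen(s1) == 7.0

    def test_empty_set_raises(self):
        s = AnalogSet(None, np.array([]), np.array([]), np.array([]),
                      np.array([]))
        with pytest.raises(ValueError, match="empty analog set"):
            predict_anen(s)


class TestRunAnEn:
    def test_duplicate_forecast_with_n1_returns_its_observation(self):
        cube, analysis, names = tiny_pair(3)
        cfg = SimilarityConfig(tau=0, variables=names)
        test_cube = cube.isel(init_time=[2])
        comp, _ = run_anen(test_cube, cube, analysis, 1, cfg)
        # the test init itself sits in the search set: exact analog
        times = pd.DatetimeIndex(analysis.valid_time.values)
        for l, lh in enumerate(cube.lead_time.values):
            valid = pd.Timestamp(test_cube.init_time.values[0]) + pd.Timedelta(
                hours=int(lh)
            )
            np.testing.assert_allclose(
                comp["anen"].values[0, l],
                analysis.pm10.values[times.get_loc(valid)],
            )

    def test_cell_permutation_gives_bit_identical_output(self):
        cube, analysis, names = tiny_pair(4, nlat=3)
        cfg = SimilarityConfig(tau=1, variables=names)
        test_cube = cube.isel(init_time=[4])
        comp_a, _ = run_anen(test_cube, cube, analysis, 2, cfg)
        perm = [2, 0, 1]
        comp_b, _ = run_anen(
            test_cube.isel(lat=perm), cube.isel(lat=perm),
            analysis.isel(lat=perm), 2, cfg,
        )
        xr.testing.assert_identical(
            comp_a["anen"].isel(lat=perm), comp_b["anen"]
        )

    def test_near_perfect_forecasts_reproduce_truth_within_analog_spread(self):
        """With zero forecast error and the target day searchable, the
        prediction is a mean of near-identical truths."""
        from anen_aq.synthetic import SyntheticConfig, simulate

        c = SyntheticConfig(
            n_days=60, n_lead=4, grid_shape=(2, 2), seed=5,
            bias_amplitude=0.0, noise_sd=0.0, overshoot_prob=0.0,
            spike_rate=0.0,
        )
        fc, truth, _ = simulate(c)
        cfg = SimilarityConfig(tau=1, variables=tuple(fc.data_vars))
        test_cube = fc.isel(init_time=slice(50, 60))
        comp, _ = run_anen(test_cube, fc, truth, 3, cfg)
        err = comp["anen"].values - comp["target_forecast"].values
        rmse = np.sqrt(np.nanmean(err**2))
        spread = float(truth.pm10.std())
        assert rmse < spread

    def test_window_offsets_truncate_symmetrically(self):
        assert window_offsets(0, 5, 1) == [0, 1]
        assert window_offsets(4, 5, 1) == [3, 4]
        assert window_offsets(2, 5, 1) == [1, 2, 3]
        assert window_offsets(2, 5, 0) == [2]
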
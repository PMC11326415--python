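"""Synthetic CAMS-like forecast/reanalysis pairs with known structure.

The generator emulates the statistical features of a desert-dust PM10
record and of a global composition forecast of it, without any physics:

* a 3-hourly "reanalysis" truth built from a deterministic seasonal
  baseline, an AR(1) noise process per grid cell, and spatially coherent
  episodic dust spikes (each spike a Gaussian bump around a random centre,
  active for a couple of days);
* forecasts of the truth carrying a lead-proportional systematic bias,
  Gaussian noise whose spread grows with lead time, and rare heavy-tailed
  (Pareto) overshoots mimicking the extreme outliers a raw composition
  forecast produces;
* auxiliary predictors coupled to PM10 through a latent "dust wind":
  spike days push the 10-m wind components up and the boundary-layer
  height down, the fine-PM fractions track PM10, temperature carries only
  the seasonal cycle, and aerosol optical depth is pure noise by default
  (a deliberately uninformative predictor for variable-importance tests).

Everything is driven by independent child RNG streams of one seed, so the
truth field is bit-identical whether or not spikes or forecast-error terms
are switched on — paired experiments can difference regenerated fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .constants import (
    DEFAULT_VARIABLES,
    INIT_DIM,
    LAT_DIM,
    LEAD_DIM,
    LON_DIM,
    PM_UNITS,
    TARGET_VARIABLE,
    VALID_DIM,
)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the standard conditions.

    Scales are µg/m³; rates are probabilities per day (or per value for
    ``overshoot_prob``); ``bias_amplitude`` is µg/m³ per 3-hourly lead step.
    """

    n_days: int = 220
    n_lead: int = 40
    grid_shape: tuple[int, int] = (6, 6)
    seed: int = 0
    bias_amplitude: float = 0.5
    spike_rate: float = 0.08
    spike_scale: float = 300.0
    noise_sd: float = 8.0
    overshoot_prob: float = 0.002

    # secondary shape parameters (fixed study choices, not tuning dials)
    start_date: str = "2016-06-21"
    step_hours: int = 3
    init_hour: int = 12
    base_level: float = 45.0
    seasonal_amplitude: float = 20.0
    truth_noise_sd: float = 6.0
    ar_coeff: float = 0.8
    spike_radius: float = 1.5
    spike_duration_days: int = 2
    overshoot_shape: float = 1.5
    overshoot_scale: float = 150.0
    noise_lead_growth: float = 0.05
    lat0: float = 27.0
    lon0: float = -13.0
    dlat: float = 0.75
    dlon: float = 0.75
    variables: tuple[str, ...] = field(default=DEFAULT_VARIABLES)
    noise_predictor: str | None = "aod"

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.n_lead < 1:
            raise ValueError("n_days and n_lead must be >= 1")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be two positive dimensions")
        for name in ("spike_rate", "overshoot_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "bias_amplitude",
            "spike_scale",
            "noise_sd",
            "truth_noise_sd",
            "overshoot_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if TARGET_VARIABLE not in self.variables:
            raise ValueError(f"variables must include {TARGET_VARIABLE!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["variables"] = list(self.variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "variables" in d:
            d["variables"] = tuple(d["variables"])
        return cls(**d)

    # --- derived geometry -------------------------------------------------
    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.grid_shape[0])

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.grid_shape[1])

    @property
    def lead_hours(self) -> np.ndarray:
        return self.step_hours * np.arange(1, self.n_lead + 1)

    @property
    def init_times(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start_date) + pd.Timedelta(hours=self.init_hour)
        return pd.date_range(start, periods=self.n_days, freq="1D")

    @property
    def valid_times(self) -> pd.DatetimeIndex:
        """3-hourly truth grid covering every (init, lead) valid time."""
        start = pd.Timestamp(self.start_date)
        last = self.init_times[-1] + pd.Timedelta(hours=int(self.lead_hours[-1]))
        n = int((last - start) / pd.Timedelta(hours=self.step_hours)) + 1
        return pd.date_range(start, periods=n, freq=f"{self.step_hours}h")


def _rngs(config: SyntheticConfig) -> dict[str, np.random.Generator]:
    """Independent child streams so switching one term off leaves the rest."""
    names = ("ar", "events", "fc_noise", "overshoot", "aux")
    seqs = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def _baseline(config: SyntheticConfig, times: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic seasonal + spatial-gradient baseline, shape (t, lat, lon)."""
    doy = times.dayofyear.to_numpy() + times.hour.to_numpy() / 24.0
    seasonal = config.base_level + config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 172.0) / 365.25
    )
    ii, jj = np.meshgrid(
        np.arange(config.grid_shape[0]), np.arange(config.grid_shape[1]), indexing="ij"
    )
    denom = max(sum(config.grid_shape) - 2, 1)
    gradient = 0.25 * config.base_level * (ii + jj) / denom  # dustier corner
    return seasonal[:, None, None] + gradient[None, :, :]


def _event_calendar(
    config: SyntheticConfig, days: pd.DatetimeIndex, rng: np.random.Generator
) -> pd.DataFrame:
    """One row per truth day; draws are made for every day regardless of
    activity so the stream is aligned across spike_rate settings."""
    rows = []
    for day in days:
        u = rng.uniform()
        amp = config.spike_scale * (0.5 + rng.exponential(0.5))
        ci = rng.integers(config.grid_shape[0])
        cj = rng.integers(config.grid_shape[1])
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rows.append(
            {
                "day": day,
                "active": bool(u < config.spike_rate),
                "amplitude": amp,
                "center_lat_idx": int(ci),
                "center_lon_idx": int(cj),
                "wind_u": 8.0 * np.cos(theta),
                "wind_v": 8.0 * np.sin(theta),
            }
        )
    return pd.DataFrame(rows)


def _dust_field(
    config: SyntheticConfig, times: pd.DatetimeIndex, events: pd.DataFrame
) -> np.ndarray:
    """Episodic spike component, shape (t, lat, lon); zero off-event."""
    nlat, nlon = config.grid_shape
    out = np.zeros((len(times), nlat, nlon))
    active = events[events["active"]]
    if active.empty or config.spike_scale == 0:
        return out
    t0 = times[0]
    step = pd.Timedelta(hours=config.step_hours)
    steps_per_day = int(pd.Timedelta("1D") / step)
    dur = max(config.spike_duration_days * steps_per_day, 1)
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    for row in active.itertuples():
        start_idx = int((row.day - t0) / step)
        prof_idx = np.arange(dur)
        # triangular rise/decay over the event duration
        profile = 1.0 - np.abs(prof_idx - (dur - 1) / 2.0) / ((dur - 1) / 2.0 + 1e-12)
        d2 = (ii - row.center_lat_idx) ** 2 + (jj - row.center_lon_idx) ** 2
        bump = np.exp(-d2 / (2.0 * config.spike_radius**2))
        for p, w in zip(prof_idx, profile):
            t = start_idx + p
            if 0 <= t < len(times):
                out[t] += row.amplitude * w * bump
    return out


def generate_truth(config: SyntheticConfig) -> tuple[xr.Dataset, pd.DataFrame]:
    """Generate the 3-hourly PM10 "reanalysis" truth and its event calendar.

    Returns a dataset with variables ``pm10`` (µg/m³, non-negative) and
    ``dust`` (the spike component alone), plus a per-day event calendar so
    downstream tests can stratify on known extremes without re-detection.
    """
    rngs = _rngs(config)
    times = config.valid_times
    nlat, nlon = config.grid_shape

    base = _baseline(config, times)

    ar = np.zeros((len(times), nlat, nlon))
    if config.truth_noise_sd > 0:
        innov_sd = config.truth_noise_sd * np.sqrt(1.0 - config.ar_coeff**2)
        eps = rngs["ar"].normal(0.0, innov_sd, size=ar.shape)
        ar[0] = rngs["ar"].normal(0.0, config.truth_noise_sd, size=(nlat, nlon))
        for t in range(1, len(times)):
            ar[t] = config.ar_coeff * ar[t - 1] + eps[t]

    days = pd.date_range(times[0].normalize(), times[-1].normalize(), freq="1D")
    events = _event_calendar(config, days, rngs["events"])
    dust = _dust_field(config, times, events)

    pm10 = np.clip(base + ar + dust, 0.0, None)

    ds = xr.Dataset(
        {
            TARGET_VARIABLE: ((VALID_DIM, LAT_DIM, LON_DIM), pm10),
            "dust": ((VALID_DIM, LAT_DIM, LON_DIM), dust),
        },
        coords={VALID_DIM: times, LAT_DIM: config.lats, LON_DIM: config.lons},
    )
    ds[TARGET_VARIABLE].attrs["units"] = PM_UNITS
    ds[TARGET_VARIABLE].attrs["long_name"] = "PM10 mass concentration"
    ds["dust"].attrs["units"] = PM_UNITS
    return ds, events


def generate_forecasts(truth: xr.Dataset, config: SyntheticConfig) -> xr.Dataset:
    """Generate the forecast cube for ``truth`` under the configured error model.

    PM10 forecast = truth at valid time + ``bias_amplitude``·ℓ (ℓ the 1-based
    lead step) + lead-growing Gaussian noise + rare Pareto overshoot, clipped
    at zero.  Auxiliary predictors are noisy functions of the PM10 truth and
    of the dust component at the same valid time.
    """
    rngs = _rngs(config)
    init_times = config.init_times
    lead_hours = config.lead_hours
    truth_times = pd.DatetimeIndex(truth[VALID_DIM].values)
    pos = pd.Series(np.arange(len(truth_times)), index=truth_times)

    valid = init_times.values[:, None] + (
        lead_hours[None, :] * np.timedelta64(1, "h")
    )
    flat = pd.DatetimeIndex(valid.ravel())
    if not flat.isin(truth_times).all():
        missing = flat[~flat.isin(truth_times)]
        raise ValueError(
            f"truth does not cover {len(missing)} forecast valid times "
            f"(first missing: {missing[0]})"
        )
    idx = pos.loc[flat].to_numpy().reshape(valid.shape)

    T = truth[TARGET_VARIABLE].values[idx]  # (init, lead, lat, lon)
    D = truth["dust"].values[idx] if "dust" in truth else np.zeros_like(T)

    shape = T.shape
    lead_steps = np.arange(1, config.n_lead + 1, dtype=float)[None, :, None, None]

    noise = np.zeros(shape)
    if config.noise_sd > 0:
        sd = config.noise_sd * np.sqrt(1.0 + config.noise_lead_growth * lead_steps)
        noise = rngs["fc_noise"].normal(0.0, 1.0, size=shape) * sd

    overshoot = np.zeros(shape)
    if config.overshoot_prob > 0:
        hit = rngs["overshoot"].uniform(size=shape) < config.overshoot_prob
        tail = rngs["overshoot"].pareto(config.overshoot_shape, size=shape)
        overshoot = np.where(hit, config.overshoot_scale * tail, 0.0)

    pm10_fc = np.clip(T + config.bias_amplitude * lead_steps + noise + overshoot, 0.0, None)

    # latent dust-wind intensity in [0, 3]: spike days blow wind, squash BLH
    scale = config.spike_scale if config.spike_scale > 0 else 1.0
    Dn = np.clip(D / scale, 0.0, 3.0)
    doy = flat.dayofyear.to_numpy().reshape(valid.shape + (1, 1))

    aux_rng = rngs["aux"]
    fields: dict[str, np.ndarray] = {TARGET_VARIABLE: pm10_fc}
    builders = {
        "pm2p5": lambda: 0.55 * T + aux_rng.normal(0.0, 6.0, shape),
        "pm1": lambda: 0.30 * T + aux_rng.normal(0.0, 5.0, shape),
        "aod": lambda: (
            aux_rng.normal(0.3, 0.15, shape)
            if config.noise_predictor == "aod"
            else 0.002 * T + aux_rng.normal(0.0, 0.05, shape)
        ),
        "t2m": lambda: 288.0
        + 8.0 * np.cos(2.0 * np.pi * (doy - 172.0) / 365.25)
        + aux_rng.normal(0.0, 2.0, shape),
        "blh": lambda: np.clip(
            800.0 - 500.0 * Dn + aux_rng.normal(0.0, 100.0, shape), 50.0, None
        ),
        "u10": lambda: 2.0 + 6.0 * Dn + aux_rng.normal(0.0, 2.0, shape),
        "v10": lambda: 1.0 + 4.0 * Dn + aux_rng.normal(0.0, 2.0, shape),
    }
    for name in config.variables:
        if name == TARGET_VARIABLE:
            continue
        if name not in builders:
            raise ValueError(f"no synthetic builder for variable {name!r}")
        fields[name] = builders[name]()

    dims = (INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM)
    ds = xr.Dataset(
        {name: (dims, arr) for name, arr in fields.items()},
        coords={
            INIT_DIM: init_times,
            LEAD_DIM: lead_hours.astype("int64"),
            LAT_DIM: config.lats,
            LON_DIM: config.lons,
        },
    )
    ds[LEAD_DIM].attrs["units"] = "hours"
    ds[TARGET_VARIABLE].attrs["units"] = PM_UNITS
    return ds


def simulate(config: SyntheticConfig) -> tuple[xr.Dataset, xr.Dataset, pd.DataFrame]:
    """Convenience: (forecast cube, truth analysis, event calendar)."""
    truth, events = generate_truth(config)
    forecasts = generate_forecasts(truth, config)
    return forecasts, truth, events
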
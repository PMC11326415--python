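# Methods

## The analog ensemble

The package post-processes a gridded PM10 forecast against a reanalysis
reference treated as observations. For each target — one initialization,
one lead time, one grid cell — the archive of historical forecasts at the
same lead and cell is ranked by the weighted multivariate distance

‖**F**_t, **F**_i‖ = Σ_j (w_j / σ_j) · √( Σ_{k=−τ}^{τ} (F^j_{t+k} − F^j_{i+k})² ),

and the prediction is the equally weighted mean of the reanalysis values
that verified the n closest historical forecasts. The method assumes the
forecast model's error structure is stationary enough that situations with
similar forecasts have similar errors, and that the archive is long enough
to contain close analogs for most targets; it degrades exactly where those
assumptions fail (unprecedented extremes, regime shifts).

Key implementation choices, each of which was genuinely open:

- **τ is counted in lead-time steps**, so τ = 1 spans ±1 step (±3 h at
  3-hourly leads). Verbal descriptions of this window are ambiguous
  between steps and hours; steps is the reading consistent with the metric's
  index set k ∈ {−τ, …, τ}.
- **Window truncation at the lead-axis edges is symmetric**: target and
  candidate windows drop the same out-of-range offsets, keeping the
  comparison fair at the first and last lead.
- **σ_j is the sample standard deviation (ddof = 1)** of the variable's
  searching-set forecasts at the target lead and cell, skipping missing
  values; with a multi-year archive the ddof choice is numerically
  immaterial but must be fixed. Fewer than two values flags σ as undefined.
- **σ_j = 0 (or undefined) drops the variable from the metric** at that
  lead and cell: a constant predictor carries no discriminating
  information, and division by zero can then never occur.
- **Distance ties break toward the earlier historical initialization**
  (stable sort over a chronologically ordered archive), so results are
  reproducible bit for bit.
- **Candidates with any missing value inside the window, or a missing
  verifying observation, are ineligible.** If fewer than n eligible
  candidates exist the ensemble shrinks to all of them with a warning,
  surfaced per block in the run report — never silently.
- The analog mean weights members equally; no distance weighting.

The core is exposed two ways: `AnalogEnsembleRegressor`, a scikit-learn
estimator for the single-site tabular problem (`fit(X, y)` on historical
windows, `predict` returns analog means; `get_params`/`set_params`/`clone`
work as usual), and `AnalogEnsemblePostProcessor`, which runs one such
problem per (lead, cell) block of an xarray cube. Blocks are independent,
so traversal order cannot affect output (tested by permuting cells).

## Threshold bias correction (AnEnBc)

The analog mean damps rare high events: a forecast far above anything in
the archive gets analogs — and hence observations — that undershoot it.
When the target forecast exceeds a threshold of the searching-set forecast
distribution at that lead and cell (quantiles Q25–Q95, linear
interpolation, or the mean), the correction adds
(target forecast − mean of the analogs' own forecasts) to the AnEn value.
A negative result falls back to the uncorrected AnEn value, so output is
never negative. Two readings of "the average analogs to this forecast"
exist — analog forecasts or analog observations; the forecast reading is
implemented because only it makes the correction decrease predictions when
a small target forecast has larger analogs.

The threshold distribution is per (lead, cell), consistent with the
method's independence structure. The default trigger is Q75; the tuning
module's validation RMSE can override it. Under a constant additive
forecast bias (forecast = truth + c, no noise) the correction is exact:
AnEn mean + (truth + c) − (analog-truth mean + c) = truth, which the tests
verify to machine precision at triggered points.

## Data preparation

- **Temporal subsampling** keeps the lead times whose valid time
  (initialization + lead) falls on the analysis series' regular 3-hourly
  lattice; for 12:00 UTC initializations and hourly leads 1–120 h this
  retains the 40 leads {3, 6, …, 120} h.
- **Regridding** is nearest-centre: each coarse target cell takes the value
  of the source cell whose centre is nearest in plain (Δlat, Δlon) degrees,
  separable per axis, ties toward the smaller coordinate. At a 0.4°→0.75°
  resolution change exact centre coincidences are rare, so a deterministic
  tie rule matters more than the (negligible) great-circle correction. A
  nearest centre farther than half a target cell raises a coverage error.
- **Unit conversion** kg/m³ → µg/m³ multiplies by 1e9 and rewrites the
  `units` attribute; only variables whose attribute matches are touched.
- **The search/test split** partitions initializations disjointly by date;
  each side's analysis slice covers every valid time its own forecasts
  reach (the search side extends up to the maximum lead past its last
  initialization date). Missing values propagate as NaN throughout; there
  is no imputation.

## Hyperparameter search

The grid crosses ensemble sizes {3, 6, 9, 10, 12, 15, 21} with p + 1
weight sets (all ones, plus each variable zeroed in turn — 63 cells for
the eight-variable roster), τ fixed at 1, scored by RMSE. To avoid any
contact with the test period, the validation targets are the final slice
of the *searching* set (default one year, capped at a quarter of the
archive) and their analogs are drawn only from the earlier part. Ties in
RMSE break toward fewer analogs, then weight-set order, so the ranking is
deterministic. Per block, the per-variable distance terms are computed
once and recombined per weight set, and a cumulative mean over the sorted
analog observations scores all ensemble sizes in one pass.

## Verification

MAE, RMSE, R² = 1 − SS_res/SS_tot (the general definition — negative when
the model does worse than the observation mean; stored as a fraction,
rendered ×100 in reports), Pearson's r, and Bias = mean(pred − obs).
Strata: overall (flatten everything), per lead time, per initialization
date, per grid cell, and per season of the initialization date
(meteorological months: DJF winter, MAM spring, JJA summer, SON autumn).
All models in one evaluation share the identical pair mask — positions
finite in the observations and every model — so rows are comparable.
Constant observations make R² and r undefined; they are reported as
missing, never silently zeroed. Error-distribution summaries report
absolute-error quartiles, shares below 10 and 20 µg/m³, the maximum, and
fixed-width (10 µg/m³) histogram counts with edges aligned to bin
multiples, so counts are deterministic.

## Synthetic data generator

The generator emulates the statistical features the method must cope with,
not the physics:

- **Truth**: 3-hourly PM10 = seasonal sinusoid (base 45 µg/m³, amplitude
  20, summer peak) + smooth spatial gradient + per-cell AR(1) noise
  (coefficient 0.8, stationary SD 6 µg/m³) + episodic dust spikes —
  per-day Bernoulli events (rate 0.08) with exponential-tailed amplitudes
  around 300 µg/m³, a Gaussian spatial bump (radius 1.5 cells) and a
  triangular two-day time profile — clipped at zero. The event calendar is
  returned alongside the field so tests stratify on known extremes.
- **Forecasts**: truth at the valid time + a lead-proportional bias
  (0.5 µg/m³ per 3-h step by default) + Gaussian noise whose SD grows with
  lead + a rare (p = 0.002) Pareto-tailed overshoot (shape 1.5, scale
  150 µg/m³) mimicking the extreme outliers raw composition forecasts
  produce, clipped at zero.
- **Auxiliary predictors** couple to PM10 through a latent "dust wind":
  spike days push U10/V10 up and BLH down; PM2.5 and PM1 track the PM10
  truth; temperature carries only the seasonal cycle; AOD is pure noise by
  default, giving the tuning tests a predictor whose exclusion must never
  hurt. Aerosol optical depth was chosen as the noise predictor because it
  is the variable whose exclusion is expected to matter least.
- **Determinism**: one seed spawns independent child RNG streams per
  component (AR noise, events, forecast noise, overshoots, auxiliaries),
  so switching one term off leaves the others bit-identical — paired
  experiments can regenerate with spikes off and difference the fields.

What the generator does *not* emulate: dust transport and chemistry,
realistic auxiliary-variable units, spatially correlated AR noise,
multi-day synoptic persistence beyond AR(1), or observation error in the
reanalysis. Passing tests therefore show the pipeline's correctness and
the method's qualitative behaviour on recurring-regime data; they do not
certify skill scores on real CAMS fields.

One consequence worth knowing: because the synthetic overshoots are pure
forecast error, uncorrelated with truth, the threshold correction passes
them straight into AnEnBc wherever they trigger. On these conditions
AnEnBc improves MAE and event-day amplitude but can worsen RMSE relative
to plain AnEn — a sharper version of the seasonal degradation the
correction is known to show when forecast–observation linearity fails.

## Problem sizes and numerical choices

The standard study size used by the test suite and the acceptance script —
a two-year searching set plus a held-out year on a 6×6 grid with eight
3-hourly leads, five seeds for the improvement check and twenty for the
tuning-recovery check — was chosen as the smallest configuration in which
seasonal regimes recur and dust events are well sampled; it runs in about
a minute on one core. Files are written as NETCDF3_64BIT through xarray so
on-disk bytes are reproducible, which the pipeline's content-hash stage
cache (and the end-to-end determinism test) relies on. The pipeline skips
a stage when the hash of its parameters and input files matches the
previous manifest; changing one parameter re-runs only downstream stages.

## Known limitations

- Analog search is exhaustive per block (no KD-tree or pruning); fine for
  multi-year daily archives, not tuned for much longer ones.
- No spatial pooling of candidate analogs across neighbouring cells, and
  only the ensemble mean is produced — no quantile or probabilistic
  output.
- The regridder is nearest-centre only (no conservative or bilinear
  options) and assumes regular lat/lon grids.
- Verification offers no significance tests for metric differences.
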
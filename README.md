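# slopefill

Percentile-based slope-constrained linear interpolation for gap filling
in highly volatile univariate time series, with daily PM2.5
concentration records as the motivating application.

## The problem

Air-quality monitoring stations lose observations to sensor faults,
maintenance and power failures, and most downstream analyses need
complete series. Linear interpolation is the workhorse for short gaps,
but it places no control on the *slope* of the reconstruction: when a
gap is bracketed by anchors at very different levels — one of them on a
pollution spike, say — the chord implies day-to-day changes the series
never actually exhibits. Higher-order splines are worse: quadratic and
cubic interpolants overshoot and ring near sharp peaks.

## The method

For a series x₁,…,x_N with missing entries:

1. **Slope distribution.** Compute first-order differences of adjacent
   observed pairs, Δxᵢ = xᵢ − xᵢ₋₁, and their magnitudes sᵢ = |Δxᵢ|
   (pairs spanning a missing day are excluded — a difference over k
   days is not a daily slope).
2. **Threshold.** τ = Percentileₚ({sᵢ}), with p = 95 by default: the
   largest day-to-day change considered plausible.
3. **Interpolate.** Fill each gap between anchors (t_a, x_a), (t_b, x_b)
   with the chord x̂ₖ(lin) = x_a + (t_k − t_a)/(t_b − t_a)·(x_b − x_a).
4. **Constrain.** Sweep each gap left to right. With x̂ₖ₋₁ the previous
   *finalised* value (x_a for the first point), if
   |x̂ₖ(lin) − x̂ₖ₋₁| > τ set x̂ₖ = x̂ₖ₋₁ + sign(·)·τ, else keep the
   linear value. Observed values are never modified; the reconnection
   step to the right anchor is left unconstrained and reported as a
   diagnostic.

The whole procedure is O(N), has a single data-driven parameter, and
returns a per-point audit log of every clipping decision.

The package also ships the evaluation apparatus used to study the
method: a synthetic volatile-series generator (seasonal baseline,
AR(1) weather noise, multi-day multiplicative pollution episodes),
MCAR mask simulation on a progressive 5–50% rate grid, spline and
global value-clipping baselines, R²/MAE/RMSE scoring at the masked
positions, and a paired benchmark harness (all methods score against
byte-identical masks per draw).

## Worked example

```python
from slopefill import (SyntheticSpec, generate_series, mcar_mask, apply_mask,
                       impute, coefficient_of_variation, score_imputation)

series = generate_series(SyntheticSpec(seed=0))     # one synthetic year
cv, category = coefficient_of_variation(series)
print(f"CV = {cv:.4f} ({category} variability)")

mask = mcar_mask(series, rate=0.10, seed=1)         # blank 10% of interior days
holed, truth = apply_mask(series, mask)

result = impute(holed, p=95.0)                      # slope-constrained fill
print(f"tau = {result.threshold.tau:.2f} ug/m3 per day")
print(f"imputed {result.n_imputed} points, clipped {result.n_clipped}")

report = score_imputation(series, result, mask)     # score masked positions
print(f"R2 = {report.r2:.3f}  MAE = {report.mae:.2f}  RMSE = {report.rmse:.2f}")
```

prints

```
CV = 0.8478 (high variability)
tau = 23.69 ug/m3 per day
imputed 36 points, clipped 2
R2 = 0.384  MAE = 5.60  RMSE = 10.36
```

The generated year is in the high-volatility regime (CV > 0.5). The
95th percentile of its observed absolute daily slopes sets the step
bound τ; of the 36 reconstructed days, 2 had a chord step steeper than
τ and were clipped. The scores compare reconstruction and truth at the
masked days only — observed days are reproduced exactly by
construction.

The same pipeline is available from the shell:

```sh
slopefill synth --length 366 --seed 0 --out series.csv
slopefill mask --rate 0.1 --seed 1 --in series.csv --out holed.csv
slopefill impute --in holed.csv --out filled.csv --audit audit.csv
slopefill threshold --in series.csv
slopefill cv --in series.csv
slopefill bench progressive --in series.csv --repeats 30 --seed 0 --out report.csv
```

Series files are two-column delimited text (`date,value`, ISO-8601
dates or integer indices, blank/`NA`/`NaN` for missing).

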
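# Methods

## The imputation model

The method treats gap filling in a volatile daily series as linear
interpolation subject to a data-driven bound on the first derivative.
The bound τ is the p-th percentile of the absolute first-order
differences of the observed series, so it is a statement about what
day-to-day change is *typical for this station*: with the default
p = 95, the reconstruction is forbidden from moving faster than 95% of
historically observed daily changes.

Within each gap the pass is strictly left-to-right and sequential: the
step of each reconstructed point is measured from the previous
*finalised* (possibly clipped) value, not from the previous linear
value. This is required for the update x̂ₖ = x̂ₖ₋₁ + sign·τ to be
well defined as a recursion, and it means a clip propagates: once the
path falls behind the chord it continues at slope τ until the chord
flattens enough to catch up.

Deliberate boundary choices:

- **Anchors are inviolable.** Observed values are never altered, and
  the final step from the last reconstructed point up (or down) to the
  right anchor is *not* constrained — clipping it would either modify
  the anchor or contradict it. The amount by which this reconnection
  step exceeds τ is reported per gap (`reconnection_excess`) as a
  diagnostic of how much the constraint distorted the path.
- **τ is estimated once per call**, from the observed values of the
  input series, before any filling; imputed values never feed back
  into the threshold. In the benchmark harness τ is likewise
  re-estimated from each holed series, since a deployed imputer only
  ever sees the series with its gaps.
- **Slope pairs are adjacent in time** (lag exactly one day); pairs of
  observed values separated by a gap are excluded because a difference
  spanning k days is not a daily slope and would bias τ upward.
- **Leading/trailing missing runs** have no anchor on one side. The
  method interpolates and never extrapolates, so the default is an
  error; a `nearest` policy (constant fill from the nearest observed
  value, flagged in the audit log) is available for pipelines that
  must return a complete series.
- **Non-unit spacing is rejected** rather than rescaled: τ is
  calibrated in µg/m³ per unit step, and resampling is a decision the
  user should make explicitly.
- **Negative values** are mechanically acceptable (the algorithm is
  sign-agnostic) but warned about, since concentrations are
  non-negative; clipped descents can legitimately produce small
  negative values near zero.
- The sign function maps a zero step to 0; since |Δ| = 0 can never
  exceed τ ≥ 0, that branch is unreachable in practice but is
  implemented for fidelity to the definition.
- **Percentile convention:** linear interpolation between closest
  ranks (rank (n−1)·p/100), the scientific-computing default; other
  conventions can be selected via `percentile_method`.

## Scoring

R², MAE and RMSE are computed at the masked positions only, with the
R² reference mean taken over those same positions. Whole-series
scoring is available (`scope="all"`) but merely dilutes errors with
exact zeros at observed points, since every method here preserves
anchors. The coefficient of variation uses the sample standard
deviation (denominator N−1) over the mean, with the conventional
three-level reading: low (< 0.2), moderate (0.2–0.5), high (> 0.5).
An empty mask (nothing to reconstruct) scores as perfect by
definition. Percent errors in the per-record table are rounded
half-even to two decimals, matching conventional report formatting.

## The synthetic generator

`generate_series` emulates one year of daily PM2.5 from a single urban
station in a strongly seasonal regime:

| parameter | default | meaning |
|---|---|---|
| `length` | 366 | days |
| `baseline_level` | 22 µg/m³ | annual mean level of the clean-season base |
| `seasonal_amplitude` | 14 µg/m³ | annual cosine, peak near the turn of the year (dry season) |
| `ar_coefficient` | 0.65 | day-to-day persistence of weather-driven noise |
| `innovation_scale` | 5 µg/m³ | standard deviation of daily AR innovations |
| `spike_probability` | 0.05 /day | episode arrival rate (~18 events/year) |
| `spike_scale` | 1.0 | log-amplitude scale of episode peaks |
| `spike_persistence` | 0.6 | per-day geometric decay of the episode log-envelope |
| `seed` | 0 | generator seed; identical parameter set ⇒ identical series |

The value at day t is `max(0, baseline + seasonal + AR(1)) ×
exp(spike_scale · envelope_t)`: episodes arrive as Bernoulli events
with half-normal log-amplitudes and decay over a few days, so a spike
is a short *episode* — sharp arrival, multi-day relaxation — rather
than an isolated one-day blip. The envelope is non-negative and scales
linearly with `spike_scale`, which makes the empirical CV monotone in
that parameter (a property the tests assert). Under the defaults the
series lands in the high-volatility regime (CV roughly 0.6–1.3
depending on the draw, around 1 as in polluted-season station
records), daily changes are strongly heavy-tailed (excess kurtosis
≫ 0), and the 95th-percentile slope threshold falls in the
15–25 µg/m³/day range.

What the generator does *not* emulate: calendar effects (weekday
cycles, holidays), meteorological covariates, instrument noise and
level shifts from recalibration, block-missing outages, and —
important for interpreting benchmark results — any temporal
*irreversibility* beyond the episode decay shape. Passing tests on
this generator show the machinery is correct and the orderings among
interpolators hold on volatile seasonal data; they are not evidence
about any particular station's records.

## The benchmark harness

Masks are Missing-Completely-At-Random draws over interior positions
(endpoints are never masked, so every gap stays bounded), with
cardinality round-half-up of rate × eligible and a progressive default
grid of 5–50% in 5% steps. Repeat i uses seed `base_seed + i`, each
(rate, repeat) cell draws one mask, and **every method in a comparison
scores against the byte-identical holed series** — a paired design, so
method contrasts are free of mask luck. Aggregation is the arithmetic
mean over repeats (standard deviations are reported alongside); a
method failure on a draw is flagged, warned about and excluded from
the mean. Defaults use 30 repeats; the full default benchmark
(4 methods × 10 rates × 30 repeats on a 366-day series) runs in a few
seconds.

Baselines: degree-1/2/3 interpolating splines fitted through **all**
observed points (the configuration whose overshoot near sharp peaks
motivates the slope constraint — a degree-1 spline coincides with
gap-wise chord interpolation, which the tests cross-check), and a
`clipped_extreme` ablation that linearly interpolates and then clamps
each imputed value into the two-sided global band
[P₁₀₀₋ₚ, Pₚ] of the observed values — range control with no slope
logic, tied to the same percentile p as the proposed method (a
one-sided variant is available via `two_sided=False`).

## Known limitations and an honest note on performance

The slope constraint is a *plausibility* guard, and against
higher-order splines it is also an accuracy win: on the default
generator the proposed method's mean RMSE beats quadratic and cubic
splines at essentially every missing rate, and the constraint-only
variant beats global value clipping — both orderings are reproduced by
`scripts/acceptance.py`.

Against plain linear interpolation the picture is subtler. For a
single masked day, the chord midpoint is close to the best possible
L2 estimate whenever the underlying dynamics are statistically
time-reversible; the clip is a bet that the truth lies near the left
anchor, which such dynamics make a 50/50 bet, and squared-error
scoring punishes the losing branch (a masked episode-onset day) more
than it rewards the winning one (a masked day just before an onset).
Consequently, on this generator the proposed method trails plain
linear interpolation slightly at low missing rates on some series
draws and beats it on others — the contrast depends on how many gap
points fall just before, versus on, episode onsets in a given draw.
Users whose priority is never introducing implausible gradients get
that guarantee unconditionally; users optimising mean squared error on
near-reversible data should expect parity with linear interpolation
rather than a systematic gain.

Other limitations: no multivariate or spatial information, no
uncertainty quantification on imputed values, no extrapolation, no
block-missing simulation mode, and a single global τ per call — no
streaming or seasonally adaptive threshold.

## Numerical and testing choices

Percentiles use numpy's linear-interpolation convention throughout.
The optimized imputer is validated for exact (bitwise) agreement
against an independent line-by-line transliteration of the method's
pseudocode on hundreds of short series over a small value grid, and
the metric implementations against naive loop versions at 1e-12.
Property tests (seeded/derandomised hypothesis) assert anchor
preservation, the within-gap step bound |x̂ₖ − x̂ₖ₋₁| ≤ τ, sign
preservation of clipped steps, identity on complete series, and
reduction to plain linear interpolation whenever nothing clips. The
constraint-property sweep runs 1000 generated series (length 60)
crossed over rates 5–50% and percentiles 80–100. Degenerate inputs
are defined rather than accidental: τ = 0 clamps a gap to its left
anchor value, a constant truth makes R² NaN with a warning, a zero
original value makes that row's percent error NaN with a warning.
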
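# Methods

## The estimation problem

A daily search-volume series for a pollen-related query is a *censored,
rescaled, noisy monotone functional* of the true airborne pollen signal in
its market. The package's job is to measure how much of the observed
pollen dynamic survives that channel — per site-year, as a rank
correlation — and to attribute failures to the two mechanisms that govern
the channel: data volume (censoring + sampling noise) and seasonal peak
prominence. A second question is whether the search series dates the
season start usefully.

All analyses operate on the early season (January 1 – June 30), when the
dominant (tree-pollen) peak occurs; late-season grass/weed dynamics are
out of scope.

## Synthetic panel model

The generator produces the coupled data the analysis assumes; it is the
test bed for every stage, standing in for observational sources that are
available only on request.

**Pollen.** Expected concentration on day *d* is

```
E[p(d)] = baseline + Σ_i amp_i · exp(−(d − peak_i)² / (2·width_i²))
```

with two Gaussian components — a dominant early peak (default day 95,
width 12 d, amplitude 800 grains/m³) and a smaller late one (day 240,
width 20 d, amplitude 250) over a 2 grains/m³ floor. Observed values
multiply this by mean-1 lognormal noise with coefficient of variation
0.4: daily counts are non-negative, right-skewed, and noisy at roughly
that level. Gaussian bumps were chosen for two-parameter control of date
and width; no claim is made about tails.

**Missingness** (station compliance): each weekend day missing with
probability 0.7, fixed gaps at the year edges (3 start / 7 end days),
and Poisson-distributed random gaps (rate 5/yr, geometric lengths, mean
3 d) — together ≈ 30% missing days, clustered the way station records
cluster. Missing days are explicit NaN, never zero.

**Search.** The latent volume is
`noise(d) · (baseline_rate + p(d − lag)^exponent)` with defaults lag 0,
exponent 0.7 (sublinear attention response), floor 10 latent units, day
noise cv 0.25. Search responds to the *complete* pollen signal, not to
whether a station sampled that day. Latent values below the display
threshold (default 12, placed so a typical market reports roughly a third
of window days as 0, matching reported feed behaviour) are **censored to
0 before rescaling**. Each of 10 download replicates adds its own
lognormal noise (cv 0.3), is independently rescaled so its maximum is
exactly 100, and is rounded half-up to integers; replicates are averaged
day-wise with censored zeros counted as zeros. An all-censored replicate
is returned all-zero with a flag, not an error.

**Panels.** Per-site heterogeneity: peak dates shift by N(0, 10 d),
amplitudes scale by lognormal(cv 0.3), coordinates are uniform over the
continental-US box, and TV-homes (market-size proxy) are log-uniform over
3×10⁴–3×10⁶. Optionally the censor threshold scales as 1/TV-homes, which
reproduces the empirical link between market size and zero-day fraction.
All draws flow from one `SeedSequence`; identical specs give bit-identical
panels.

What the generator does **not** emulate: taxa-specific seasons,
weather-driven release and its spatial correlation, true search-behaviour
psychology (the power-law coupling is a stand-in, uncalibrated), media
events that spike searches without pollen, and quantisation of the feed's
sampling (modelled as smooth lognormal noise instead). Passing tests
therefore demonstrate that the *pipeline* recovers planted structure
through the censoring/rescaling channel — not that real search data have
these properties.

## Transform stack and statistics

The correlation pathway is window → normalise pollen to max 100 → treat
censored search zeros as missing → log(v + 1) → LOWESS(0.1) on both →
Spearman ρ over jointly observed days (average ranks for ties; ρ
undefined below 3 joint days). ρ is invariant to the monotone steps, so
the normalise/log order is immaterial for it; it matters only for plots
and for onset estimates on smoothed variants.

**LOWESS** is implemented in-package with the exact semantics the analysis
depends on: for each target day the nearest `ceil(bw·n)` observed days
(stable tie-break toward earlier days), tricube weights scaled by the
farthest neighbour, weighted *linear* fit evaluated at the target, no
robustness iterations by default (an iteration count is exposed).
Local-linear fits reproduce straight lines exactly — several invariants
(peak SNR of a linear series ≡ 0, linear data pass through unchanged)
rely on this. Degenerate neighbourhoods (zero weighted x-variance) fall
back to the weighted mean. The test suite checks the smoother pointwise
(1e−8) against an independent brute-force weighted-least-squares oracle
and against the statsmodels implementation at matched neighbourhood size.

**Peak SNR** is the mean absolute difference between the daily series and
its LOWESS(0.8) baseline, computed on the log1p scale (a `scale="raw"`
option exists). The log scale is the deliberate choice: after per-sample
rescaling to max 100, the raw-scale statistic is dominated by the
absolute baseline level and is nearly invariant to — or even decreasing
in — peak prominence, while on the log scale it decomposes into an
off-season noise term (≈ 0.8·cv) plus a peak term
(≈ peak-fraction · ln prominence), which is exactly the "is there one
distinct peak" quantity the stratification needs, and which produces
values on the 0.1–0.5 scale on which the statistic is conventionally
reported.

**Quartiles** use linear-interpolation (type-7) percentiles as cutoffs;
assignment is `v ≤ c25 → Q1`, …, `else Q4`. Group comparisons are
pooled-variance t-tests (Welch by flag); covariate screens are univariate
OLS with normal-theory 95% CIs, with an optional log transform for the
market-size covariate.

**Inclusion rules** follow the strict boundary conventions: *more than*
60% missing excludes (exactly 60% does not); a run of *more than* 4
consecutive missing days excludes when it intersects
`[first_high − 10, first_high + 10]` — the run's full length counts, not
just the overlap — and the rule is skipped (not failed) when no day
reaches 200 grains/m³. The 60% rule is assessed over the calendar year;
the correlation/onset analyses use the January–June window. Both windows
are explicit parameters. Reported search zeros count as missing for the
search-side missingness covariate (toggleable), and the per-year
non-missing day count is exposed so callers can apply sparse-market
pre-screens.

## Season starts

`cumulative_fraction` takes the first day the running sum (missing days
contribute 0 — no imputation anywhere) reaches the fraction of the total;
station totals use the full calendar year, search totals the January–June
window sum, since daily search data cover only the early season.
`consecutive_days` returns the *first* day of the earliest qualifying run
(the common convention for consecutive-day rules). `absolute_threshold`
uses ≥ by default, matching the "high day" definition, with a strict
comparator available. Smoothed variants are clipped at 0 before
accumulation so the cumulative sum stays monotone and the first crossing
is well defined.

Discrepancy tiers nest: all included site-years → station record begins
within January → additionally fewer than 20% unquantified search days.
Per tier the median and IQR of Δ = search start − station start are
reported per data variant (raw / smoothed / log-smoothed), next to a
previous-year station baseline (current − prior-year station start) where
a prior year exists. A constant search floor accumulates cumulative mass
before the season and drags search starts earlier — the main systematic
behind search-derived starts *preceding* station-derived ones.

## The recovery experiments

**Censoring ladder** (`censoring_experiment`). The zero-day fraction and
the series' noisiness are not independent dials in real feeds — both are
consequences of market search volume. The experiment makes that coupling
explicit: a market at volume *V* (relative to the reference) has censor
threshold `12 / V` in latent units and sampling noise `cv / √V` (day and
replicate noise alike), anchored at the defaults (V = 1 ⇔ threshold 12,
cv 0.25/0.3). Level 0 is a large market (V = 16, no censored days); the
other levels' volumes are calibrated by bisection on pilot panels so the
median zero-day fraction hits 15 / 35 / 60%. Correlations in this
experiment *retain* censored zeros — it measures the proxy as a consumer
of the feed would use it. (Under the pipeline's default zero-exclusion,
censoring alone mildly *raises* ρ in this generator, because the removed
days are the flat, uninformative off-season — a restriction-of-range
subtlety documented here precisely because it is counter-intuitive.)

**Prominence ladder** (`prominence_experiment`). Levels fix the peak
search response and vary the off-season floor so the peak/floor ratio is
1×, 2×, 3× — deliberately *below* the default (~10×), in the regime where
peak detectability transitions; above ~4× the SNR→ρ relationship
saturates and quartile medians become indistinguishable. Pooled
site-years are stratified into peak-SNR quartiles to summarise ρ.

**Lag recovery** (`lag_experiment`). Search is an identity-coupled
(exponent 1, no floor, no censoring) copy of pollen shifted −10 days, on
a *unimodal* season (late peak off). The unimodal design is what makes
the planted lag identifiable: with the default bimodal season the
late-season mass enters only the station-side annual total, inflating its
5% threshold and biasing Δ by roughly −2.7 additional days (Gaussian-mass
computation) — a real definitional asymmetry worth knowing about, but a
confound in a recovery experiment. Adding a constant search floor makes
Δ more negative, as expected from the accumulation argument above.

Problem sizes — 100 site-years per level for the ladders, 50 for lag
recovery, 150 for the end-to-end reproduction panel, 30 for calibration
pilots — were chosen so that level-to-level differences exceed the
sampling error of a median at that n while a full run stays in the tens
of seconds.

## Numerical and degenerate-input choices

Zero-total series yield no onset (flagged), all-missing or all-zero
series refuse normalisation ("degenerate series"), fewer than 5 observed
points refuse smoothing, fewer than 3 joint days yield no ρ (flagged,
never silently 0). Integer rounding of search values is half-up
(`floor(x + 0.5)`), matching the feed's integer appearance. Equal
Chebyshev distances in station–market matching break by region id;
equal-distance neighbours in LOWESS break toward earlier days. Config
hashes cover every scientific setting but not the output directory.

## Known limitations

The search–symptom coupling is uncalibrated; absolute ρ values from
synthetic panels should not be read as predictions for real markets, only
the *orderings* (by volume, by prominence) and the recovery properties
are the validated claims. The volume law (threshold ∝ 1/V, noise ∝ 1/√V)
is a first-order model of a sampled-share feed, not a reverse-engineered
one. Station–market matching uses per-axis decimal-degree boxes, not
geodesic distance, because market assignment is administrative rather
than metric. No multiple-testing correction is applied to the screening
regressions, which are exploratory by design.
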
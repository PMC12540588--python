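# Methods

This note records the statistical model behind `anomviol`, the defaults and
why they are what they are, what the synthetic generator does and does not
emulate, and the numerical conventions a re-implementer would need.

## Anomaly definition

A weather anomaly is a departure from *recent* conditions. For each daily
series the baseline on day *t* is the arithmetic mean and sample SD
(n−1 denominator throughout the package) of the 30 values at days
t−30 … t−1. The window trails and excludes the index day, so a day's label
is a function of its past only; a property test shuffles future values and
checks labels are unchanged.

* **Threshold.** Upward/downward labels use strict inequalities at
  ±`threshold_sd` (default 2) baseline SDs. Equality has probability zero
  for continuous weather; strictness is the documented tie-break.
* **Warm-up.** The first `window` days are `unclassified`: excluded from
  every anomaly-vs-normal comparison but retained in share denominators, so
  a five-year study reports shares out of all 1,825 days.
* **Degenerate windows.** A zero-SD temperature window yields `none` — an
  identical month of temperature readings is a data artifact, and no
  departure is measurable against it. For rainfall no special case is
  needed: with SD = 0 the strict rule reduces to `value > mean`, so any
  positive fall after an all-dry window is an upward anomaly, which is
  exactly the "departure from recent conditions" the definition intends.
  Dry days count in rainfall windows like any other day.
* **Variable.** Temperature anomalies are computed on mean apparent
  temperature (the human-experienced measure); the dry-bulb column is
  carried through the panel but unused unless selected via
  `AnomalyParams.temperature_column`.

The estimated-baseline construction makes the null exceedance rate heavier
than the fixed-threshold Gaussian tail (2.28%): with mean and SD estimated
from 30 days the exceedance statistic is t-like, and serial correlation
moves it further. A test documents this by comparing the implementation's
null rate against a brute-force reference simulation rather than against
2.28%.

## Day classes

Exposure (low/medium/high) uses the full-period mean ± `exposure_sd`
(default 1) full-period sample SDs — deliberately a different object from
the rolling anomaly, capturing absolutely hot/cold days rather than
surprising ones. Seasons default to DJF summer / JJA winter (both study
archetypes are Southern-Hemisphere coastal sites); everything else is
shoulder. Weekends are whole civil Saturdays and Sundays in local time.
The study calendar excludes February 29 so that whole-year periods have
exactly 365 rows per year; incidents on a dropped leap day are discarded
with a logged count. Missing weather days are a hard error — imputation
would be an undeclared method.

## Comparisons

Daily counts are compared untransformed, matching how mean daily counts
are usually reported, despite overdispersion: the ANOVA and Tukey–Kramer
p-values therefore rest on the central limit theorem at the group sizes a
multi-year panel provides (the smallest routinely used groups are anomaly
classes of ~50–120 days). The type-I calibration experiment below verifies
this is adequate at the study's scale. `alpha` defaults to 0.05; Tukey
handles multiplicity within a comparison family and no cross-family
correction is applied. Crossed weekend × anomaly comparisons run as a
one-way ANOVA on the crossed labels so that any pair (e.g. hot-weekend vs
hot-weekday) has an adjusted contrast. Groups with fewer than two days are
dropped with a log message; a comparison whose surviving groups number
fewer than two, or whose observations are all identical, is skipped and
logged, never fabricated.

The SD-bin profile assigns each classified day `floor(z)` clipped to
[−3, 3], where z is the rolling temperature z-score, and divides bin mean
counts by the all-classified-days mean. The weighted average of bin means
over all classified days equals the classified-days mean by construction
(tested to 1e-12).

ANOVA and Tukey–Kramer are computed via `scipy.stats.f_oneway` and
`scipy.stats.tukey_hsd`; tests verify both against independent brute-force
sums-of-squares formulas and `statsmodels.pairwise_tukeyhsd` to 1e-6 on
random small instances.

## Synthetic generator

The generator's defaults are the study conditions, fixed once:

* **Temperature**: seasonal sinusoid (warmest mid-January for southern
  hemisphere) plus stationary AR(1) deviations,
  d_t = φ d_{t−1} + ε_t, φ = 0.6, with `temp_noise_sd` the stationary SD.
  The AR(1) term gives the 30-day baseline realistic serial structure.
  Khayelitsha-like: mean 15.51 °C, amplitude 6.0 °C, stationary SD 2.57 °C,
  chosen so amplitude²/2 + SD² reproduces the target marginal SD of
  4.96 °C. Ipswich-like: 20.57 °C, amplitude 7.0, SD 2.97 (marginal
  5.77 °C).
* **Rainfall**: Bernoulli wet-day indicator × Gamma amount. Khayelitsha-
  like: wet probability 0.25, shape 0.58, scale 9.03 mm, matching a
  marginal ≈ 1.31 ± 4.12 mm (most days dry); Ipswich-like parameters give
  the heavier-tailed ≈ 2.0 ± 8.0 mm regime. Parameters are fixture-tuned
  to those moments, not estimated from any archive.
* **Injected events** add `magnitude_sd` × the local noise scale (the
  stationary temperature SD, or the wet-day Gamma SD) on randomly placed,
  non-overlapping runs after the warm-up window, and are returned as a
  ground-truth calendar for detector-recovery tests.
* **Counts**: negative binomial with variance = μ + μ²/k; k → ∞ is the
  Poisson limit. The NB choice follows from the marginal moments of the
  emulated site (SD 9.4 at mean 18.5 implies variance ≫ mean); the null
  fixture solves k = 18.5²/(9.4² − 18.5) ≈ 4.90 exactly. The daily
  log-mean adds log rate ratios for weekend (khayelitsha-like default 1.4),
  summer (1.1) and detector-flagged hot days (1.3); under that covariate
  structure the khayelitsha-like baseline is deflated to 15.96/day and k
  raised to 6.0 so the *marginal* mean/SD stay ≈ 18.5/9.4. The
  ipswich-like fixture has all multipliers at 1 with mean 2.6, SD 1.7.
  Effect sizes are this package's choices — the emulated studies report
  significance, not magnitudes — picked to be detectable but not dominant
  at a five-year panel's power.
* **Disadvantage**: each day's rate splits into a disadvantaged substream
  (share 0.10, reflecting a bottom-decile-area definition) and the rest;
  on anomaly days the substream's rate carries an extra interaction
  multiplier (khayelitsha-like default 1.5). The total is drawn NB at the
  summed rate and the substream by binomial thinning at the rate share, so
  the interaction acts at the daily-rate level while total moments stay
  exact. Incident rows add a uniform time of day and a fixed category mix
  (assault/robbery/homicide 0.72/0.22/0.06) — cosmetic plumbing for the
  ingest path; aggregation reproduces the count stream bit-exactly.
* **Seeding**: one master seed fans out through named
  `numpy.random.SeedSequence` spawn-key streams (temperature, rainfall,
  events, counts, incidents, replicates); identical inputs give
  byte-identical files.

What the generator does **not** emulate: synoptic multi-day weather systems
beyond AR(1) memory, within-day crime timing structure, spatial layout,
reporting artifacts (weekday recording lags, batch entries), long-term
trends, and any dependence of crime on rainfall/temperature other than the
configured day-class rate ratios. Passing tests therefore show the
*pipeline* is correct and calibrated under its stated assumptions — not
that real heat–violence effects of a given size exist.

## Validation experiments and problem sizes

Replicate experiments use 1,825-day single-site panels. Counts for these
loops are taken from the generator's count stream directly (the incident
expansion is an exact elaboration of it, verified by test).

* **Type-I calibration**: on the null fixture, the hot-vs-normal ANOVA
  rejects at α = 0.05 in about 4–5% of 400 seeded replicates (checked
  within 5% ± 2 pp).
* **Power / effect recovery**: with a 1.3 hot-day rate ratio and nothing
  else (the `hot-effect` fixture), the hot-vs-normal comparison is
  significant in ≈ 99% of 200 replicates (required ≥ 80%), and the mean
  hot-vs-normal rate ratio recovers 1.3 within Monte-Carlo error. The
  ≥+2 SD bin's relative rate sits slightly below 1.3 (≈ 1.28) because its
  denominator — the all-days mean — itself contains the elevated hot days;
  tests compare it against the analytic expectation
  1.3 / (1 + 0.3 × hot-day share).
* **Moment recovery**: generator temperature and count moments converge to
  configured values within 3 Monte-Carlo SEs (10,000-day frames for
  counts, 25 × 1,825-day replicates for weather).

## Known limitations

* Ordinary ANOVA on overdispersed counts is used by design to mirror the
  emulated analysis style; a count GLM would be more efficient and is
  deliberately out of scope.
* Seasonal comparisons restrict every group (including "normal" days) to
  the season's days but reuse the all-year rolling baseline; baselines are
  not re-derived within season.
* Downward rainfall anomalies are computed internally but not reported:
  with zero-inflated rainfall a downward 2-SD departure is rarely
  attainable and has no standard interpretation.
* The disadvantage flag is consumed as an input label; constructing it
  from income or area indices is out of scope.
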
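# anomviol

Do unusually hot, cold or wet days move daily violent-crime counts?
`anomviol` implements a reusable pipeline for that question, built around a
short-memory definition of a weather anomaly: a day is anomalous when its
value departs from *recent* conditions, not from a long-run climatology.

The pipeline is aimed at analysts working with incident-level police
extracts and daily weather series (one coordinate per study site), and at
methodologists who want to stress-test this class of analysis on synthetic
data with known ground truth.

## Method

For a daily series $x_t$ (apparent temperature in °C or precipitation in
mm), the trailing baseline on day $t$ is the mean $\bar{x}_t$ and sample SD
$s_t$ of the window $x_{t-30}, \dots, x_{t-1}$ — the index day is excluded.
Day $t$ is an **upward anomaly** when $x_t > \bar{x}_t + 2 s_t$ and a
**downward anomaly** when $x_t < \bar{x}_t - 2 s_t$ (rainfall is analysed
for upward anomalies only; any positive fall after an all-dry window counts
as upward). The first 30 days are unclassifiable warm-up; they stay in
share denominators but out of comparisons.

Days also get coarser labels: **exposure** low/medium/high by ±1 SD around
the full-period mean apparent temperature, wet/dry, season (DJF summer, JJA
winter, else shoulder), and weekend (whole Saturdays and Sundays).

Mean daily violent-crime counts are then compared across classes — overall,
within season, crossed with weekend, and again on the disadvantaged-area
incident substream — with one-way ANOVA
($F = \mathrm{MS}_{between}/\mathrm{MS}_{within}$, df $(k-1, N-k)$) and
Tukey–Kramer all-pairs tests (studentized-range adjusted p, pooled
within-group variance, unequal group sizes allowed). A SD-bin profile
reports the daily crime rate relative to the panel mean by integer bins of
the rolling z-score.

The synthetic generator produces seeded two-site studies: sinusoidal
seasonal apparent temperature with AR(1) deviations, zero-inflated Gamma
rainfall, injected ground-truth hot/cold/wet events, and negative-binomial
daily counts with configurable weekend/summer/anomaly-day rate ratios and a
disadvantaged-substream interaction.

## Worked example

```python
from anomviol import run_fixture

run = run_fixture("khayelitsha-like", seed=7)
comp = run.results.get("khayelitsha", "temp_anomaly", "all")
for g in comp.groups:
    print(f"{g.label:>8}: n={g.n_days:4d}  mean={g.mean:6.2f}  sd={g.sd:5.2f}")
print(f"ANOVA: F={comp.anova_f:.2f}, df={comp.anova_df}, p={comp.anova_p:.2e}")
```

prints

```
downward: n=  74  mean= 18.68  sd= 8.22
    none: n=1651  mean= 18.32  sd= 9.39
  upward: n=  70  mean= 25.49  sd=11.52
ANOVA: F=19.39, df=(2, 1792), p=4.66e-09
```

Read: over a five-year synthetic panel (1,825 days; February 29 is excluded
so whole years have 365 rows), 70 days were flagged unusually hot. Their
mean daily count (25.5) exceeds anomaly-free days (18.3) by roughly the 1.3
rate ratio the fixture injects on detector-flagged hot days, and the
omnibus ANOVA rejects equality of the three class means. The Tukey output
(see `examples/03_compare_crime_by_class.py`) attributes the difference to
the upward-vs-none and upward-vs-downward pairs, not downward-vs-none.

The `examples/` directory has one short script per capability: fixture
generation, anomaly detection against ground truth, group comparisons and
the SD-bin profile, type-I/power calibration, and the CSV-file route. A
thin CLI mirrors the file route:

```sh
anomviol simulate --fixture khayelitsha-like --seed 4 --out data/
anomviol run --config study.yaml
```

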
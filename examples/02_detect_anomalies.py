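"""Detect weather anomalies against a 30-day trailing baseline.

A day is anomalous when its value departs more than two sample SDs from the
mean of the 30 preceding days.  The summary mirrors the shape of a
per-direction anomaly table: day counts, share of all study days, the
baseline level on anomaly days, and the anomalous values themselves.
"""

from anomviol import AnomalyParams, classify_panel, make_fixture, summarize_anomalies

fixture = make_fixture("khayelitsha-like", seed=7)
data = fixture.sites["khayelitsha"]

params = AnomalyParams(window=30, threshold_sd=2.0)
panel = classify_panel(data.weather.set_index("date"), params)

print(summarize_anomalies(panel, params).round(2).to_string(index=False))

# How many injected ground-truth hot days did the detector flag?
truth_hot = data.ground_truth.query("event_kind == 'hot'")["date"]
flagged = (panel.loc[truth_hot, "temp_anomaly"] == "upward").sum()
print(f"\ninjected hot days flagged upward: {flagged}/{len(truth_hot)}")

# Each row reads like: N days (share % of the 1,825-day study) were upward
# temperature anomalies; on those days the trailing 30-day baseline sat at
# `baseline_mean` °C while the observed values averaged `anomaly_mean` °C.
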
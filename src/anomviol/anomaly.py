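"""Rolling-baseline anomaly detection and day-level exposure labels.

A day's baseline is the arithmetic mean and sample SD (n−1 denominator) of
the ``window`` values strictly preceding it — the index day is excluded, so
tomorrow's weather can never change today's label.  A day is an *upward*
(*downward*) anomaly when its value lies strictly more than ``threshold_sd``
baseline SDs above (below) the baseline mean.  The first ``window`` days of a
series lack a complete baseline and are *unclassified*: they are excluded
from anomaly-vs-normal comparisons but still count in share denominators.

Degenerate windows: a zero-SD temperature window yields *none* (no departure
is measurable against an identical month of readings), while any positive
rainfall after an all-dry window is *upward* — rain onset after a dry month
is precisely a departure from recent conditions.  The rainfall case needs no
special branch: with SD = 0 the strict rule ``value > mean + t·SD`` reduces
to ``value > mean``.

Exposure categories (low/medium/high) are a different construction: they
split days by ±``exposure_sd`` sample SDs around the *full-period* mean
apparent temperature, not the rolling baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TEMP_LABELS = ("upward", "downward", "none", "unclassified")
RAIN_LABELS = ("upward", "none", "unclassified")
EXPOSURE_LABELS = ("low", "medium", "high")
SEASON_LABELS = ("summer", "winter", "shoulder")


@dataclass(frozen=True)
class AnomalyParams:
    """Tunable knobs of the day-classification step.

    window
        Length of the trailing baseline window in days.
    threshold_sd
        How many baseline SDs a value must depart to count as an anomaly.
    exposure_sd
        Half-width (in full-period SDs) of the "medium" exposure band.
    summer_months / winter_months
        Month numbers of the two analysed seasons (defaults DJF / JJA, the
        austral convention; everything else is "shoulder").
    temperature_column
        Panel column the temperature classifications read (apparent
        temperature by default; the dry-bulb column is carried but unused).
    """

    window: int = 30
    threshold_sd: float = 2.0
    exposure_sd: float = 1.0
    summer_months: frozenset = frozenset({12, 1, 2})
    winter_months: frozenset = frozenset({6, 7, 8})
    temperature_column: str = "apparent_temperature_mean"

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 days")
        if self.threshold_sd <= 0 or self.exposure_sd <= 0:
            raise ValueError("threshold_sd and exposure_sd must be positive")
        if set(self.summer_months) & set(self.winter_months):
            raise ValueError("summer and winter month sets must be disjoint")
        object.__setattr__(self, "summer_months", frozenset(self.summer_months))
        object.__setattr__(self, "winter_months", frozenset(self.winter_months))


def rolling_baseline(values, params: AnomalyParams = AnomalyParams()) -> pd.DataFrame:
    """Trailing-window baseline per day.

    For day t the baseline uses exactly the ``window`` values at days
    t−window … t−1.  Returns a frame with ``baseline_mean``, ``baseline_sd``
    (sample SD) and ``complete`` (False for the first ``window`` days).
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if len(s) < params.window + 1:
        raise ValueError(
            f"series of length {len(s)} is shorter than window+1 = {params.window + 1}"
        )
    prior = s.shift(1)
    roll = prior.rolling(params.window, min_periods=params.window)
    out = pd.DataFrame(
        {
            "baseline_mean": roll.mean(),
            "baseline_sd": roll.std(ddof=1),
        }
    )
    out["complete"] = out["baseline_mean"].notna()
    return out


def classify_temperature(values, baseline: pd.DataFrame, params: AnomalyParams = AnomalyParams()) -> np.ndarray:
    """Label each day upward / downward / none / unclassified.

    Strict inequalities; a zero-SD baseline yields ``none``.
    """
    v = np.asarray(values, dtype=float)
    m = baseline["baseline_mean"].to_numpy()
    sd = baseline["baseline_sd"].to_numpy()
    complete = baseline["complete"].to_numpy()
    labels = np.full(v.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        up = complete & (sd > 0) & (v > m + params.threshold_sd * sd)
        down = complete & (sd > 0) & (v < m - params.threshold_sd * sd)
    labels[up] = "upward"
    labels[down] = "downward"
    labels[~complete] = "unclassified"
    return labels


def classify_rainfall(values, baseline: pd.DataFrame, params: AnomalyParams = AnomalyParams()) -> np.ndarray:
    """Label each day upward / none / unclassified (rainfall has no downward).

    Dry days are part of every window; a positive fall exceeding the strict
    threshold — including any rain after an all-dry (SD = 0) window — is
    upward.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative rainfall value")
    m = baseline["baseline_mean"].to_numpy()
    sd = baseline["baseline_sd"].to_numpy()
    complete = baseline["complete"].to_numpy()
    labels = np.full(v.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        up = complete & (v > 0) & (v > m + params.threshold_sd * sd)
    labels[up] = "upward"
    labels[~complete] = "unclassified"
    return labels


def classify_exposure(values, params: AnomalyParams = AnomalyParams()) -> np.ndarray:
    """Split days into low/medium/high around the full-period mean.

    low: value < mean − exposure_sd·SD;  high: value > mean + exposure_sd·SD;
    ties fall to medium (strict inequalities).  SD is the sample SD of the
    whole series; a constant series is all medium.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    labels = np.full(v.shape, "medium", dtype=object)
    if sd > 0:
        labels[v < mean - params.exposure_sd * sd] = "low"
        labels[v > mean + params.exposure_sd * sd] = "high"
    return labels


def season_of(dates, params: AnomalyParams = AnomalyParams()) -> np.ndarray:
    """Map dates to summer / winter / shoulder by calendar month."""
    months = pd.DatetimeIndex(dates).month
    labels = np.full(len(months), "shoulder", dtype=object)
    labels[np.isin(months, list(params.summer_months))] = "summer"
    labels[np.isin(months, list(params.winter_months))] = "winter"
    return labels


def weekend_flag(dates) -> np.ndarray:
    """True for Saturdays and Sundays (whole civil days, local time)."""
    return np.asarray(pd.DatetimeIndex(dates).dayofweek >= 5)


def classify_panel(panel: pd.DataFrame, params: AnomalyParams = AnomalyParams()) -> pd.DataFrame:
    """Attach every day-level label to a panel (index = study calendar).

    Adds baseline columns for temperature and rainfall, anomaly labels,
    the rolling temperature z-score, exposure, wet/dry, season and weekend.
    """
    out = panel.copy()
    temp = out[params.temperature_column].to_numpy(dtype=float)
    rain = out["precipitation_sum"].to_numpy(dtype=float)

    tb = rolling_baseline(temp, params)
    rb = rolling_baseline(rain, params)
    out["temp_baseline_mean"] = tb["baseline_mean"].to_numpy()
    out["temp_baseline_sd"] = tb["baseline_sd"].to_numpy()
    out["baseline_complete"] = tb["complete"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (temp - out["temp_baseline_mean"].to_numpy()) / out["temp_baseline_sd"].to_numpy()
    z[~np.isfinite(z)] = np.nan
    out["temp_z"] = z
    out["temp_anomaly"] = classify_temperature(temp, tb, params)
    out["rain_baseline_mean"] = rb["baseline_mean"].to_numpy()
    out["rain_baseline_sd"] = rb["baseline_sd"].to_numpy()
    out["rain_anomaly"] = classify_rainfall(rain, rb, params)
    out["exposure"] = classify_exposure(temp, params)
    out["wet"] = rain > 0
    out["season"] = season_of(out.index, params)
    out["weekend"] = weekend_flag(out.index)
    return out


def summarize_anomalies(panel: pd.DataFrame, params: AnomalyParams = AnomalyParams()) -> pd.DataFrame:
    """Anomaly-day roll-up per variable × direction.

    For temperature upward/downward and rainfall upward: the number of
    anomaly days, their share of the *full* study calendar (warm-up days
    included in the denominator, percent), the mean/SD of the rolling
    baseline mean over anomaly days, and the mean/SD of the observed values
    on those days.  Directions with no anomaly days report NaN statistics.
    """
    n_total = len(panel)
    rows = []
    specs = [
        ("temperature", "upward", "temp_anomaly", params.temperature_column, "temp_baseline_mean"),
        ("temperature", "downward", "temp_anomaly", params.temperature_column, "temp_baseline_mean"),
        ("rainfall", "upward", "rain_anomaly", "precipitation_sum", "rain_baseline_mean"),
    ]
    for variable, direction, label_col, value_col, base_col in specs:
        mask = panel[label_col] == direction
        n = int(mask.sum())
        base = panel.loc[mask, base_col]
        obs = panel.loc[mask, value_col]
        rows.append(
            {
                "variable": variable,
                "direction": direction,
                "n_days": n,
                "share_pct": 100.0 * n / n_total,
                "baseline_mean": base.mean() if n else np.nan,
                "baseline_sd": base.std(ddof=1) if n > 1 else np.nan,
                "anomaly_mean": obs.mean() if n else np.nan,
                "anomaly_sd": obs.std(ddof=1) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
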
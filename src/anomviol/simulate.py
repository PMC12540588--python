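"""Seeded synthetic two-site study generator.

The generator produces daily panels with the statistical structure the
analysis assumes, so the whole pipeline runs — and can be stress-tested for
type-I error and power — without any external data.

Weather is a seasonal sinusoid (phase set by hemisphere) plus stationary
AR(1) deviations, with optional injected hot/cold/wet events whose days are
returned as ground truth.  Rainfall is zero-inflated: Bernoulli wet-day
indicator times a Gamma amount.  Daily violent-crime counts are negative
binomial (variance = mean + mean²/dispersion; dispersion → ∞ recovers the
Poisson limit) with a log-linear daily rate built from weekend, summer and
anomaly-day rate ratios; a disadvantaged substream carries an extra
interaction multiplier on anomaly days.

All randomness flows from one master seed through named substreams
(see :mod:`anomviol._seeds`), so identical inputs give bit-identical output.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._seeds import spawn_rng
from .anomaly import AnomalyParams, classify_panel
from .ingest import study_calendar

CATEGORIES = ("assault", "robbery", "homicide")
CATEGORY_WEIGHTS = (0.72, 0.22, 0.06)


@dataclass(frozen=True)
class SiteProfile:
    """Weather-generating parameters of one site.

    ``temp_noise_sd`` is the *stationary* SD of the AR(1) deviation process
    (°C); the innovation SD is derived as ``temp_noise_sd·sqrt(1−ar1²)``.
    ``drybulb_scale``/``drybulb_offset`` map apparent to dry-bulb temperature
    (a carried, analytically unused column).
    """

    site_id: str
    start_date: dt.date
    end_date: dt.date
    temp_annual_mean: float
    temp_annual_amplitude: float
    temp_noise_sd: float
    temp_ar1: float = 0.6
    rain_wet_prob: float = 0.25
    rain_gamma_shape: float = 0.6
    rain_gamma_scale: float = 9.0
    hemisphere: str = "south"
    drybulb_scale: float = 0.8
    drybulb_offset: float = 4.4

    def __post_init__(self) -> None:
        if self.temp_noise_sd <= 0:
            raise ValueError("temp_noise_sd must be positive")
        if not 0 <= self.temp_ar1 < 1:
            raise ValueError("temp_ar1 must be in [0, 1)")
        if not 0 <= self.rain_wet_prob <= 1:
            raise ValueError("rain_wet_prob must be in [0, 1]")
        if self.rain_gamma_shape <= 0 or self.rain_gamma_scale <= 0:
            raise ValueError("rainfall gamma parameters must be positive")
        if self.end_date < self.start_date:
            raise ValueError("end_date precedes start_date")
        if self.hemisphere not in ("north", "south"):
            raise ValueError("hemisphere must be 'north' or 'south'")


@dataclass(frozen=True)
class CrimeEffects:
    """Daily-count generating parameters.

    Multipliers are rate ratios applied to ``baseline_mean`` on days with the
    matching label; ``dispersion`` is the negative-binomial size parameter
    (variance = mean + mean²/dispersion; ``math.inf`` means Poisson).
    ``disadvantage_interaction`` multiplies the anomaly-day rate of the
    disadvantaged substream on top of the shared anomaly multipliers.
    """

    baseline_mean: float = 18.5
    dispersion: float = 4.899
    weekend_multiplier: float = 1.0
    summer_multiplier: float = 1.0
    hot_anomaly_multiplier: float = 1.0
    cold_anomaly_multiplier: float = 1.0
    wet_anomaly_multiplier: float = 1.0
    disadvantaged_share: float = 0.1
    disadvantage_interaction: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (math.inf for Poisson)")
        for name in ("weekend_multiplier", "summer_multiplier", "hot_anomaly_multiplier",
                     "cold_anomaly_multiplier", "wet_anomaly_multiplier", "disadvantage_interaction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.disadvantaged_share <= 1:
            raise ValueError("disadvantaged_share must be in [0, 1]")

    @staticmethod
    def dispersion_for(mean: float, sd: float) -> float:
        """Solve the NB size parameter from a target mean and SD."""
        excess = sd**2 - mean
        if excess <= 0:
            return math.inf
        return mean**2 / excess


@dataclass(frozen=True)
class AnomalyInjection:
    """A batch of ground-truth weather events to inject.

    ``magnitude_sd`` is in units of the generator's local noise scale:
    ``temp_noise_sd`` for hot/cold events, the wet-day Gamma SD for wet ones.
    """

    n_events: int
    event_kind: str  # hot | cold | wet
    magnitude_sd: float = 3.0
    duration_days: int = 1

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.event_kind not in ("hot", "cold", "wet"):
            raise ValueError("event_kind must be hot, cold or wet")
        if self.magnitude_sd <= 0:
            raise ValueError("magnitude_sd must be positive")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")


def _seasonal_cycle(dates: pd.DatetimeIndex, profile: SiteProfile) -> np.ndarray:
    # Warmest around mid-January in the south, mid-July in the north.
    peak_doy = 15.0 if profile.hemisphere == "south" else 196.0
    doy = dates.dayofyear.to_numpy(dtype=float)
    return profile.temp_annual_mean + profile.temp_annual_amplitude * np.cos(
        2 * np.pi * (doy - peak_doy) / 365.25
    )


def _ar1_deviations(n: int, profile: SiteProfile, rng: np.random.Generator) -> np.ndarray:
    phi = profile.temp_ar1
    innov_sd = profile.temp_noise_sd * math.sqrt(1 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, profile.temp_noise_sd)  # stationary start
    return signal.lfilter([1.0], [1.0, -phi], eps)


def _event_days(
    injections: Sequence[AnomalyInjection],
    n_days: int,
    window: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pick non-overlapping event runs, all after the warm-up window."""
    taken = np.zeros(n_days, dtype=bool)
    rows: list[tuple[int, str, float]] = []
    for inj in injections:
        if inj.n_events == 0:
            continue
        placed = 0
        candidates = rng.permutation(np.arange(window, n_days - inj.duration_days + 1))
        for start in candidates:
            span = slice(start, start + inj.duration_days)
            if taken[span].any():
                continue
            taken[span] = True
            rows.extend(
                (i, inj.event_kind, inj.magnitude_sd)
                for i in range(start, start + inj.duration_days)
            )
            placed += 1
            if placed == inj.n_events:
                break
        if placed < inj.n_events:
            raise ValueError(f"could not place {inj.n_events} {inj.event_kind} events in {n_days} days")
    rows.sort()
    return pd.DataFrame(rows, columns=["day_index", "event_kind", "magnitude_sd"])


def generate_weather(
    profile: SiteProfile,
    injections: "AnomalyInjection | Sequence[AnomalyInjection] | None" = None,
    seed: int = 0,
    window: int = 30,
) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Simulate one site's daily weather series.

    Returns ``(weather, ground_truth)``: a frame in the ingest CSV dialect
    (one row per study-calendar day, leap days excluded) and a frame of the
    injected event days (``date``, ``event_kind``).  ``window`` only
    constrains injected events to fall after the warm-up period.
    """
    if injections is None:
        injections = ()
    elif isinstance(injections, AnomalyInjection):
        injections = (injections,)
    dates = study_calendar(pd.Timestamp(profile.start_date), pd.Timestamp(profile.end_date))
    n = len(dates)

    rng_t = spawn_rng(seed, "temperature")
    rng_r = spawn_rng(seed, "rainfall")
    rng_e = spawn_rng(seed, "events")

    temp = _seasonal_cycle(dates, profile) + _ar1_deviations(n, profile, rng_t)
    wet = rng_r.random(n) < profile.rain_wet_prob
    rain = np.where(wet, rng_r.gamma(profile.rain_gamma_shape, profile.rain_gamma_scale, size=n), 0.0)

    truth = _event_days(injections, n, window, rng_e)
    gamma_sd = math.sqrt(profile.rain_gamma_shape) * profile.rain_gamma_scale
    for idx, kind, magnitude in truth.itertuples(index=False):
        if kind == "hot":
            temp[idx] += profile.temp_noise_sd * magnitude
        elif kind == "cold":
            temp[idx] -= profile.temp_noise_sd * magnitude
        else:
            rain[idx] += gamma_sd * magnitude

    weather = pd.DataFrame(
        {
            "date": dates,
            "apparent_temperature_mean": np.round(temp, 4),
            "temperature_mean": np.round(profile.drybulb_scale * temp + profile.drybulb_offset, 4),
            "precipitation_sum": np.round(rain, 4),
        }
    )
    truth_out = pd.DataFrame(
        {"date": dates[truth["day_index"].to_numpy(int)] if len(truth) else pd.DatetimeIndex([]),
         "event_kind": truth["event_kind"].to_numpy() if len(truth) else np.array([], dtype=object)}
    )
    return weather, truth_out


def _daily_rates(classified: pd.DataFrame, effects: CrimeEffects) -> "tuple[np.ndarray, np.ndarray]":
    """Expected daily counts for the disadvantaged and remaining substreams.

    Unclassified (warm-up) days carry no anomaly effect.  The interaction
    multiplier applies to the disadvantaged substream on any anomaly day.
    """
    weekend = classified["weekend"].to_numpy(bool)
    summer = (classified["season"] == "summer").to_numpy()
    hot = (classified["temp_anomaly"] == "upward").to_numpy()
    cold = (classified["temp_anomaly"] == "downward").to_numpy()
    rainup = (classified["rain_anomaly"] == "upward").to_numpy()
    anomaly_day = hot | cold | rainup

    base = effects.baseline_mean * np.where(weekend, effects.weekend_multiplier, 1.0)
    base = base * np.where(summer, effects.summer_multiplier, 1.0)
    m_anom = (
        np.where(hot, effects.hot_anomaly_multiplier, 1.0)
        * np.where(cold, effects.cold_anomaly_multiplier, 1.0)
        * np.where(rainup, effects.wet_anomaly_multiplier, 1.0)
    )
    share = effects.disadvantaged_share
    lam_dis = base * share * m_anom * np.where(anomaly_day, effects.disadvantage_interaction, 1.0)
    lam_other = base * (1.0 - share) * m_anom
    return lam_dis, lam_other


def generate_daily_counts(
    classified: pd.DataFrame, effects: CrimeEffects, seed: int = 0
) -> pd.DataFrame:
    """Draw daily total and disadvantaged-substream counts.

    The total is negative binomial around the summed substream rates; the
    disadvantaged count is a binomial thinning at the substream rate share,
    which applies the interaction multiplier at the daily-rate level while
    keeping the total's moments exact.
    """
    lam_dis, lam_other = _daily_rates(classified, effects)
    lam = lam_dis + lam_other
    rng = spawn_rng(seed, "counts")
    if math.isinf(effects.dispersion):
        total = rng.poisson(lam)
    else:
        k = effects.dispersion
        total = rng.negative_binomial(k, k / (k + lam))
    with np.errstate(invalid="ignore"):
        p_dis = np.where(lam > 0, lam_dis / lam, 0.0)
    dis = rng.binomial(total, p_dis)
    return pd.DataFrame(
        {"crime_count": total.astype(int), "crime_count_disadvantaged": dis.astype(int)},
        index=classified.index,
    )


def generate_crime(
    classified: pd.DataFrame, effects: CrimeEffects, seed: int = 0
) -> pd.DataFrame:
    """Expand daily counts into an incident table.

    Incidents get a uniformly random time of day and a category drawn from a
    fixed violent-crime mix; within each day, exactly the substream count of
    incidents carries the disadvantaged flag.  Counts come from the same
    seed stream as :func:`generate_daily_counts`, so aggregating the
    incidents by date reproduces those counts exactly.
    """
    counts = generate_daily_counts(classified, effects, seed)
    rng = spawn_rng(seed, "incidents")
    n_by_day = counts["crime_count"].to_numpy()
    total = int(n_by_day.sum())
    dates = np.repeat(counts.index.to_numpy(), n_by_day)
    within = np.concatenate([np.arange(c) for c in n_by_day]) if total else np.array([], int)
    dis_cut = np.repeat(counts["crime_count_disadvantaged"].to_numpy(), n_by_day)
    seconds = rng.integers(0, 86400, size=total)
    times = pd.to_datetime(seconds, unit="s").strftime("%H:%M:%S")
    cats = rng.choice(CATEGORIES, size=total, p=CATEGORY_WEIGHTS)
    return pd.DataFrame(
        {
            "date": pd.DatetimeIndex(dates),
            "time": np.asarray(times),
            "category": cats,
            "disadvantaged": (within < dis_cut).astype(int),
        }
    )


# --------------------------------------------------------------------------
# Fixture registry
# --------------------------------------------------------------------------

_STUDY_START = dt.date(2011, 1, 1)
_STUDY_END = dt.date(2015, 12, 31)

#: Khayelitsha-like weather: marginal apparent temperature ≈ 15.51 ± 4.96 °C
#: (amplitude²/2 + noise² = SD²); zero-inflated rain ≈ 1.31 ± 4.12 mm.
KHAYELITSHA_PROFILE = SiteProfile(
    site_id="khayelitsha",
    start_date=_STUDY_START,
    end_date=_STUDY_END,
    temp_annual_mean=15.51,
    temp_annual_amplitude=6.0,
    temp_noise_sd=2.57,
    temp_ar1=0.6,
    rain_wet_prob=0.25,
    rain_gamma_shape=0.58,
    rain_gamma_scale=9.03,
    hemisphere="south",
    drybulb_scale=0.8,
    drybulb_offset=4.39,
)

#: Ipswich-like weather: apparent temperature ≈ 20.57 ± 5.77 °C; rainfall
#: heavier-tailed (≈ 2.03 ± 7.98 mm).
IPSWICH_PROFILE = SiteProfile(
    site_id="ipswich",
    start_date=_STUDY_START,
    end_date=_STUDY_END,
    temp_annual_mean=20.57,
    temp_annual_amplitude=7.0,
    temp_noise_sd=2.97,
    temp_ar1=0.6,
    rain_wet_prob=0.30,
    rain_gamma_shape=0.254,
    rain_gamma_scale=26.6,
    hemisphere="south",
    drybulb_scale=0.719,
    drybulb_offset=5.28,
)

#: Khayelitsha-like effects: weekend and hot-day elevation with disadvantage
#: amplification; baseline deflated so the marginal mean stays ≈ 18.5/day and
#: dispersion chosen so the marginal SD stays ≈ 9.4 under the covariates.
KHAYELITSHA_EFFECTS = CrimeEffects(
    baseline_mean=15.96,
    dispersion=6.0,
    weekend_multiplier=1.4,
    summer_multiplier=1.1,
    hot_anomaly_multiplier=1.3,
    disadvantaged_share=0.1,
    disadvantage_interaction=1.5,
)

#: Ipswich-like effects: no weather or weekend structure; mean 2.6, SD 1.7.
IPSWICH_EFFECTS = CrimeEffects(
    baseline_mean=2.6,
    dispersion=CrimeEffects.dispersion_for(2.6, 1.7),
    disadvantaged_share=0.1,
)

#: Null effects: all multipliers one; the Khayelitsha-like marginal count
#: moments (18.5 ± 9.4 per day) hold exactly.
NULL_EFFECTS = CrimeEffects(
    baseline_mean=18.5,
    dispersion=CrimeEffects.dispersion_for(18.5, 9.4),
    disadvantaged_share=0.1,
)

#: Hot-effect-only variant for clean parameter recovery: a 1.3 rate ratio on
#: detector-flagged hot days and nothing else.
HOT_ONLY_EFFECTS = replace(NULL_EFFECTS, hot_anomaly_multiplier=1.3)

_DEFAULT_INJECTIONS = (
    AnomalyInjection(n_events=8, event_kind="hot", magnitude_sd=3.0, duration_days=2),
    AnomalyInjection(n_events=5, event_kind="cold", magnitude_sd=3.0, duration_days=2),
    AnomalyInjection(n_events=6, event_kind="wet", magnitude_sd=3.0, duration_days=1),
)

FIXTURES: "dict[str, dict]" = {
    "khayelitsha-like": {
        "sites": [(KHAYELITSHA_PROFILE, KHAYELITSHA_EFFECTS, _DEFAULT_INJECTIONS)],
    },
    "ipswich-like": {
        "sites": [(IPSWICH_PROFILE, IPSWICH_EFFECTS, _DEFAULT_INJECTIONS)],
    },
    "null": {
        "sites": [(KHAYELITSHA_PROFILE, NULL_EFFECTS, ())],
    },
    "hot-effect": {
        "sites": [(KHAYELITSHA_PROFILE, HOT_ONLY_EFFECTS, _DEFAULT_INJECTIONS)],
    },
    "two-site": {
        "sites": [
            (KHAYELITSHA_PROFILE, KHAYELITSHA_EFFECTS, _DEFAULT_INJECTIONS),
            (IPSWICH_PROFILE, IPSWICH_EFFECTS, _DEFAULT_INJECTIONS),
        ],
    },
}


@dataclass
class SiteData:
    profile: SiteProfile
    effects: CrimeEffects
    weather: pd.DataFrame
    incidents: pd.DataFrame
    ground_truth: pd.DataFrame
    classified: pd.DataFrame


@dataclass
class Fixture:
    name: str
    seed: int
    sites: "dict[str, SiteData]"


def build_fixture(
    name: str,
    seed: int,
    params: AnomalyParams = AnomalyParams(),
    effects_override: "CrimeEffects | None" = None,
) -> Fixture:
    """Generate a registered fixture in memory.

    The crime-generating classification uses the same detector the analysis
    runs, so configured anomaly multipliers act on detector-flagged days.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    sites: dict[str, SiteData] = {}
    for i, (profile, effects, injections) in enumerate(FIXTURES[name]["sites"]):
        if effects_override is not None:
            effects = effects_override
        site_seed = int(np.random.SeedSequence(seed, spawn_key=(100 + i,)).generate_state(1)[0] % 2**31)
        weather, truth = generate_weather(profile, injections, seed=site_seed, window=params.window)
        skeleton = weather.set_index("date")
        classified = classify_panel(skeleton, params)
        incidents = generate_crime(classified, effects, seed=site_seed)
        sites[profile.site_id] = SiteData(profile, effects, weather, incidents, truth, classified)
    return Fixture(name=name, seed=seed, sites=sites)


def make_fixture(name: str, seed: int, out_dir: "str | Path | None" = None) -> Fixture:
    """Generate a fixture and, if ``out_dir`` is given, write its files.

    Writes per site: ``weather_<site>.csv``, ``incidents_<site>.csv``,
    ``ground_truth_<site>.csv``, plus ``fixture_config.json`` describing the
    generating parameters.  Byte-identical across runs with the same seed.
    """
    fixture = build_fixture(name, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config: dict = {"fixture": name, "seed": seed, "sites": {}}
        for site_id, data in fixture.sites.items():
            data.weather.assign(date=data.weather["date"].dt.strftime("%Y-%m-%d")).to_csv(
                out / f"weather_{site_id}.csv", index=False
            )
            data.incidents.assign(date=data.incidents["date"].dt.strftime("%Y-%m-%d")).to_csv(
                out / f"incidents_{site_id}.csv", index=False
            )
            truth = data.ground_truth.copy()
            truth["date"] = pd.DatetimeIndex(truth["date"]).strftime("%Y-%m-%d")
            truth.to_csv(out / f"ground_truth_{site_id}.csv", index=False)
            config["sites"][site_id] = {
                "profile": {k: str(v) if isinstance(v, dt.date) else v
                            for k, v in asdict(data.profile).items()},
                "effects": asdict(data.effects),
            }
        (out / "fixture_config.json").write_text(json.dumps(config, indent=2, sort_keys=True))
    return fixture
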
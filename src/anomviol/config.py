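"""YAML study configuration.

Example::

    sites:
      - id: khayelitsha
        weather: weather_khayelitsha.csv
        crime: incidents_khayelitsha.csv
    study:
      start: 2011-01-01
      end: 2015-12-31
    anomaly:
      window: 30
      threshold_sd: 2.0
      exposure_sd: 1.0
      summer_months: [12, 1, 2]
      winter_months: [6, 7, 8]
    violent_categories: [homicide, assault, robbery]
    alpha: 0.05
    out_dir: results/
    seed: 0
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anomaly import AnomalyParams
from .ingest import VIOLENT_CATEGORIES


class ConfigError(ValueError):
    """Raised for invalid study configuration."""


@dataclass
class SiteConfig:
    site_id: str
    weather_path: Path
    crime_path: Path


@dataclass
class StudyConfig:
    sites: "list[SiteConfig]"
    study_start: dt.date
    study_end: dt.date
    anomaly: AnomalyParams = field(default_factory=AnomalyParams)
    violent_categories: frozenset = VIOLENT_CATEGORIES
    alpha: float = 0.05
    out_dir: Path = Path("results")
    seed: int = 0
    allow_bad_rows: bool = False

    def validate_paths(self) -> None:
        for site in self.sites:
            for p in (site.weather_path, site.crime_path):
                if not Path(p).exists():
                    raise ConfigError(f"site {site.site_id!r}: input file not found: {p}")


def _as_date(value, key: str) -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigError(f"{key}: unparseable date {value!r}") from exc


def load_config(path: "str | Path") -> StudyConfig:
    """Parse and validate a YAML study configuration (paths not checked)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    base = Path(path).parent
    if not raw.get("sites"):
        raise ConfigError("config needs at least one entry under 'sites'")
    sites = []
    for entry in raw["sites"]:
        for key in ("id", "weather", "crime"):
            if key not in entry:
                raise ConfigError(f"site entry missing {key!r}: {entry}")
        sites.append(SiteConfig(entry["id"], base / entry["weather"], base / entry["crime"]))
    study = raw.get("study", {})
    if "start" not in study or "end" not in study:
        raise ConfigError("config needs study.start and study.end")
    start = _as_date(study["start"], "study.start")
    end = _as_date(study["end"], "study.end")
    if end < start:
        raise ConfigError("study.end precedes study.start")
    anom_kwargs = dict(raw.get("anomaly", {}))
    for key in ("summer_months", "winter_months"):
        if key in anom_kwargs:
            anom_kwargs[key] = frozenset(int(m) for m in anom_kwargs[key])
    try:
        anomaly = AnomalyParams(**anom_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid anomaly parameters: {exc}") from exc
    return StudyConfig(
        sites=sites,
        study_start=start,
        study_end=end,
        anomaly=anomaly,
        violent_categories=frozenset(
            c.casefold() for c in raw.get("violent_categories", VIOLENT_CATEGORIES)
        ),
        alpha=float(raw.get("alpha", 0.05)),
        out_dir=base / raw.get("out_dir", "results"),
        seed=int(raw.get("seed", 0)),
        allow_bad_rows=bool(raw.get("allow_bad_rows", False)),
    )


def echo_config(config: StudyConfig) -> str:
    """Render the effective configuration back as YAML for the run log."""
    return yaml.safe_dump(
        {
            "sites": [
                {"id": s.site_id, "weather": str(s.weather_path), "crime": str(s.crime_path)}
                for s in config.sites
            ],
            "study": {"start": str(config.study_start), "end": str(config.study_end)},
            "anomaly": {
                "window": config.anomaly.window,
                "threshold_sd": config.anomaly.threshold_sd,
                "exposure_sd": config.anomaly.exposure_sd,
                "summer_months": sorted(config.anomaly.summer_months),
                "winter_months": sorted(config.anomaly.winter_months),
                "temperature_column": config.anomaly.temperature_column,
            },
            "violent_categories": sorted(config.violent_categories),
            "alpha": config.alpha,
            "out_dir": str(config.out_dir),
            "seed": config.seed,
            "calendar_rule": "all dates in [start, end], February 29 excluded",
            "baseline_rule": "trailing window excluding the index day; sample SD",
        },
        sort_keys=False,
    )
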
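"""Writing run artifacts: panels, summary tables, comparisons, plots, log."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .ingest import write_panel
from .pipeline import StudyRun

logger = logging.getLogger(__name__)


def descriptive_stats(panels: "dict[str, pd.DataFrame]") -> pd.DataFrame:
    """Min/max/mean/SD of daily counts and weather variables per site."""
    rows = []
    variables = [
        ("crime_count", "crime_count"),
        ("apparent_temperature_mean", "apparent_temperature_mean"),
        ("temperature_mean", "temperature_mean"),
        ("precipitation_sum", "precipitation_sum"),
    ]
    for site, panel in panels.items():
        for name, col in variables:
            s = panel[col]
            rows.append(
                {"site": site, "variable": name, "min": s.min(), "max": s.max(),
                 "mean": s.mean(), "sd": s.std(ddof=1)}
            )
    return pd.DataFrame(rows)


def write_outputs(run: StudyRun, out_dir: "str | Path", config_echo: "str | None" = None,
                  plots: bool = False) -> "list[Path]":
    """Write all tabular artifacts of a run; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for site, panel in run.panels.items():
        path = out / f"panel_{site}.csv"
        write_panel(panel, path)
        written.append(path)
        path = out / f"anomaly_summary_{site}.csv"
        run.summaries[site].to_csv(path, index=False)
        written.append(path)
        path = out / f"relative_rate_profile_{site}.csv"
        run.profiles[site].to_csv(path)
        written.append(path)

    path = out / "descriptive_stats.csv"
    descriptive_stats(run.panels).to_csv(path, index=False)
    written.append(path)

    path = out / "comparisons_groups.csv"
    run.results.groups_frame().to_csv(path, index=False)
    written.append(path)
    path = out / "comparisons_tukey.csv"
    run.results.tukey_frame().to_csv(path, index=False)
    written.append(path)

    if config_echo is not None:
        path = out / "config_echo.yaml"
        path.write_text(config_echo)
        written.append(path)

    log_path = out / "run_log.txt"
    log_path.write_text(
        f"anomviol {__version__}\n"
        f"sites: {sorted(run.panels)}\n"
        f"panel lengths: { {s: len(p) for s, p in run.panels.items()} }\n"
        f"comparisons run: {len(run.results.comparisons)}\n"
        f"alpha: {run.results.alpha}\n"
    )
    written.append(log_path)

    if plots:
        written.extend(_write_plots(run, out))
    return written


def _write_plots(run: StudyRun, out: Path) -> "list[Path]":
    """Headless-safe quick-look figures (not part of the tested surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for site, prof in run.profiles.items():
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ok = prof["n_days"] > 0
        ax.bar(prof.index[ok], prof.loc[ok, "relative_rate"], color="#a84343")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("rolling temperature z-score bin (SD)")
        ax.set_ylabel("daily crime rate / baseline")
        ax.set_title(site)
        fig.tight_layout()
        path = out / f"relative_rate_{site}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
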
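"""Group-mean comparisons of daily violent-crime counts.

Daily counts are compared untransformed across day classes with classical
one-way fixed-effects ANOVA (F = MS_between / MS_within on k−1 and N−k
degrees of freedom) and the Tukey–Kramer all-pairs procedure, which adjusts
each pairwise comparison via the studentized-range distribution with the
within-group mean square pooled across all groups (valid for unequal group
sizes).  Counts are overdispersed, so the normal-theory p-values lean on the
central limit theorem at the group sizes a multi-year daily panel provides.

The relative-rate profile bins classified days by the integer part of the
rolling temperature z-score (clipped to ±3) and reports each bin's mean
daily count relative to the all-classified-days mean.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ComparisonError(ValueError):
    """Raised when a group comparison is not well-posed."""


@dataclass(frozen=True)
class GroupStats:
    label: str
    n_days: int
    mean: float
    sd: float


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float


@dataclass
class GroupComparison:
    """One grouping within one stratum: group summaries + ANOVA + Tukey."""

    site: str
    grouping: str
    stratum: str
    count_variable: str
    groups: "list[GroupStats]"
    anova_f: float
    anova_df: "tuple[int, int]"
    anova_p: float
    tukey: "list[PairwiseResult]"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.anova_p < alpha

    def pairwise_p(self, a: str, b: str) -> float:
        for pair in self.tukey:
            if {pair.group_a, pair.group_b} == {a, b}:
                return pair.p_adj
        raise KeyError(f"no Tukey pair ({a}, {b})")


def group_means(panel: pd.DataFrame, labels, count_col: str = "crime_count") -> pd.DataFrame:
    """n / mean / sample-SD of daily counts per group label.

    ``labels`` is a per-day label sequence aligned with the panel; days with
    a null label are excluded.
    """
    lab = pd.Series(np.asarray(labels, dtype=object), index=panel.index)
    counts = panel[count_col]
    keep = lab.notna()
    g = counts[keep].groupby(lab[keep])
    out = pd.DataFrame({"n_days": g.size(), "mean": g.mean(), "sd": g.std(ddof=1)})
    out.index.name = "group"
    return out


def _validate_groups(groups: "list[np.ndarray]") -> None:
    if len(groups) < 2:
        raise ComparisonError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ComparisonError("every group needs at least two observations")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ComparisonError("all observations identical; F is undefined")


def one_way_anova(groups: "list") -> "tuple[float, tuple[int, int], float]":
    """Classical one-way ANOVA: returns (F, (df_between, df_within), p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(arrays)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    f, p = stats.f_oneway(*arrays)
    return float(f), (k - 1, n_total - k), float(p)


def tukey_hsd(groups: "list", labels: "list[str] | None" = None) -> "list[PairwiseResult]":
    """Tukey–Kramer all-pairs comparison with studentized-range adjusted p."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    res = stats.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        out.append(
            PairwiseResult(
                group_a=labels[i],
                group_b=labels[j],
                mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                p_adj=float(np.clip(res.pvalue[i, j], 0.0, 1.0)),
            )
        )
    return out


def compare_groups(
    panel: pd.DataFrame,
    labels,
    site: str = "site",
    grouping: str = "grouping",
    stratum: str = "all",
    count_col: str = "crime_count",
    count_variable: str = "all",
) -> "GroupComparison | None":
    """Build a GroupComparison from per-day labels, or None if degenerate.

    Groups with fewer than two days are dropped (logged); if fewer than two
    groups survive, or all counts are identical, the comparison is skipped
    (logged) rather than fabricated.
    """
    stats_df = group_means(panel, labels, count_col)
    small = stats_df[stats_df["n_days"] < 2]
    if len(small):
        logger.warning("%s/%s/%s: dropping group(s) with < 2 days: %s",
                       site, grouping, stratum, list(small.index))
        stats_df = stats_df[stats_df["n_days"] >= 2]
    if len(stats_df) < 2:
        logger.warning("%s/%s/%s: fewer than two usable groups; comparison skipped",
                       site, grouping, stratum)
        return None
    lab = pd.Series(np.asarray(labels, dtype=object), index=panel.index)
    arrays = [
        panel.loc[lab == g, count_col].to_numpy(dtype=float) for g in stats_df.index
    ]
    try:
        f, df, p = one_way_anova(arrays)
        pairs = tukey_hsd(arrays, list(stats_df.index))
    except ComparisonError as exc:
        logger.warning("%s/%s/%s: %s; comparison skipped", site, grouping, stratum, exc)
        return None
    return GroupComparison(
        site=site,
        grouping=grouping,
        stratum=stratum,
        count_variable=count_variable,
        groups=[
            GroupStats(str(g), int(r.n_days), float(r["mean"]), float(r["sd"]))
            for g, r in stats_df.iterrows()
        ],
        anova_f=f,
        anova_df=df,
        anova_p=p,
        tukey=pairs,
    )


def relative_rate_profile(panel: pd.DataFrame, count_col: str = "crime_count") -> pd.DataFrame:
    """Mean daily counts by integer SD bin of the rolling temperature z-score.

    Bins are floor(z) clipped to [−3, +3] over classified days; the relative
    rate divides each bin mean by the all-classified-days mean.  Empty bins
    are reported with n = 0 and no rate.
    """
    classified = panel[panel["baseline_complete"] & panel["temp_z"].notna()]
    z = classified["temp_z"].to_numpy(dtype=float)
    bins = np.clip(np.floor(z), -3, 3).astype(int)
    counts = classified[count_col].to_numpy(dtype=float)
    overall = counts.mean()
    rows = []
    for b in range(-3, 4):
        sel = bins == b
        n = int(sel.sum())
        mean = counts[sel].mean() if n else np.nan
        rows.append(
            {
                "sd_bin": b,
                "n_days": n,
                "mean_count": mean,
                "relative_rate": mean / overall if n else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("sd_bin")
    out.attrs["overall_mean"] = overall
    return out


@dataclass
class StudyResults:
    """The full battery of comparisons for one or more sites."""

    comparisons: "list[GroupComparison]"
    alpha: float = 0.05

    def get(self, site: str, grouping: str, stratum: str = "all",
            count_variable: str = "all") -> GroupComparison:
        for c in self.comparisons:
            if (c.site, c.grouping, c.stratum, c.count_variable) == (site, grouping, stratum, count_variable):
                return c
        raise KeyError((site, grouping, stratum, count_variable))

    def groups_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            for g in c.groups:
                rows.append(
                    {
                        "site": c.site, "grouping": c.grouping, "stratum": c.stratum,
                        "count_variable": c.count_variable, "group": g.label,
                        "n_days": g.n_days, "mean": g.mean, "sd": g.sd,
                        "anova_F": c.anova_f, "anova_df_between": c.anova_df[0],
                        "anova_df_within": c.anova_df[1], "anova_p": c.anova_p,
                        "significant": c.significant(self.alpha),
                    }
                )
        return pd.DataFrame(rows)

    def tukey_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            for pair in c.tukey:
                rows.append(
                    {
                        "site": c.site, "grouping": c.grouping, "stratum": c.stratum,
                        "count_variable": c.count_variable,
                        "group_a": pair.group_a, "group_b": pair.group_b,
                        "mean_diff": pair.mean_diff, "p_adj": pair.p_adj,
                        "significant": pair.p_adj < self.alpha,
                    }
                )
        return pd.DataFrame(rows)


def _crossed_labels(panel: pd.DataFrame, anomaly_col: str) -> np.ndarray:
    base = panel[anomaly_col].to_numpy(dtype=object)
    wk = np.where(panel["weekend"].to_numpy(bool), "weekend", "weekday")
    out = np.array([f"{a}-{w}" for a, w in zip(base, wk)], dtype=object)
    out[base == "unclassified"] = None
    return out


def run_full_study(
    panels: "dict[str, pd.DataFrame]",
    alpha: float = 0.05,
) -> StudyResults:
    """Run the whole comparison battery on classified per-site panels.

    Per site and count variable (all incidents, then the disadvantaged
    substream): the 3-way temperature-anomaly comparison (all-year and
    restricted to summer / winter days), the 2-way rainfall-anomaly
    comparison, the low/medium/high exposure comparison, weekend vs weekday,
    and weekend-crossed anomaly comparisons with all pairwise Tukey
    contrasts.  Degenerate comparisons are skipped and logged.
    """
    comparisons: list[GroupComparison] = []

    def masked(panel: pd.DataFrame, labels: np.ndarray, mask) -> np.ndarray:
        out = labels.copy()
        out[~np.asarray(mask, bool)] = None
        return out

    for site, panel in panels.items():
        for count_col, variable in (
            ("crime_count", "all"),
            ("crime_count_disadvantaged", "disadvantaged"),
        ):
            if count_col not in panel.columns:
                continue
            temp = panel["temp_anomaly"].to_numpy(dtype=object).copy()
            temp[temp == "unclassified"] = None
            rain = panel["rain_anomaly"].to_numpy(dtype=object).copy()
            rain[rain == "unclassified"] = None
            season = panel["season"].to_numpy(dtype=object)
            jobs = [
                ("temp_anomaly", "all", temp),
                ("temp_anomaly", "summer", masked(panel, temp, season == "summer")),
                ("temp_anomaly", "winter", masked(panel, temp, season == "winter")),
                ("rain_anomaly", "all", rain),
                ("exposure", "all", panel["exposure"].to_numpy(dtype=object)),
                ("weekend", "all",
                 np.where(panel["weekend"].to_numpy(bool), "weekend", "weekday").astype(object)),
                ("weekend_x_temp_anomaly", "all", _crossed_labels(panel, "temp_anomaly")),
                ("weekend_x_rain_anomaly", "all", _crossed_labels(panel, "rain_anomaly")),
            ]
            for grouping, stratum, labels in jobs:
                comp = compare_groups(
                    panel, labels, site=site, grouping=grouping, stratum=stratum,
                    count_col=count_col, count_variable=variable,
                )
                if comp is not None:
                    comparisons.append(comp)
    return StudyResults(comparisons=comparisons, alpha=alpha)
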
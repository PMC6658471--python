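"""Within-study normalization of non-European polygenic-score performance.

Each curated comparison pairs the score's effect size in a non-European
ancestry sample with the matched European ancestry sample from the same
study. The non-European effect is expressed as a percentage of the European
one (100 = parity); odds ratios are compared on the log scale. Group-level
summaries are medians per ancestry group plus a one-sample t-test of the
percentages against parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polyport.io_formats import METRIC_TYPES

RATIO_METRICS = ("variance_explained", "beta", "auc")


class UndefinedBaselineError(ValueError):
    """European baseline effect is zero (or OR = 1), so the ratio is undefined."""


@dataclass(frozen=True)
class RelativePerformance:
    """One comparison's non-European performance as % of the European baseline."""

    study_id: str
    phenotype: str
    ancestry_group: str
    relative_pct: float
    metric_type: str


def relative_effect(
    effect_noneur: float,
    effect_eur: float,
    metric_type: str,
    study_id: str = "",
    phenotype: str = "",
    ancestry_group: str = "",
    auc_baseline_adjust: bool = False,
) -> RelativePerformance:
    """Normalize one non-European effect to its matched European baseline.

    variance_explained / beta / auc: ``100 * noneur / eur``. odds_ratio:
    ``100 * ln(OR_noneur) / ln(OR_eur)`` (ratios on the log-odds scale).
    ``auc_baseline_adjust`` optionally ratios AUC - 0.5 instead of raw AUC
    (raw-AUC ratios compress differences); off by default.
    """
    if metric_type not in METRIC_TYPES:
        raise ValueError(f"unknown metric_type {metric_type!r}")
    if not (math.isfinite(effect_noneur) and math.isfinite(effect_eur)):
        raise ValueError("effect sizes must be finite")
    if metric_type == "odds_ratio":
        if effect_noneur <= 0 or effect_eur <= 0:
            raise ValueError("odds ratios must be positive")
        if effect_eur == 1.0:
            raise UndefinedBaselineError("European OR = 1 gives log(OR) = 0 baseline")
        pct = 100.0 * math.log(effect_noneur) / math.log(effect_eur)
    else:
        if metric_type == "auc" and auc_baseline_adjust:
            effect_noneur = effect_noneur - 0.5
            effect_eur = effect_eur - 0.5
        if effect_eur == 0:
            raise UndefinedBaselineError("European effect size is zero")
        pct = 100.0 * effect_noneur / effect_eur
    return RelativePerformance(
        study_id=study_id,
        phenotype=phenotype,
        ancestry_group=ancestry_group,
        relative_pct=pct,
        metric_type=metric_type,
    )


def relative_effects(study_table: pd.DataFrame, auc_baseline_adjust: bool = False) -> pd.DataFrame:
    """Apply :func:`relative_effect` to every row of a study-comparison table."""
    rows = [
        relative_effect(
            row.effect_noneur,
            row.effect_eur,
            row.metric_type,
            study_id=str(row.study_id),
            phenotype=str(row.phenotype),
            ancestry_group=str(row.ancestry_group),
            auc_baseline_adjust=auc_baseline_adjust,
        )
        for row in study_table.itertuples(index=False)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def group_median(performance: pd.DataFrame, ancestry_group: str) -> float:
    """Sample median of relative percentages within one ancestry group."""
    vals = performance.loc[performance["ancestry_group"] == ancestry_group, "relative_pct"]
    if vals.empty:
        raise ValueError(f"no comparisons for ancestry group {ancestry_group!r}")
    return float(vals.median())


def group_ttest(
    performance: pd.DataFrame, ancestry_group: str, null_pct: float = 100.0
) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of a group's percentages against parity.

    Returns ``(t, df, p)`` with ``df = n - 1``.
    """
    vals = performance.loc[
        performance["ancestry_group"] == ancestry_group, "relative_pct"
    ].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 comparisons for a t-test")
    if np.ptp(vals) == 0:
        raise ValueError("zero dispersion: t-test undefined")
    res = stats.ttest_1samp(vals, null_pct)
    return float(res.statistic), len(vals) - 1, float(res.pvalue)


def group_summary(performance: pd.DataFrame, null_pct: float = 100.0) -> pd.DataFrame:
    """Tidy per-ancestry-group summary: n, median, t, df, p."""
    rows = []
    for group, sub in performance.groupby("ancestry_group", sort=True):
        n = len(sub)
        median = float(sub["relative_pct"].median())
        if n >= 2 and np.ptp(sub["relative_pct"].to_numpy()) > 0:
            t, dfree, p = group_ttest(performance, group, null_pct)
        else:
            t, dfree, p = np.nan, n - 1, np.nan
        rows.append({"ancestry_group": group, "n": n, "median_pct": median, "t": t, "df": dfree, "p": p})
    return pd.DataFrame(rows)


def representation_ratio(study_fraction: float, world_fraction: float) -> float:
    """Study representation of an ancestry group as % of its world share."""
    if world_fraction <= 0:
        raise ValueError("world_fraction must be positive")
    if study_fraction < 0:
        raise ValueError("study_fraction must be non-negative")
    return 100.0 * study_fraction / world_fraction


def forest_plot(performance: pd.DataFrame, path=None):
    """Forest-style plot of relative percentages by ancestry group.

    One point per comparison, vertical parity line at 100%, group medians as
    colored vertical lines. Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(performance["ancestry_group"].unique())
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(performance))))
    ordered = performance.sort_values(["ancestry_group", "relative_pct"]).reset_index(drop=True)
    for gi, group in enumerate(groups):
        sub = ordered[ordered["ancestry_group"] == group]
        ax.scatter(sub["relative_pct"], sub.index, s=18, color=cmap(gi), label=group)
        ax.axvline(sub["relative_pct"].median(), color=cmap(gi), lw=1, ls="--", alpha=0.7)
    ax.axvline(100.0, color="black", lw=1.2)
    ax.set_xlabel("relative performance (% of matched European sample)")
    ax.set_yticks(ordered.index)
    ax.set_yticklabels(ordered["study_id"], fontsize=6)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
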
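"""Population-level score summaries and score/phenotype correlation.

Summarizes polygenic scores per population across the methods grid, tracks a
between-population dispersion statistic (variance of population means over
pooled within-population variance), applies the standard population
exclusions, and correlates population mean scores with population mean
phenotypes (one point per population, populations weighted equally).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polyport.prs_engine import PRSMatrix

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("no_phenotype", "admixed_mixed_origin", "no_single_country")


@dataclass(frozen=True)
class ExclusionRule:
    """One population excluded from the phenotype-correlation analysis."""

    population: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


#: The seven standard exclusions for the height analysis: four populations
#: without phenotype data, two admixed/mixed-origin cohorts, and one cohort
#: without a single country of origin.
DEFAULT_EXCLUSIONS = (
    ExclusionRule("PUR", "no_phenotype"),
    ExclusionRule("BEB", "no_phenotype"),
    ExclusionRule("PJL", "no_phenotype"),
    ExclusionRule("MSL", "no_phenotype"),
    ExclusionRule("ASW", "admixed_mixed_origin"),
    ExclusionRule("ACB", "admixed_mixed_origin"),
    ExclusionRule("CEU", "no_single_country"),
)


@dataclass
class PopulationSummary:
    """Per-population score summaries plus per-cell dispersion.

    ``by_population``: one row per (population, clump_spec, p_T) with mean,
    sd (NaN and flagged when n = 1) and n. ``dispersion``: one row per grid
    cell with the ratio of the variance of population means to the pooled
    within-population variance.
    """

    by_population: pd.DataFrame
    dispersion: pd.DataFrame


def population_summaries(
    prs: PRSMatrix, panel: pd.DataFrame, standardize: bool = False
) -> PopulationSummary:
    """Summarize every PRS grid cell within each panel population.

    With ``standardize`` the scores are z-scored against the pooled cohort
    before summarizing. Dispersion per cell is Var(population means) /
    pooled within-population variance (0 when the within variance is 0 and
    the means agree).
    """
    panel_map = panel.set_index("sample")["population"]
    missing = [s for s in prs.samples if s not in panel_map.index]
    if missing:
        raise KeyError(f"scored samples missing from panel: {missing[:5]}")
    pops = panel_map.loc[prs.samples].to_numpy()

    rows, disp_rows = [], []
    for (label, p_t), col in prs.scores.items():
        y = col.to_numpy(dtype=float)
        if standardize:
            sd = y.std(ddof=0)
            y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        cell = pd.DataFrame({"population": pops, "score": y})
        agg = cell.groupby("population")["score"].agg(["mean", "std", "count"])
        for pop, r in agg.iterrows():
            rows.append(
                {
                    "population": pop,
                    "clump_spec": label,
                    "p_T": p_t,
                    "mean": r["mean"],
                    "sd": r["std"],
                    "n": int(r["count"]),
                    "sd_defined": r["count"] > 1,
                }
            )
        between = agg["mean"].to_numpy().var(ddof=0)
        dof = (agg["count"] - 1).to_numpy(dtype=float)
        if dof.sum() > 0:
            within = float(np.nansum((agg["std"].to_numpy() ** 2) * dof) / dof.sum())
        else:
            within = np.nan
        disp = between / within if within and within > 0 else (0.0 if between == 0 else np.inf)
        disp_rows.append({"clump_spec": label, "p_T": p_t, "dispersion": disp})

    by_population = pd.DataFrame(rows)
    dispersion = pd.DataFrame(disp_rows)
    for label, spec in prs.specs.items():
        sel = dispersion["clump_spec"] == label
        dispersion.loc[sel, "r2"] = spec.r2_threshold
        dispersion.loc[sel, "reference_pop"] = spec.reference_population
    return PopulationSummary(by_population=by_population, dispersion=dispersion)


def dispersion_trend(summary: PopulationSummary, axis: str) -> pd.DataFrame:
    """Dispersion ordered along one grid axis with the others held fixed.

    ``axis`` is one of ``p_T``, ``r2``, ``reference_pop``. Returns one row
    per (fixed-factor combination, axis level); each fixed-factor group gets
    a ``monotonic`` flag ('increasing', 'decreasing', 'mixed', or NaN when
    the axis has a single level).
    """
    if axis not in ("p_T", "r2", "reference_pop"):
        raise ValueError(f"axis must be one of p_T, r2, reference_pop, got {axis!r}")
    disp = summary.dispersion.copy()
    if axis != "p_T" and axis not in disp.columns:
        raise ValueError("grid specs lack r2/reference_pop metadata")
    fixed = [c for c in ("p_T", "r2", "reference_pop") if c in disp.columns and c != axis]
    out = []
    for keys, sub in disp.groupby(fixed, dropna=False):
        sub = sub.sort_values(axis, kind="mergesort")
        vals = sub["dispersion"].to_numpy()
        if len(vals) < 2:
            mono = np.nan
        else:
            diffs = np.diff(vals)
            if np.all(diffs >= 0):
                mono = "increasing"
            elif np.all(diffs <= 0):
                mono = "decreasing"
            else:
                mono = "mixed"
        sub = sub.copy()
        sub["monotonic"] = mono
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def apply_population_exclusions(
    panel: pd.DataFrame, rules=DEFAULT_EXCLUSIONS
) -> pd.DataFrame:
    """Remove all samples of the excluded populations from a panel.

    Raises on rule codes absent from the panel; logs the removed count per
    rule; warns if nothing remains. ``excluded + retained == input`` holds.
    """
    present = set(panel["population"])
    rules = list(rules)
    codes = [r.population for r in rules]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate population codes in exclusion rules")
    unknown = [c for c in codes if c not in present]
    if unknown:
        raise KeyError(f"exclusion rules name unknown populations: {unknown}")
    removed_log = {}
    for rule in rules:
        removed_log[rule.population] = int((panel["population"] == rule.population).sum())
    out = panel.loc[~panel["population"].isin(codes)].reset_index(drop=True)
    logger.info(
        "apply_population_exclusions: removed %d samples (%s), retained %d",
        sum(removed_log.values()), removed_log, len(out),
    )
    if out.empty:
        warnings.warn("all populations excluded: empty panel")
    out.attrs["exclusion_log"] = removed_log
    return out


def phenotype_correlation(
    population_means: pd.DataFrame, phenotype_table: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation of population mean PRS with population mean phenotype.

    ``population_means`` needs columns ``population`` and ``mean`` (one grid
    cell of :class:`PopulationSummary`). Populations are matched by code and
    weighted equally. Returns ``(r, p, n_populations)`` with the two-sided p
    from the t-distribution on n - 2 df.
    """
    joined = population_means.merge(phenotype_table, on="population", how="inner")
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 populations after join, got {n}")
    x = joined["mean"].to_numpy(dtype=float)
    y = joined["phenotype"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on one axis: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def grid_phenotype_correlations(
    summary: PopulationSummary, phenotype_table: pd.DataFrame
) -> pd.DataFrame:
    """phenotype_correlation for every grid cell; tidy output."""
    rows = []
    for (label, p_t), sub in summary.by_population.groupby(["clump_spec", "p_T"], sort=False):
        r, p, n = phenotype_correlation(sub[["population", "mean"]], phenotype_table)
        rows.append({"clump_spec": label, "p_T": p_t, "r": r, "p": p, "n_populations": n})
    return pd.DataFrame(rows)


def distribution_grid_plot(prs: PRSMatrix, panel: pd.DataFrame, path=None, thresholds=None):
    """Density grid of score distributions per population (rows = clump spec,
    columns = p_T), mirroring the published figure layout. Returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panel_map = panel.set_index("sample")["population"]
    pops = panel_map.loc[prs.samples].to_numpy()
    labels = list(dict.fromkeys(prs.scores.columns.get_level_values(0)))
    if thresholds is None:
        thresholds = list(dict.fromkeys(prs.scores.columns.get_level_values(1)))
    uniq_pops = sorted(set(pops))
    cmap = plt.get_cmap("tab10")
    fig, axes = plt.subplots(
        len(labels), len(thresholds),
        figsize=(3 * len(thresholds), 1.8 * len(labels)),
        squeeze=False,
    )
    for i, label in enumerate(labels):
        for j, p_t in enumerate(thresholds):
            ax = axes[i][j]
            col = prs.scores[(label, p_t)].to_numpy()
            for k, pop in enumerate(uniq_pops):
                vals = col[pops == pop]
                if np.ptp(vals) == 0:
                    ax.axvline(vals[0], color=cmap(k), lw=1)
                    continue
                density = stats.gaussian_kde(vals)
                xs = np.linspace(vals.min(), vals.max(), 100)
                ax.plot(xs, density(xs), color=cmap(k), lw=1, label=pop if (i == 0 and j == 0) else None)
            ax.set_yticks([])
            if i == 0:
                ax.set_title(f"p_T={p_t:g}", fontsize=8)
            if j == 0:
                ax.set_ylabel(label, fontsize=7)
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
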
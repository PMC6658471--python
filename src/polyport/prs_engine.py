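"""Clumping + thresholding (C+T) polygenic scoring.

Pipeline: harmonize summary-statistic alleles to the target panel, greedily
clump by LD against a chosen reference population, subset weights at each
p-value ceiling, and compute additive scores.

Determinism: ties on p in clumping break by ascending chromosome, position,
then variant_id; grid columns are emitted in spec order then threshold order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polyport.io_formats import GenotypeMatrix, join_keys_for

logger = logging.getLogger(__name__)

#: The 13 default p-value ceilings for score construction.
DEFAULT_THRESHOLDS = (
    5e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0,
)

#: Default r^2 ceilings varied in the scoring grid.
DEFAULT_R2_GRID = (0.2, 0.05, 0.01)

AMBIGUOUS_PAIRS = frozenset({frozenset(("A", "T")), frozenset(("C", "G"))})

HARMONIZE_ACTIONS = ("match", "sign_flip", "dropped_ambiguous", "dropped_mismatch", "dropped_absent")


class UndefinedLDError(ValueError):
    """LD is undefined (a variant is monomorphic over pairwise-complete samples)."""


@dataclass(frozen=True)
class ClumpSpec:
    """Parameters of one greedy LD-clumping pass."""

    window_kb: int = 500
    r2_threshold: float = 0.2
    p1: float = 1.0
    p2: float = 1.0
    reference_population: str = "ALL"

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if self.p2 < 0:
            raise ValueError("p2 must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.reference_population}_r2_{self.r2_threshold:g}"


def validate_thresholds(thresholds) -> tuple[float, ...]:
    """Check a threshold set: strictly increasing, all in (0, 1]."""
    t = tuple(float(x) for x in thresholds)
    if not t:
        raise ValueError("threshold set is empty")
    if any(not (0 < x <= 1) for x in t):
        raise ValueError("thresholds must lie in (0, 1]")
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return t


@dataclass
class HarmonizedWeights:
    """Summary-statistic weights aligned to the target panel's alt alleles.

    ``table`` holds the retained rows (one per matched target variant):
    ``variant_id`` (target id), ``col`` (column index into the target dosage
    matrix), ``weight`` (signed effect per alt-allele copy), ``p``, ``action``.
    ``audit`` records the action taken for every source row, including drops.
    """

    table: pd.DataFrame
    audit: pd.DataFrame

    @property
    def counts(self) -> dict:
        c = self.audit["action"].value_counts().to_dict()
        return {a: int(c.get(a, 0)) for a in HARMONIZE_ACTIONS}

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PRSMatrix:
    """Samples x (clump spec x p_T) score table with per-cell variant counts."""

    scores: pd.DataFrame   # index: samples; columns: MultiIndex (clump_spec, p_T)
    counts: pd.DataFrame   # same shape; contributing-variant count per cell
    specs: dict = field(default_factory=dict)  # label -> ClumpSpec

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.scores.stack([0, 1], future_stack=True)
            .rename("score")
            .reset_index()
        )
        long.columns = ["sample", "clump_spec", "p_T", "score"]
        counts = self.counts.stack([0, 1], future_stack=True).rename("n_variants").reset_index(drop=True)
        long["n_variants"] = counts.astype(int)
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame, specs: dict | None = None) -> "PRSMatrix":
        scores = long.pivot_table(
            index="sample", columns=["clump_spec", "p_T"], values="score", sort=False
        )
        counts = long.pivot_table(
            index="sample", columns=["clump_spec", "p_T"], values="n_variants", sort=False
        )
        return cls(scores=scores, counts=counts, specs=specs or {})


def harmonize(
    sumstats: pd.DataFrame, gm: GenotypeMatrix, drop_ambiguous: bool = True
) -> HarmonizedWeights:
    """Align summary-statistic effect alleles to the target panel.

    Per source row: if the effect allele is the target alt allele the weight
    is +beta (``match``); if it is the target ref allele the weight is -beta
    (``sign_flip``); strand-ambiguous A/T and C/G pairs are dropped when
    ``drop_ambiguous`` is set; allele pairs matching neither orientation are
    ``dropped_mismatch``; variants absent from the target are
    ``dropped_absent``. Every source row's outcome is recorded in the audit.
    """
    if len(sumstats) == 0 or gm.n_variants == 0:
        raise ValueError("harmonize requires non-empty summary statistics and genotypes")
    target = gm.variants.copy()
    target["col"] = np.arange(len(target))
    target["join_key"] = gm.join_keys()
    src = sumstats.copy()
    src["join_key"] = join_keys_for(src)

    merged = src.merge(
        target[["join_key", "col", "ref_allele", "alt_allele", "variant_id"]],
        on="join_key", how="left", suffixes=("", "_target"),
    )
    eff = merged["effect_allele"].to_numpy()
    oth = merged["other_allele"].to_numpy()
    ref = merged["ref_allele"].to_numpy(dtype=object)
    alt = merged["alt_allele"].to_numpy(dtype=object)

    absent = merged["col"].isna().to_numpy()
    ambiguous = np.array(
        [frozenset((e, o)) in AMBIGUOUS_PAIRS for e, o in zip(eff, oth)]
    )
    is_match = (eff == alt) & (oth == ref)
    is_flip = (eff == ref) & (oth == alt)

    action = np.full(len(merged), "dropped_mismatch", dtype=object)
    action[is_match] = "match"
    action[is_flip] = "sign_flip"
    if drop_ambiguous:
        action[ambiguous & ~absent] = "dropped_ambiguous"
    action[absent] = "dropped_absent"

    weight = np.where(action == "match", merged["beta"], np.where(action == "sign_flip", -merged["beta"], np.nan))
    audit = pd.DataFrame(
        {
            "source_variant_id": merged["variant_id"],
            "target_variant_id": merged["variant_id_target"],
            "action": action,
            "weight": weight,
            "p": merged["p"],
        }
    )
    kept = np.isin(action, ("match", "sign_flip"))
    table = pd.DataFrame(
        {
            "variant_id": merged.loc[kept, "variant_id_target"].to_numpy(),
            "col": merged.loc[kept, "col"].to_numpy(dtype=int),
            "weight": weight[kept].astype(float),
            "p": merged.loc[kept, "p"].to_numpy(dtype=float),
            "action": action[kept],
        }
    )
    if table["col"].duplicated().any():
        raise ValueError("multiple summary-statistic rows map to one target variant")
    hw = HarmonizedWeights(table=table.reset_index(drop=True), audit=audit)
    logger.info("harmonize: %s", hw.counts)
    return hw


def ld_r2(gm: GenotypeMatrix, variant_i: int, variant_j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    gi = gm.dosages[:, variant_i]
    gj = gm.dosages[:, variant_j]
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    if ok.sum() < 2:
        raise ValueError("need >= 2 samples with non-missing dosage at both variants")
    gi, gj = gi[ok], gj[ok]
    vi, vj = gi.var(), gj.var()
    if vi == 0 or vj == 0:
        raise UndefinedLDError("variant monomorphic over pairwise-complete samples")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(min(r * r, 1.0))


def _complete_dosages(gm: GenotypeMatrix) -> np.ndarray:
    dos = gm.dosages
    if np.isnan(dos).any():
        dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    return dos


def clump(
    sumstats: pd.DataFrame,
    reference: GenotypeMatrix,
    spec: ClumpSpec,
    keep_unmatched: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Greedy LD clumping of summary statistics against a reference panel.

    Repeatedly promotes the unassigned variant with the smallest p (ties:
    chromosome, position, variant_id) with p <= p1 to clump index, and
    assigns to it every unassigned variant with p <= p2 within
    ``window_kb`` kb on the same chromosome whose dosage r^2 with the index
    is >= ``r2_threshold``. Variants absent from the reference are dropped
    (kept as singleton indices only if ``keep_unmatched``).

    Returns the index-variant rows of ``sumstats`` (original order) and an
    assignment map index variant_id -> list of clumped member variant_ids.
    """
    ref_keys = pd.Index(reference.join_keys())
    ss = sumstats.reset_index(drop=True)
    ss_keys = join_keys_for(ss)
    ref_col = ss_keys.map(pd.Series(np.arange(len(ref_keys)), index=ref_keys))
    matched = ref_col.notna().to_numpy()
    n_dropped = int((~matched).sum())
    if n_dropped:
        logger.info("clump: %d summary-statistic variants absent from LD reference", n_dropped)

    work = ss.loc[matched].copy()
    work["ref_col"] = ref_col[matched].astype(int).to_numpy()
    if work.empty and not keep_unmatched:
        raise ValueError("no summary-statistic variants present in the LD reference")

    eligible = work["p"] <= spec.p1
    if not eligible.any() and not keep_unmatched:
        raise ValueError(f"no variants with p <= p1 ({spec.p1}) after matching to reference")

    dos = _complete_dosages(reference)
    centered = dos - dos.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", centered, centered))

    order = work.sort_values(
        ["p", "chromosome", "position", "variant_id"], kind="mergesort"
    ).index.to_numpy()
    assigned = pd.Series(False, index=work.index)
    window_bp = spec.window_kb * 1000
    assignment: dict[str, list[str]] = {}
    index_rows = []

    pos = work["position"].to_numpy()
    chrom = work["chromosome"].to_numpy()
    pvals = work["p"].to_numpy()
    ids = work["variant_id"].to_numpy()
    cols = work["ref_col"].to_numpy()
    loc = {ix: k for k, ix in enumerate(work.index)}

    for ix in order:
        k = loc[ix]
        if assigned.iloc[k] or pvals[k] > spec.p1:
            continue
        assigned.iloc[k] = True
        index_rows.append(ix)
        members: list[str] = []
        cand = np.flatnonzero(
            (~assigned.to_numpy())
            & (chrom == chrom[k])
            & (np.abs(pos - pos[k]) <= window_bp)
            & (pvals <= spec.p2)
        )
        if cand.size:
            ck = cols[k]
            if norms[ck] > 0:
                ccols = cols[cand]
                num = centered[:, ck] @ centered[:, ccols]
                denom = norms[ck] * norms[ccols]
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2 = np.where(denom > 0, (num / np.where(denom == 0, 1, denom)) ** 2, 0.0)
                hits = cand[r2 >= spec.r2_threshold]
                for h in hits:
                    assigned.iloc[h] = True
                    members.append(ids[h])
        assignment[ids[k]] = members

    clumped = ss.loc[sorted(index_rows)].drop(columns=[], errors="ignore").reset_index(drop=True)
    if keep_unmatched and n_dropped:
        singletons = ss.loc[~matched]
        clumped = pd.concat([clumped, singletons], ignore_index=True)
        for vid in singletons["variant_id"]:
            assignment[vid] = []
    clumped.attrs["n_dropped_absent_from_reference"] = n_dropped
    return clumped, assignment


def threshold(weights: HarmonizedWeights, p_t: float) -> HarmonizedWeights:
    """Subset weights at a p-value ceiling: strict ``p < p_T``, except
    ``p_T = 1`` which keeps everything (p <= 1)."""
    if not 0 < p_t <= 1:
        raise ValueError("p_T must be in (0, 1]")
    if p_t == 1.0:
        mask = weights.table["p"] <= 1.0
    else:
        mask = weights.table["p"] < p_t
    return HarmonizedWeights(table=weights.table.loc[mask].reset_index(drop=True), audit=weights.audit)


def score(
    gm: GenotypeMatrix,
    weights: HarmonizedWeights,
    mode: str = "sum",
    missing_policy: str = "mean",
) -> np.ndarray:
    """Additive polygenic score per sample.

    ``sum`` mode: sum over weighted variants of weight x dosage, with missing
    dosages replaced per ``missing_policy`` ('mean' = cohort mean dosage at
    the variant, 'zero'). ``average`` mode divides by 2 x (number of weighted
    variants).
    """
    if mode not in ("sum", "average"):
        raise ValueError(f"mode must be 'sum' or 'average', got {mode!r}")
    if missing_policy not in ("mean", "zero"):
        raise ValueError(f"missing_policy must be 'mean' or 'zero', got {missing_policy!r}")
    if len(weights.table) == 0:
        raise ValueError("weight set is empty")
    cols = weights.table["col"].to_numpy(dtype=int)
    w = weights.table["weight"].to_numpy(dtype=float)
    dos = gm.dosages[:, cols]
    if np.isnan(dos).any():
        if missing_policy == "mean":
            fill = np.nanmean(dos, axis=0)
            fill = np.where(np.isnan(fill), 0.0, fill)
        else:
            fill = np.zeros(dos.shape[1])
        dos = np.where(np.isnan(dos), fill, dos)
    s = dos @ w
    if mode == "average":
        s = s / (2 * len(w))
    return s


def score_grid(
    target: GenotypeMatrix,
    sumstats: pd.DataFrame,
    reference: GenotypeMatrix,
    reference_panel: pd.DataFrame,
    specs,
    thresholds=DEFAULT_THRESHOLDS,
    mode: str = "sum",
    drop_ambiguous: bool = True,
) -> PRSMatrix:
    """Full C+T factorial grid: every ClumpSpec x every p_T.

    For each spec the LD reference is the subset of ``reference`` samples
    whose population or superpopulation matches ``spec.reference_population``
    (``ALL`` keeps everyone); the clumped summary statistics are harmonized
    to the target panel and scored at every threshold.
    """
    thresholds = validate_thresholds(thresholds)
    score_cols: dict[tuple, np.ndarray] = {}
    count_cols: dict[tuple, int] = {}
    spec_map = {}
    for spec in specs:
        pop = spec.reference_population
        if pop == "ALL":
            ref = reference
        else:
            mask = (reference_panel["population"] == pop) | (
                reference_panel["superpopulation"] == pop
            )
            ids = reference_panel.loc[mask, "sample"].tolist()
            if not ids:
                raise KeyError(f"reference population {pop!r} not present in panel")
            ref = reference.subset_samples(ids)
        clumped, _ = clump(sumstats, ref, spec)
        weights = harmonize(clumped, target, drop_ambiguous=drop_ambiguous)
        spec_map[spec.label] = spec
        for p_t in thresholds:
            sub = threshold(weights, p_t)
            key = (spec.label, p_t)
            if len(sub.table) == 0:
                score_cols[key] = np.zeros(target.n_samples)
                count_cols[key] = 0
            else:
                score_cols[key] = score(target, sub, mode=mode)
                count_cols[key] = len(sub.table)
    columns = pd.MultiIndex.from_tuples(score_cols.keys(), names=["clump_spec", "p_T"])
    scores = pd.DataFrame(
        np.column_stack(list(score_cols.values())), index=pd.Index(target.samples, name="sample"),
        columns=columns,
    )
    counts = pd.DataFrame(
        np.tile(np.array(list(count_cols.values()), dtype=int), (target.n_samples, 1)),
        index=scores.index, columns=columns,
    )
    return PRSMatrix(scores=scores, counts=counts, specs=spec_map)


def default_grid_specs(
    reference_populations=("ALL", "EUR", "AFR", "AMR", "EAS", "SAS"),
    r2_grid=DEFAULT_R2_GRID,
    window_kb: int = 500,
) -> list[ClumpSpec]:
    """The published methods grid: r^2 ceilings x LD reference populations."""
    return [
        ClumpSpec(window_kb=window_kb, r2_threshold=r2, reference_population=pop)
        for pop in reference_populations
        for r2 in r2_grid
    ]
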
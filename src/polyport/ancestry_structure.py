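"""Population-structure tooling: long-range-LD masks, LD pruning, genotype
PCA, and the PRS-vs-principal-component correlation scan."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polyport.io_formats import GenotypeMatrix
from polyport.prs_engine import PRSMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """Closed genomic interval, 1-based inclusive on both ends."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


#: Long-range LD regions conventionally excluded before genotype PCA:
#: the MHC on chromosome 6 (25-35 Mb) and the chromosome 8 inversion (7-13 Mb).
DEFAULT_LONG_RANGE_LD = (
    Region("6", 25_000_000, 35_000_000),
    Region("8", 7_000_000, 13_000_000),
)


@dataclass
class PCResult:
    """PCA of a genotype matrix.

    ``coords``: samples x components DataFrame (columns PC1..PCk);
    ``explained_variance_ratio``: share of total variance per component,
    non-increasing; ``loadings``: variants x components array.
    """

    coords: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def exclude_regions(gm: GenotypeMatrix, mask=DEFAULT_LONG_RANGE_LD) -> GenotypeMatrix:
    """Drop variants falling inside any masked closed interval (inclusive ends)."""
    chrom = gm.variants["chromosome"].astype(str)
    pos = gm.variants["position"]
    inside = np.zeros(gm.n_variants, dtype=bool)
    for region in mask:
        inside |= ((chrom == str(region.chromosome)) & (pos >= region.start) & (pos <= region.end)).to_numpy()
    removed = int(inside.sum())
    out = gm.subset_variants(~inside)
    out.filter_log = dict(gm.filter_log, region_masked=removed)
    logger.info("exclude_regions: removed %d of %d variants", removed, gm.n_variants)
    return out


def ld_prune(
    gm: GenotypeMatrix, window_variants: int = 50, step: int = 5, r2_max: float = 0.2
) -> GenotypeMatrix:
    """Sliding-window greedy LD pruning.

    Within each window (per chromosome, in position order), while any pair of
    surviving variants has r^2 > ``r2_max``, the member of the worst pair
    with the lower MAF is removed (tie: the later position goes); the window
    then advances by ``step`` variants. The result is a fixed point: pruning
    the output again removes nothing.
    """
    if not window_variants > step >= 1:
        raise ValueError("require window_variants > step >= 1")
    dos = gm.dosages
    if np.isnan(dos).any():
        dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    maf = gm.maf()
    keep = np.ones(gm.n_variants, dtype=bool)

    order = gm.variants.sort_values(["chromosome", "position"], kind="mergesort").index.to_numpy()
    by_chrom = gm.variants["chromosome"].astype(str)

    def _pass() -> bool:
        removed_any = False
        for chrom in by_chrom.unique():
            idx = [j for j in order[by_chrom[order].to_numpy() == chrom] if keep[j]]
            start = 0
            while start < len(idx):
                window = [j for j in idx[start : start + window_variants] if keep[j]]
                changed = True
                while changed and len(window) > 1:
                    changed = False
                    sub = dos[:, window]
                    with np.errstate(invalid="ignore"):
                        corr = np.corrcoef(sub, rowvar=False)
                    corr = np.nan_to_num(corr, nan=0.0)
                    r2 = corr**2
                    np.fill_diagonal(r2, 0.0)
                    worst = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[worst] > r2_max:
                        a, b = window[worst[0]], window[worst[1]]
                        if maf[a] < maf[b]:
                            victim = a
                        elif maf[b] < maf[a]:
                            victim = b
                        else:  # tie: remove the later position
                            victim = a if gm.variants.loc[a, "position"] > gm.variants.loc[b, "position"] else b
                        keep[victim] = False
                        window.remove(victim)
                        changed = True
                        removed_any = True
                if start + window_variants >= len(idx):
                    break
                start += step
        return removed_any

    # iterate passes (windows shift after removals) until a fixed point
    while _pass():
        pass
    out = gm.subset_variants(keep)
    out.filter_log = dict(gm.filter_log, ld_pruned=int((~keep).sum()))
    logger.info("ld_prune: kept %d of %d variants", int(keep.sum()), gm.n_variants)
    return out


def pca(gm: GenotypeMatrix, n_components: int = 20, scaling: str = "patterson") -> PCResult:
    """Principal components of the genotype matrix.

    Variants are centered by twice the cohort alt-allele frequency and, under
    ``patterson`` scaling, divided by sqrt(2 f (1-f)) (binomial standard
    deviation); ``unit`` scaling divides by the empirical standard deviation
    instead. Missing dosages are mean-imputed before decomposition.
    Monomorphic variants are dropped. Each component is oriented so that its
    largest-magnitude sample coordinate is positive.
    """
    if scaling not in ("patterson", "unit"):
        raise ValueError(f"scaling must be 'patterson' or 'unit', got {scaling!r}")
    if gm.n_samples < n_components:
        raise ValueError(f"need >= {n_components} samples, got {gm.n_samples}")
    dos = gm.dosages
    if np.isnan(dos).any():
        dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    f = dos.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if int(poly.sum()) < n_components:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic variants for {n_components} components"
        )
    dos = dos[:, poly]
    f = f[poly]
    if scaling == "patterson":
        scale = np.sqrt(2 * f * (1 - f))
    else:
        scale = dos.std(axis=0)
    x = (dos - 2 * f) / scale

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = n_components
    coords = u[:, :k] * s[:k]
    # deterministic orientation: largest-|coordinate| sample positive
    for c in range(k):
        j = np.argmax(np.abs(coords[:, c]))
        if coords[j, c] < 0:
            coords[:, c] = -coords[:, c]
            vt[c, :] = -vt[c, :]
    explained = (s**2) / np.sum(s**2)
    return PCResult(
        coords=pd.DataFrame(
            coords, index=pd.Index(gm.samples, name="sample"),
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        explained_variance_ratio=explained[:k],
        loadings=vt[:k, :].T,
    )


def prs_pc_scan(prs: PRSMatrix, pcs: PCResult, adjust: str = "none") -> pd.DataFrame:
    """Pearson correlation of every PRS grid column with every PC.

    Returns a tidy table (clump_spec, p_T, component, r, p, p_adj, defined).
    Constant score columns are flagged ``defined=False`` and excluded from
    the optional Benjamini-Hochberg adjustment, which spans every defined
    cell of the scan.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    if list(prs.scores.index) != list(pcs.coords.index):
        raise ValueError("PRS matrix and PC result must cover the same samples in the same order")
    n = len(prs.scores)
    rows = []
    pc_mat = pcs.coords.to_numpy()
    pc_c = pc_mat - pc_mat.mean(axis=0)
    pc_norm = np.sqrt(np.einsum("ij,ij->j", pc_c, pc_c))
    for (label, p_t), col in prs.scores.items():
        y = col.to_numpy(dtype=float)
        yc = y - y.mean()
        ynorm = np.sqrt(yc @ yc)
        if ynorm == 0:
            for c in range(pcs.n_components):
                rows.append((label, p_t, c + 1, np.nan, np.nan, False))
            continue
        r = (yc @ pc_c) / (ynorm * pc_norm)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
        pvals = 2 * stats.t.sf(np.abs(tstat), n - 2)
        for c in range(pcs.n_components):
            rows.append((label, p_t, c + 1, float(r[c]), float(pvals[c]), True))
    out = pd.DataFrame(rows, columns=["clump_spec", "p_T", "component", "r", "p", "defined"])
    out["p_adj"] = np.nan
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = out["defined"].to_numpy()
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
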
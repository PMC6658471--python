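"""Synthetic multi-population cohorts for end-to-end pipeline testing.

Generates genotypes under Balding-Nichols drift with Gaussian-copula LD
blocks, additive quantitative phenotypes at a target heritability, a
marginal-OLS discovery GWAS, optional uncorrected-stratification bias in
the summary statistics, and study-comparison / phenotype-table fixtures.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly;
no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from polyport.io_formats import GenotypeMatrix, METRIC_TYPES

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "sample_ancestral_freqs",
    "balding_nichols_freqs",
    "simulate_genotypes",
    "simulate_phenotype",
    "run_gwas",
    "inject_stratification",
    "simulate_study_table",
    "simulate_phenotype_table",
    "make_reference_panel_fixture",
]


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic multi-population cohort."""

    n_pops: int = 3
    n_per_pop: int = 100
    n_variants: int = 500
    fst: tuple[float, ...] = (0.01, 0.05, 0.15)
    block_size: int = 10
    within_block_r: float = 0.5
    n_causal: int = 50
    h2: float = 0.5
    strat_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if np.isscalar(self.fst):
            self.fst = (float(self.fst),) * self.n_pops
        if len(self.fst) != self.n_pops:
            raise ValueError("fst must have one value per population")
        if not all(0 <= f < 1 for f in self.fst):
            raise ValueError("each FST must be in [0, 1)")
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must be in [0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal must be <= n_variants")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    beta_true: np.ndarray          # per-variant true effect; 0 off the causal set
    causal: np.ndarray             # boolean causal indicator
    pop_freqs: pd.DataFrame | None = None  # populations x variants true frequencies
    heritability: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.beta_true[~self.causal] != 0):
            raise ValueError("non-causal variants must have beta_true == 0")


def sample_ancestral_freqs(n_variants: int, seed) -> np.ndarray:
    """Ancestral allele frequencies, i.i.d. Uniform[0.05, 0.95]."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.05, 0.95, size=n_variants)


def balding_nichols_freqs(ancestral_freqs, fst_per_pop, seed) -> pd.DataFrame:
    """Per-population frequencies under the Balding-Nichols drift model.

    For drift parameter F > 0 the population frequency at a variant with
    ancestral frequency p is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F), whose
    mean is p and variance F p (1-p). F = 0 copies the ancestral frequency
    exactly.

    Returns a DataFrame with one row per population (``POP1``, ``POP2``, ...)
    and one column per variant.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    fst_per_pop = np.atleast_1d(np.asarray(fst_per_pop, dtype=float))
    if np.any(fst_per_pop >= 1) or np.any(fst_per_pop < 0):
        raise ValueError("each FST must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fst_per_pop:
        if f == 0:
            rows.append(p.copy())
        else:
            c = (1 - f) / f
            rows.append(rng.beta(p * c, (1 - p) * c))
    return pd.DataFrame(
        np.vstack(rows), index=[f"POP{i + 1}" for i in range(len(fst_per_pop))]
    )


def _block_haplotypes(rng, n_hap: int, freqs: np.ndarray, r: float) -> np.ndarray:
    """Haplotype alleles for one LD block via a Gaussian copula.

    Latent vector per haplotype is multivariate normal with exchangeable
    correlation ``r`` (one shared factor per haplotype), thresholded at the
    per-variant normal quantile of the allele frequency.
    """
    m = len(freqs)
    shared = rng.standard_normal((n_hap, 1))
    indep = rng.standard_normal((n_hap, m))
    z = np.sqrt(r) * shared + np.sqrt(1 - r) * indep
    thresh = stats.norm.ppf(freqs)  # P(z < thresh) = f
    return (z < thresh).astype(np.int8)


def simulate_genotypes(
    pop_freqs: pd.DataFrame,
    n_per_pop: int,
    block_size: int,
    within_block_r: float,
    seed,
    chromosome: str = "1",
    block_gap_bp: int = 1_000_000,
    within_block_spacing_bp: int = 1_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate diploid dosages for every population in ``pop_freqs``.

    LD blocks of ``block_size`` consecutive variants share an exchangeable
    latent correlation ``within_block_r``; blocks are independent. Two
    haplotypes are summed into a 0/1/2 dosage. Blocks are laid out on one
    chromosome with ``block_gap_bp`` between block starts so that default
    clumping windows never span blocks.

    Returns the genotype matrix (samples ordered population by population)
    and a matching sample panel (superpopulation = population).
    """
    if not 0 <= within_block_r < 1:
        raise ValueError("within_block_r must be in [0, 1)")
    if block_size < 1 or n_per_pop < 1:
        raise ValueError("block_size and n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    pops = list(pop_freqs.index)
    n_variants = pop_freqs.shape[1]
    n_blocks = int(np.ceil(n_variants / block_size))

    dosage_pops = []
    for pop in pops:
        freqs = pop_freqs.loc[pop].to_numpy(dtype=float)
        cols = []
        for b in range(n_blocks):
            sl = slice(b * block_size, min((b + 1) * block_size, n_variants))
            h1 = _block_haplotypes(rng, n_per_pop, freqs[sl], within_block_r)
            h2 = _block_haplotypes(rng, n_per_pop, freqs[sl], within_block_r)
            cols.append(h1 + h2)
        dosage_pops.append(np.hstack(cols).astype(float))
    dosages = np.vstack(dosage_pops)

    samples = [f"{pop}_{i:04d}" for pop in pops for i in range(n_per_pop)]
    positions = [
        (j // block_size) * block_gap_bp + (j % block_size) * within_block_spacing_bp + 1
        for j in range(n_variants)
    ]
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j + 1:06d}" for j in range(n_variants)],
            "chromosome": chromosome,
            "position": positions,
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    panel = pd.DataFrame(
        {
            "sample": samples,
            "population": [s.rsplit("_", 1)[0] for s in samples],
            "superpopulation": [s.rsplit("_", 1)[0] for s in samples],
        }
    )
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
    return gm, panel


def simulate_phenotype(
    gm: GenotypeMatrix, n_causal: int, h2: float, seed
) -> tuple[np.ndarray, TruthRecord]:
    """Additive quantitative phenotype at exact in-sample heritability ``h2``.

    Causal variants are chosen uniformly, true effects are i.i.d. standard
    normal, and the environmental noise is rescaled so that
    Var(G)/Var(y) == h2 holds exactly in-sample.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    if n_causal > gm.n_variants:
        raise ValueError("n_causal must be <= n_variants")
    rng = np.random.default_rng(seed)
    causal_idx = rng.choice(gm.n_variants, size=n_causal, replace=False)
    causal = np.zeros(gm.n_variants, dtype=bool)
    causal[causal_idx] = True
    beta = np.zeros(gm.n_variants)
    beta[causal] = rng.standard_normal(n_causal)

    dos = gm.dosages
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean, dos)
    g = dos @ beta
    var_g = g.var()
    if h2 == 0:
        y = rng.standard_normal(gm.n_samples)
    else:
        if var_g == 0:
            raise ValueError("genetic variance is zero but h2 > 0 requested")
        if h2 == 1:
            y = g.copy()
        else:
            e = rng.standard_normal(gm.n_samples)
            e = e - e.mean()
            # project out G so the in-sample ratio is exact
            e = e - (e @ (g - g.mean())) / ((g - g.mean()) @ (g - g.mean())) * (g - g.mean())
            e *= np.sqrt(var_g * (1 - h2) / h2 / e.var())
            y = g + e
    truth = TruthRecord(beta_true=beta, causal=causal, heritability=h2)
    return y, truth


def run_gwas(gm: GenotypeMatrix, phenotype, discovery_samples=None) -> pd.DataFrame:
    """Marginal discovery GWAS: per-variant OLS of phenotype on dosage.

    Returns canonical summary statistics (effect allele = alt allele).
    Monomorphic variants get beta = 0, se = NaN, p = 1. No covariates are
    fitted; stratification bias, when wanted, is injected downstream.
    """
    y = np.asarray(phenotype, dtype=float)
    if discovery_samples is not None:
        wanted = set(discovery_samples)
        idx = np.array([i for i, s in enumerate(gm.samples) if s in wanted])
        dos = gm.dosages[idx]
        y = y[idx]
    else:
        dos = gm.dosages
    n = dos.shape[0]
    if n < 30:
        raise ValueError(f"need >= 30 discovery samples, got {n}")
    if len(y) != n:
        raise ValueError("phenotype length does not match sample count")
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean, dos)

    gc = dos - dos.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = yc @ gc
    syy = yc @ yc
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = np.where(mono, 0.0, sxy / sxx_safe)
    sse = np.maximum(syy - beta * sxy, 0.0)
    dfree = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dfree / sxx_safe)
        tstat = np.where(se > 0, beta / np.where(se == 0, 1.0, se), np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(tstat), dfree)
    p = np.where(mono, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    se = np.where(mono, np.nan, se)
    beta = np.where(mono, 0.0, beta)

    out = gm.variants[["variant_id", "chromosome", "position"]].copy()
    out["effect_allele"] = gm.variants["alt_allele"]
    out["other_allele"] = gm.variants["ref_allele"]
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    return out


def inject_stratification(
    sumstats: pd.DataFrame, pop_freqs: pd.DataFrame, delta: float,
    pop_a: str, pop_b: str,
) -> pd.DataFrame:
    """Add uncorrected-stratification bias to discovery effect estimates.

    ``beta' = beta + delta * (f_popA - f_popB)`` per variant (frequencies
    indexed by position within ``pop_freqs`` columns, matched on variant
    order). All other fields are unchanged.
    """
    for pop in (pop_a, pop_b):
        if pop not in pop_freqs.index:
            raise KeyError(f"unknown population code {pop!r}")
    if pop_freqs.shape[1] != len(sumstats):
        raise ValueError("frequency table does not cover all summary-statistic variants")
    out = sumstats.copy()
    diff = pop_freqs.loc[pop_a].to_numpy() - pop_freqs.loc[pop_b].to_numpy()
    out["beta"] = out["beta"].to_numpy() + delta * diff
    return out


def simulate_study_table(
    n_per_group, true_ratio_per_group: dict, noise_sd: float, seed
) -> pd.DataFrame:
    """Fixture generator for the effect-size meta-analysis.

    For each ancestry group, draws ``n_per_group`` matched comparisons where
    the non-European effect equals the European effect times
    ``true_ratio + Normal(0, noise_sd)``. Metric types rotate round-robin
    over the four kinds; odds-ratio rows apply the ratio on the log-OR scale
    so that at ``noise_sd = 0`` every row's relative effect equals the
    configured ratio exactly.
    """
    if any(r <= 0 for r in true_ratio_per_group.values()):
        raise ValueError("true ratios must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for group, ratio in true_ratio_per_group.items():
        for i in range(n_per_group):
            metric = METRIC_TYPES[k % len(METRIC_TYPES)]
            k += 1
            ratio_i = ratio + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            if metric == "odds_ratio":
                log_or_eur = rng.uniform(0.2, 1.0)
                eur = float(np.exp(log_or_eur))
                noneur = float(np.exp(log_or_eur * ratio_i))
            elif metric == "auc":
                eur = rng.uniform(0.55, 0.75)
                noneur = eur * ratio_i
            else:
                eur = rng.uniform(0.01, 0.2)
                noneur = eur * ratio_i
            rows.append(
                {
                    "study_id": f"study_{group}_{i + 1}",
                    "phenotype": f"trait{(i % 5) + 1}",
                    "ancestry_group": group,
                    "metric_type": metric,
                    "effect_eur": eur,
                    "effect_noneur": noneur,
                    "significant_noneur": bool(rng.random() < 0.5),
                }
            )
    columns = [
        "study_id", "phenotype", "ancestry_group", "metric_type",
        "effect_eur", "effect_noneur", "significant_noneur",
    ]
    return pd.DataFrame(rows, columns=columns)


def simulate_phenotype_table(
    gm: GenotypeMatrix, panel: pd.DataFrame, truth: TruthRecord, seed,
    noise_sd: float = 0.0, offset: float = 170.0, scale: float = 1.0,
) -> pd.DataFrame:
    """Population phenotype table proportional to true per-population genetic means.

    Mirrors a country-level mean-phenotype lookup: one row per population,
    value = offset + scale * (population mean of the true genetic score)
    + optional noise.
    """
    rng = np.random.default_rng(seed)
    dos = gm.dosages
    if np.isnan(dos).any():
        dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    g = dos @ truth.beta_true
    by_pop = (
        pd.DataFrame({"population": panel.set_index("sample").loc[gm.samples, "population"].to_numpy(), "g": g})
        .groupby("population")["g"]
        .mean()
    )
    values = offset + scale * by_pop.to_numpy()
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=len(values))
    return pd.DataFrame({"population": by_pop.index, "phenotype": values})


# 1000Genomes-phase-3-like panel layout: 26 populations in 5 superpopulations.
# The seven populations excluded in the height analysis carry their published
# cohort sizes; remaining sizes are synthetic, chosen to total 2577 samples.
_PANEL_LAYOUT = [
    # (population, superpopulation, n)
    ("CHB", "EAS", 106), ("JPT", "EAS", 105), ("CHS", "EAS", 108),
    ("CDX", "EAS", 95), ("KHV", "EAS", 101),
    ("CEU", "EUR", 103), ("TSI", "EUR", 109), ("FIN", "EUR", 101),
    ("GBR", "EUR", 94), ("IBS", "EUR", 109),
    ("YRI", "AFR", 110), ("LWK", "AFR", 102), ("GWD", "AFR", 115),
    ("MSL", "AFR", 85), ("ESN", "AFR", 102), ("ASW", "AFR", 66),
    ("ACB", "AFR", 96),
    ("MXL", "AMR", 67), ("PUR", "AMR", 105), ("CLM", "AMR", 96),
    ("PEL", "AMR", 87),
    ("GIH", "SAS", 106), ("PJL", "SAS", 96), ("BEB", "SAS", 86),
    ("STU", "SAS", 111), ("ITU", "SAS", 116),
]


def make_reference_panel_fixture() -> pd.DataFrame:
    """A 2577-sample panel in the 1000Genomes 26-population layout.

    The populations excluded from the height-correlation analysis (PUR, BEB,
    PJL, MSL, ASW, ACB, CEU) have their published sizes (105, 86, 96, 85,
    66, 96, 103); the other cohort sizes are synthetic and sum with them to
    2577 samples.
    """
    rows = []
    for pop, sup, n in _PANEL_LAYOUT:
        for i in range(n):
            rows.append({"sample": f"{pop}{i + 1:04d}", "population": pop, "superpopulation": sup})
    return pd.DataFrame(rows)
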
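"""Readers and writers for the external formats the pipeline touches.

All loaders enforce input filters at load time (biallelic SNPs only,
minor-allele-frequency floor, p-values in (0, 1]) and keep bookkeeping of
what was removed, so that ``retained + removed == input`` always holds.

Conventions
-----------
* Coordinates are 1-based and inclusive everywhere (VCF convention).
* Minor allele frequency is computed from the non-missing dosages of the
  loaded cohort, never taken from INFO fields.
* Missing genotypes are kept as ``NaN`` in the dosage matrix; nothing is
  imputed at load time.
* Sample order is the file order and is preserved downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: Valid metric kinds for study-comparison rows.
METRIC_TYPES = ("variance_explained", "beta", "odds_ratio", "auc")

#: Default column map for summary-statistics files: canonical name -> file column.
DEFAULT_SUMSTAT_COLUMNS = {
    "variant_id": "SNP",
    "chromosome": "CHR",
    "position": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "odds_ratio": "OR",
    "se": "SE",
    "p": "P",
}

VARIANT_COLUMNS = ["variant_id", "chromosome", "position", "ref_allele", "alt_allele"]


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed; message names the offending record."""


class DuplicateVariantError(ValueError):
    """Raised when a genotype source contains repeated variant identifiers."""


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage table.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, in input (VCF) order.
    variants : pandas.DataFrame
        One row per retained variant with columns ``variant_id``,
        ``chromosome``, ``position`` (1-based int), ``ref_allele``,
        ``alt_allele``. Row order matches dosage columns.
    dosages : numpy.ndarray
        ``(n_samples, n_variants)`` float array counting alt alleles
        (0/1/2); missing genotypes are ``NaN``.
    filter_log : dict
        Counts of variants removed per reason at load/filter time.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant over non-missing dosages."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def join_keys(self) -> pd.Series:
        """Join key per variant: variant_id, falling back to chr:pos:sorted alleles.

        The fallback covers sources that mix rsID and chr:pos conventions or
        leave the id column as '.'.
        """
        return join_keys_for(self.variants)

    def subset_variants(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given variant positional indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
            filter_log=dict(self.filter_log),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        """New matrix restricted to the given samples (kept in current order)."""
        wanted = set(sample_ids)
        missing = wanted - set(self.samples)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        idx = [i for i, s in enumerate(self.samples) if s in wanted]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
            filter_log=dict(self.filter_log),
        )


def join_keys_for(variants: pd.DataFrame) -> pd.Series:
    """Join keys for a variant table (or summary-stats table).

    Uses ``variant_id`` when present and non-missing; otherwise
    ``chromosome:position:allele1:allele2`` with alleles sorted so the key
    is orientation-free.
    """
    if {"ref_allele", "alt_allele"}.issubset(variants.columns):
        a, b = variants["ref_allele"], variants["alt_allele"]
    else:
        a, b = variants["effect_allele"], variants["other_allele"]
    a, b = a.astype(str), b.astype(str)
    lo = pd.Series(np.where(a <= b, a, b), index=variants.index)
    hi = pd.Series(np.where(a <= b, b, a), index=variants.index)
    fallback = (
        variants["chromosome"].astype(str)
        + ":"
        + variants["position"].astype(int).astype(str)
        + ":"
        + lo
        + ":"
        + hi
    )
    vid = variants["variant_id"].astype("string")
    use_id = vid.notna() & (vid != ".") & (vid != "")
    return pd.Series(np.where(use_id, vid, fallback), index=variants.index, name="join_key")


def _is_snp(ref: str, alts: list[str]) -> bool:
    if len(alts) != 1:
        return False
    alt = alts[0]
    return (
        len(ref) == 1
        and len(alt) == 1
        and ref in NUCLEOTIDES
        and alt in NUCLEOTIDES
        and ref != alt
    )


def read_genotypes(path, maf_min: float = 0.001) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`, filtering at load time.

    Multiallelic sites, indels/non-SNPs, and variants whose cohort MAF is
    <= ``maf_min`` are removed; removal counts are logged and stored in
    ``filter_log``.

    Parameters
    ----------
    path : str or Path
        Plain or bgzipped VCF.
    maf_min : float
        MAF floor in [0, 0.5); a variant is kept only if ``maf > maf_min``.

    Raises
    ------
    VCFParseError
        If the file cannot be parsed (the message names the file and, when
        known, the record).
    DuplicateVariantError
        If retained variant identifiers are not unique.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = dosage, 3 = missing
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare Exceptions for bad headers
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc

    rows, dosage_cols = [], []
    log = {"input": 0, "multiallelic": 0, "non_snp": 0, "low_maf": 0}
    try:
        for var in vcf:
            log["input"] += 1
            alts = list(var.ALT)
            if len(alts) > 1:
                log["multiallelic"] += 1
                continue
            if not _is_snp(var.REF, alts):
                log["non_snp"] += 1
                continue
            # gt_types: 0=hom-ref 1=het 2=hom-alt 3=unknown
            gt = var.gt_types.astype(float)
            dos = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
            f = np.nanmean(dos) / 2.0 if np.any(~np.isnan(dos)) else np.nan
            maf = min(f, 1.0 - f) if not np.isnan(f) else 0.0
            if not maf > maf_min:
                log["low_maf"] += 1
                continue
            vid = var.ID if var.ID not in (None, "") else "."
            rows.append((vid, str(var.CHROM), int(var.POS), var.REF, alts[0]))
            dosage_cols.append(dos)
    except Exception as exc:
        if isinstance(exc, (VCFParseError, DuplicateVariantError)):
            raise
        raise VCFParseError(
            f"cannot parse VCF {path} at record {log['input'] + 1}: {exc}"
        ) from exc

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0))
    )
    log["retained"] = len(variants)
    logger.info(
        "read_genotypes(%s): %d input, %d retained (%d multiallelic, %d non-SNP, %d low-MAF removed)",
        path, log["input"], log["retained"], log["multiallelic"], log["non_snp"], log["low_maf"],
    )
    named = variants.loc[variants["variant_id"] != ".", "variant_id"]
    dups = named[named.duplicated()].unique().tolist()
    if dups:
        raise DuplicateVariantError(f"duplicate variant ids in {path}: {dups}")
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages, filter_log=log)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Serialize a :class:`GenotypeMatrix` back to a minimal diploid VCF 4.2.

    Dosages are written as unphased GT fields; missing dosage becomes ``./.``.
    ``read_genotypes`` on the output reproduces the matrix (idempotence).
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, v in gm.variants.iterrows():
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_sumstats(path, column_map: dict | None = None, effect_scale: str = "beta",
                  sep: str | None = None) -> pd.DataFrame:
    """Load GWAS summary statistics into the canonical schema.

    Returns a DataFrame with columns ``variant_id``, ``chromosome``,
    ``position``, ``effect_allele``, ``other_allele``, ``beta``, ``se``,
    ``p``. With ``effect_scale='odds_ratio'`` the effect column is read as an
    odds ratio and stored as its natural log; rows with OR <= 0 are rejected.
    Rows with p outside (0, 1] or missing alleles are dropped; drop counts go
    to ``df.attrs['filter_log']`` and the logger.

    ``column_map`` overrides :data:`DEFAULT_SUMSTAT_COLUMNS` entries
    (canonical name -> column name in the file).
    """
    if effect_scale not in ("beta", "odds_ratio"):
        raise ValueError(f"effect_scale must be 'beta' or 'odds_ratio', got {effect_scale!r}")
    cmap = dict(DEFAULT_SUMSTAT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    effect_col = cmap["odds_ratio"] if effect_scale == "odds_ratio" else cmap["beta"]

    if sep is None:
        sep = "," if str(path).endswith(".csv") else r"\s+"
    raw = pd.read_csv(path, sep=sep)

    required = ["variant_id", "chromosome", "position", "effect_allele", "other_allele", "se", "p"]
    missing = [cmap[k] for k in required if cmap[k] not in raw.columns]
    if effect_col not in raw.columns:
        missing.append(effect_col)
    if missing:
        raise ValueError(f"summary statistics {path} lack required columns: {missing}")

    out = pd.DataFrame(
        {
            "variant_id": raw[cmap["variant_id"]].astype(str),
            "chromosome": raw[cmap["chromosome"]].astype(str),
            "position": raw[cmap["position"]].astype(int),
            "effect_allele": raw[cmap["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[cmap["other_allele"]].astype(str).str.upper(),
            "beta": pd.to_numeric(raw[effect_col], errors="coerce"),
            "se": pd.to_numeric(raw[cmap["se"]], errors="coerce"),
            "p": pd.to_numeric(raw[cmap["p"]], errors="coerce"),
        }
    )

    log = {"input": len(out)}
    bad_p = ~((out["p"] > 0) & (out["p"] <= 1))
    bad_alleles = (
        out["effect_allele"].isin(["", "NAN", "."])
        | out["other_allele"].isin(["", "NAN", "."])
        | (out["effect_allele"] == out["other_allele"])
    )
    bad_or = pd.Series(False, index=out.index)
    if effect_scale == "odds_ratio":
        bad_or = ~(out["beta"] > 0)
    drop = bad_p | bad_alleles | bad_or | out["beta"].isna()
    log.update(
        bad_p=int(bad_p.sum()),
        bad_alleles=int((bad_alleles & ~bad_p).sum()),
        nonpositive_or=int((bad_or & ~bad_p & ~bad_alleles).sum()),
    )
    out = out.loc[~drop].reset_index(drop=True)
    if effect_scale == "odds_ratio":
        out["beta"] = np.log(out["beta"])
    log["retained"] = len(out)
    if out["variant_id"].duplicated().any():
        dups = out.loc[out["variant_id"].duplicated(), "variant_id"].unique().tolist()
        raise DuplicateVariantError(f"duplicate variant ids in {path}: {dups[:10]}")
    logger.info("read_sumstats(%s): %s", path, log)
    out.attrs["filter_log"] = log
    return out


def read_panel(path) -> pd.DataFrame:
    """Read a sample panel (1000Genomes ``integrated_call_samples`` dialect).

    Whitespace/tab-delimited with a header containing at least ``sample``,
    ``pop`` and ``super_pop``. Returns a DataFrame with columns ``sample``,
    ``population``, ``superpopulation``. Duplicate consistent lines are
    deduplicated with a warning; conflicting duplicates raise.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    try:
        panel = pd.DataFrame(
            {
                "sample": df[cols["sample"]].astype(str),
                "population": df[cols["pop"]].astype(str),
                "superpopulation": df[cols["super_pop"]].astype(str),
            }
        )
    except KeyError as exc:
        raise ValueError(f"panel {path} lacks column {exc}") from exc
    before = len(panel)
    panel = panel.drop_duplicates()
    if len(panel) < before:
        warnings.warn(f"panel {path}: dropped {before - len(panel)} duplicate lines")
    conflicts = panel.loc[panel["sample"].duplicated(keep=False), "sample"].unique()
    if len(conflicts):
        raise ValueError(
            f"panel {path}: samples with conflicting population assignments: {sorted(conflicts)}"
        )
    # populations must nest within superpopulations
    nesting = panel.groupby("population")["superpopulation"].nunique()
    broken = nesting[nesting > 1].index.tolist()
    if broken:
        raise ValueError(f"panel {path}: populations in multiple superpopulations: {broken}")
    return panel.reset_index(drop=True)


def read_study_table(path) -> pd.DataFrame:
    """Read a curated study-comparison table (CSV with headers).

    Expected columns: ``study_id``, ``phenotype``, ``ancestry_group``,
    ``metric_type``, ``effect_eur``, ``effect_noneur``, ``significant_noneur``.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"study table {path} is empty")
        return df
    required = [
        "study_id", "phenotype", "ancestry_group", "metric_type",
        "effect_eur", "effect_noneur", "significant_noneur",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"study table {path} lacks columns: {missing}")
    bad = ~df["metric_type"].isin(METRIC_TYPES)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(
            f"study table {path}: unknown metric_type in rows {rows}: "
            f"{df.loc[bad, 'metric_type'].unique().tolist()}"
        )
    for col in ("effect_eur", "effect_noneur"):
        vals = pd.to_numeric(df[col], errors="raise")
        if not np.isfinite(vals).all():
            raise ValueError(f"study table {path}: non-finite values in {col}")
        df[col] = vals
    return df


def read_phenotype_table(path) -> pd.DataFrame:
    """Read a population phenotype table (CSV).

    Accepts either ``population, phenotype`` directly, or
    ``population, male, female`` in which case the two sex-specific country
    means are averaged into ``phenotype``.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "phenotype" in cols:
        out = pd.DataFrame(
            {"population": df[cols["population"]].astype(str),
             "phenotype": pd.to_numeric(df[cols["phenotype"]])}
        )
    elif "male" in cols and "female" in cols:
        out = pd.DataFrame(
            {
                "population": df[cols["population"]].astype(str),
                "phenotype": (pd.to_numeric(df[cols["male"]]) + pd.to_numeric(df[cols["female"]])) / 2.0,
            }
        )
    else:
        raise ValueError(f"phenotype table {path} needs 'phenotype' or 'male'+'female' columns")
    if out["population"].duplicated().any():
        raise ValueError(f"phenotype table {path}: duplicate population rows")
    if not np.isfinite(out["phenotype"]).all():
        raise ValueError(f"phenotype table {path}: non-finite phenotype values")
    return out


def write_scores(prs_matrix, path) -> None:
    """Write a PRS matrix as a long CSV: sample, clump_spec, p_T, score, n_variants.

    Scores are written with 17 significant digits so a write -> read round
    trip is stable to at least 12 significant digits.
    """
    long = prs_matrix.to_long()
    long.to_csv(path, index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    """Read a scores CSV written by :func:`write_scores` (long layout)."""
    df = pd.read_csv(path, dtype={"sample": str, "clump_spec": str})
    required = ["sample", "clump_spec", "p_T", "score", "n_variants"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"scores file {path} lacks columns: {missing}")
    return df
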
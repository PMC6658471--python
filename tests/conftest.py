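import numpy as np
import pandas as pd
import pytest

from polyport import synthetic_data as sd
from polyport.io_formats import GenotypeMatrix


def make_genotype_matrix(dosages, positions=None, chromosome="1", ids=None,
                         ref="A", alt="G"):
    """Small literal GenotypeMatrix for hand-built test cases."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if ids is None:
        ids = [f"rs{j + 1}" for j in range(m)]
    refs = [ref] * m if isinstance(ref, str) else list(ref)
    alts = [alt] * m if isinstance(alt, str) else list(alt)
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": str(chromosome),
            "position": positions,
            "ref_allele": refs,
            "alt_allele": alts,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i + 1}" for i in range(n)], variants=variants, dosages=dosages
    )


def write_vcf_text(path, records, samples=("s1", "s2", "s3", "s4")):
    """Write a toy VCF: records are (chrom, pos, id, ref, alt, genotypes)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, vid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    def _factory(records, samples=("s1", "s2", "s3", "s4"), name="toy.vcf"):
        return write_vcf_text(tmp_path / name, records, samples)

    return _factory


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two populations at FST 0.1, independent variants; shared across tests."""
    anc = sd.sample_ancestral_freqs(5000, 11)
    pf = sd.balding_nichols_freqs(anc, (0.1, 0.1), 12)
    gm, panel = sd.simulate_genotypes(pf, 150, block_size=1, within_block_r=0.0, seed=13)
    return gm, panel, pf


@pytest.fixture(scope="session")
def three_pop_cohort():
    """Three populations with LD blocks, plus discovery GWAS ingredients."""
    anc = sd.sample_ancestral_freqs(400, 21)
    pf = sd.balding_nichols_freqs(anc, (0.02, 0.08, 0.15), 22)
    gm, panel = sd.simulate_genotypes(pf, 100, block_size=5, within_block_r=0.5, seed=23)
    disc_gm, _ = sd.simulate_genotypes(pf.loc[["POP1"]], 400, block_size=5, within_block_r=0.5, seed=24)
    y, truth = sd.simulate_phenotype(disc_gm, 40, 0.5, 25)
    sumstats = sd.run_gwas(disc_gm, y)
    truth.pop_freqs = pf
    return gm, panel, pf, sumstats, truth
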
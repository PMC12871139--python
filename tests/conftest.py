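import numpy as np
import pandas as pd
import pytest

from hybridzone import simzone as sz


def small_architecture():
    """Architecture scaled for a 2-chromosome, 60-locus-per-chromosome zone."""
    return (
        sz.ClineBlock("steep_block", chrom=0, start_locus=5, n_loci=10, v=3.0),
        sz.ClineBlock("shallow_block", chrom=1, start_locus=5, n_loci=10, v=0.3),
        sz.ClineBlock("het_excess_block", chrom=1, start_locus=30, n_loci=3,
                      v=0.3, force_het=True),
        sz.ClineBlock("hue_locus", chrom=0, start_locus=30, n_loci=1,
                      v=0.3, c=0.35),
    )


@pytest.fixture(scope="session")
def small_config():
    return sz.SimConfig(n_parent1=15, n_parent2=15, n_hybrids=80,
                        n_chromosomes=2, loci_per_chromosome=60,
                        chromosome_length_bp=5_000_000,
                        cline_architecture=small_architecture(), seed=42)


@pytest.fixture(scope="session")
def bundle(small_config):
    """A small simulated zone reused across read-only tests."""
    return sz.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def parental_freqs(bundle):
    from hybridzone import popstats as ps

    return ps.allele_freqs(bundle.genotypes, bundle.metadata)


@pytest.fixture()
def toy_vcf(tmp_path):
    """3-sample, 4-record toy VCF: one clean SNP, a multiallelic record,
    an indel, and a half-call/phased-genotype SNP."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t300\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t400\t.\tC\tT\t.\tPASS\t.\tGT\t./1\t1|1\t./.
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture()
def toy_gff(tmp_path):
    text = """##gff-version 3
chr1\tsrc\tgene\t1000\t2500\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t1000\t1900\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\tsrc\tmRNA\t1000\t2200\t.\t+\t.\tID=geneA.t2;Parent=geneA
chr1\tsrc\tgene\t5000\t6000\t.\t-\t.\tID=geneB
chr2\tsrc\tgene\t100\t900\t.\t+\t.\tID=geneC
"""
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path


def make_matrix(dosage, chrom="chr1", spacing=100):
    """GenotypeMatrix from a plain dosage array (rows = samples)."""
    from hybridzone.dataio import GenotypeMatrix

    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    var = pd.DataFrame({"chrom": chrom, "pos": (np.arange(L) + 1) * spacing,
                        "ref": "A", "alt": "G"})
    return GenotypeMatrix([f"s{i}" for i in range(n)], var, dosage)
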
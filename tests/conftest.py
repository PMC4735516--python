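import numpy as np
import pytest

from enums_ne import HaplotypeMatrix


def make_matrix(columns, positions=None, chromosome="1"):
    """Haplotype matrix from a list of 0/1 strings (one per haplotype)."""
    alleles = np.array([[int(c) for c in row] for row in columns], dtype=np.int8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    refs = np.array(["A"] * n_sites)
    alts = np.array(["G"] * n_sites)
    return HaplotypeMatrix(
        chromosome=chromosome,
        positions=np.asarray(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        alleles=alleles,
        haplotype_ids=[f"s{i // 2}|{i % 2}" for i in range(alleles.shape[0])],
    )


@pytest.fixture
def four_gamete_matrix():
    """Sites 0-1 compatible (identical columns), site 2 shows all four
    gametes against both of them."""
    return make_matrix(["000", "001", "110", "111"])


@pytest.fixture
def clean_matrix():
    """No four-gamete violation anywhere (perfect nesting)."""
    return make_matrix(["0000", "1000", "1100", "1110"])


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path
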
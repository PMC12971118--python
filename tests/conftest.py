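import numpy as np
import pytest

from adaptscan.genotype_io import (
    MISSING, GenotypeMatrix, SampleTable, Variant, read_vcf,
)

# Hand-written 4-sample, 6-record VCF: one triallelic record (sc1:200),
# one record with DP=2 cells (sc2:50), one explicit missing genotype
# (sc1:300, S1), one monomorphic site (sc2:60).
TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##contig=<ID=sc1>
##contig=<ID=sc2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
sc1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:12\t1/1:9\t0/1:11
sc1\t200\t.\tG\tC,T\t.\tPASS\t.\tGT:DP\t0/0:10\t1/2:8\t0/1:15\t2/2:9
sc1\t300\t.\tC\tG\t.\tPASS\t.\tGT:DP\t./.:.\t0/1:7\t0/0:5\t1/1:6
sc2\t50\t.\tT\tA\t.\tPASS\t.\tGT:DP\t0/1:2\t0/0:2\t0/1:10\t1/1:12
sc2\t60\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:9\t0/0:8\t0/0:11\t0/0:10
sc2\t70\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:20\t1/1:18\t0/1:9\t0/1:7
"""

# Hand transcription of TOY_VCF, made from the text above (samples x
# variants; -1 = missing). Alt dosage counts every non-reference allele,
# so the triallelic 1/2 genotype is dosage 2.
TOY_DOSAGE = np.array(
    [
        [0, 0, MISSING, 1, 0, 2],
        [1, 2, 1, 0, 0, 2],
        [2, 1, 0, 1, 0, 1],
        [1, 2, 2, 2, 0, 1],
    ]
)
TOY_DEPTH = np.array(
    [
        [10, 10, MISSING, 2, 9, 20],
        [12, 8, 7, 2, 8, 18],
        [9, 15, 5, 10, 11, 9],
        [11, 9, 6, 12, 10, 7],
    ]
)


@pytest.fixture
def toy_vcf_path(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_gm(toy_vcf_path):
    return read_vcf(toy_vcf_path)


def make_gm(dosage, populations=None, depth=None):
    """Build a GenotypeMatrix from a plain samples-x-variants array."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if depth is None:
        depth = np.full((n, m), 10, dtype=np.int32)
        depth[dosage == MISSING] = MISSING
    if populations is None:
        populations = ["pop1"] * n
    samples = SampleTable([f"s{i}" for i in range(n)], list(populations))
    variants = [Variant("chr1", j + 1, "A", ("T",)) for j in range(m)]
    return GenotypeMatrix(samples, variants, dosage, depth)
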
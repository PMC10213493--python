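import numpy as np
import pytest

from hapclean.scheme import MatingDesign, StateSpace


@pytest.fixture(scope="session")
def f2_design() -> MatingDesign:
    return MatingDesign.from_scenario("homoP2_F2")


@pytest.fixture(scope="session")
def f2_space(f2_design) -> StateSpace:
    return StateSpace(f2_design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


VCF_BODY = """\
##fileformat=VCFv4.3
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tS1
chr1\t100\tm1\tA\tC\t.\t.\t.\tGT:AD\t0/0:3,1\t1/1:0,4\t./.:0,0
chr1\t200\tm2\tA\tC,T\t.\t.\t.\tGT:AD\t0/0:5,0,0\t1/1:0,5,0\t./.:1,1,0
chr1\t300\tm3\tG\tT\t.\t.\t.\tGT:AD\t0/0:2,0\t1/1:.\t0/1:1,2
"""


@pytest.fixture()
def small_vcf(tmp_path):
    """Three records: one multiallelic (dropped), one with a missing AD."""
    p = tmp_path / "small.vcf"
    p.write_text(VCF_BODY)
    return p
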
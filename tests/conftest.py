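import numpy as np
import pytest

from snpcascade import GenotypeMatrix, SimSpec, simulate_populations

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMSMappingQuality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">
##INFO=<ID=SOR,Number=1,Type=Float,Description="StrandOddsRatio">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def make_vcf(path, rows, samples=("s1", "s2", "s3")):
    """Write a minimal VCF; rows = (chrom, pos, ref, alt, qual, info, gts)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, qual, info, gts in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


@pytest.fixture
def toy_gm():
    values = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, -1],
            [2, 0, 1, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["a", "b", "c"], ["L1", "L2", "L3", "L4"], values)


@pytest.fixture(scope="session")
def two_pop_separable():
    """Two well-differentiated populations (strong drift, 30 samples each)."""
    spec = SimSpec(
        n_populations=2, samples_per_population=30, n_loci=60, fst=0.5, seed=11
    )
    gm, labels, pf = simulate_populations(spec)
    return gm, labels, pf


@pytest.fixture(scope="session")
def four_pop():
    spec = SimSpec(
        n_populations=4, samples_per_population=25, n_loci=150, fst=0.2, seed=7
    )
    gm, labels, pf = simulate_populations(spec)
    return gm, labels, pf
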
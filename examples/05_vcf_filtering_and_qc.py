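"""Hard-filter variants, convert VCF genotypes to dosages, and QC a panel.

Builds a small VCF in a temp directory, applies GATK-style hard filters
(QUAL < 30, QD < 2, MQ < 4, MQRankSum < -12.4, ReadPosRankSum < -8,
FS > 60, SOR > 3 — any firing rule rejects), converts GT fields to the
0/1/2 dosage encoding, and drops monomorphic loci and high-missingness
samples.
"""

import tempfile
from pathlib import Path

from snpcascade import (
    hard_filter_variants,
    qc_loci,
    qc_samples,
    read_vcf_records,
    vcf_to_genotypes,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""
ROWS = [
    "chr1\t100\t.\tA\tT\t90\t.\tQD=12;FS=2\tGT\t0/0\t0/1\t1/1",
    "chr1\t200\t.\tG\tC\t90\t.\tQD=12;FS=75\tGT\t0/0\t0/0\t0/1",  # strand bias
    "chr1\t300\t.\tT\tA\t12\t.\tQD=12;FS=2\tGT\t1/1\t./.\t0/1",   # low QUAL
    "chr1\t400\t.\tC\tG\t90\t.\tQD=12;FS=2\tGT\t0/0\t0/0\t0/0",   # monomorphic
]

with tempfile.TemporaryDirectory() as d:
    vcf = Path(d) / "toy.vcf"
    vcf.write_text(HEADER + "\n".join(ROWS) + "\n")

    records = read_vcf_records(vcf)
    kept, rejected = hard_filter_variants(records)
    print(f"hard filter: kept {len(kept)} of {len(records)} records")
    for rec, rules in rejected:
        print(f"  rejected {rec.key}: fired {', '.join(rules)}")

    gm = vcf_to_genotypes(vcf)
    print(f"\ndosage matrix: {gm.n_samples} samples x {gm.n_loci} loci")
    print(gm.to_dataframe().to_string())

    gm2, dropped = qc_loci(gm)
    print(f"\nlocus QC dropped {dropped} (homozygous in every sample)")
    gm3, report = qc_samples(gm2, max_missing_count=96, max_missing_frac=0.5)
    print(f"sample QC kept {gm3.n_samples} of {gm2.n_samples} samples "
          "(none exceed 96 missing loci or 50% missingness)")
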
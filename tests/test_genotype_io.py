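import numpy as np
import pytest

from snpcascade import (
    MISSING,
    GenotypeMatrix,
    LocusMeta,
    VariantRecord,
    flank_filter,
    hard_filter_variants,
    qc_loci,
    qc_samples,
    read_genotype_table,
    read_vcf_records,
    vcf_to_genotypes,
    write_genotype_table,
)
from snpcascade.genotype_io import DEFAULT_HARD_FILTERS, GenotypeError

from conftest import make_vcf


class TestGenotypeMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(GenotypeError, match="duplicate"):
            GenotypeMatrix(["a", "a"], ["L1"], np.zeros((2, 1), dtype=np.int8))

    def test_rejects_illegal_value(self):
        with pytest.raises(GenotypeError, match="illegal genotype 3"):
            GenotypeMatrix(["a"], ["L1"], np.array([[3]], dtype=np.int8))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(GenotypeError, match="inconsistent"):
            GenotypeMatrix(["a", "b"], ["L1"], np.zeros((2, 2), dtype=np.int8))

    def test_subset_preserves_order_and_meta(self, toy_gm):
        sub = toy_gm.subset(samples=["c", "a"], loci=["L3", "L1"])
        assert sub.sample_ids == ["c", "a"]
        assert sub.values.tolist() == [[1, 2], [2, 0]]


class TestTabularIO:
    def test_round_trip_identity(self, toy_gm, tmp_path):
        p = tmp_path / "g.tsv"
        write_genotype_table(toy_gm, p)
        back = read_genotype_table(p)
        assert back.sample_ids == toy_gm.sample_ids
        assert back.locus_ids == toy_gm.locus_ids
        assert np.array_equal(back.values, toy_gm.values)

    def test_missing_token_maps_to_sentinel(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample\tL1\tL2\nA\t0\tNA\nB\t2\t1\n")
        gm = read_genotype_table(p, missing_token="NA")
        assert gm.values[0, 1] == MISSING
        assert gm.values[1, 0] == 2

    def test_bad_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample\tL1\tL2\nA\t0\t1\nB\t2\tx\n")
        with pytest.raises(GenotypeError, match=r"'B'.*'L2'"):
            read_genotype_table(p)


class TestVcfConversion:
    def test_diploid_gt_dosages(self, tmp_path):
        p = make_vcf(
            tmp_path / "t.vcf",
            [
                ("chr1", 100, "A", "T", 50, ".", ["0/0", "0/1", "1/1"]),
                ("chr1", 200, "G", "C", 50, ".", ["1/0", "./.", "0/0"]),
            ],
        )
        gm = vcf_to_genotypes(p)
        assert gm.locus_ids == ["chr1:100", "chr1:200"]
        assert gm.values[:, 0].tolist() == [0, 1, 2]
        assert gm.values[:, 1].tolist() == [1, MISSING, 0]

    def test_haploid_diplotize_doubles_allele(self, tmp_path):
        p = make_vcf(
            tmp_path / "t.vcf",
            [
                ("chr1", 100, "A", "T", 50, ".", ["0", "1", "."]),
                ("chr1", 150, "C", "G", 50, ".", ["1", "0", "1"]),
                ("chr2", 10, "T", "A", 50, ".", ["0", "0", "1"]),
            ],
        )
        gm = vcf_to_genotypes(p, diplotize=True)
        assert gm.values[:, 0].tolist() == [0, 2, MISSING]
        assert gm.values[:, 1].tolist() == [2, 0, 2]
        assert gm.values[:, 2].tolist() == [0, 0, 2]
        # without diplotize the haploid dosage is the raw allele count
        raw = vcf_to_genotypes(p)
        assert raw.values[:, 1].tolist() == [1, 0, 1]

    def test_multiallelic_error_or_skip(self, tmp_path):
        p = make_vcf(
            tmp_path / "t.vcf",
            [
                ("chr1", 100, "A", "T,G", 50, ".", ["0/0", "0/1", "1/1"]),
                ("chr1", 200, "G", "C", 50, ".", ["0/0", "0/0", "1/1"]),
            ],
        )
        with pytest.raises(GenotypeError, match="multiallelic"):
            vcf_to_genotypes(p)
        gm = vcf_to_genotypes(p, on_multiallelic="skip")
        assert gm.locus_ids == ["chr1:200"]

    def test_dosage_equals_alt_allele_count(self, tmp_path):
        # oracle: direct GT string parse
        gts = ["0/0", "0/1", "1/1", "1/0", "./.", "0/0"]
        p = make_vcf(
            tmp_path / "t.vcf",
            [("chr1", 100, "A", "T", 50, ".", gts)],
            samples=tuple(f"s{i}" for i in range(6)),
        )
        gm = vcf_to_genotypes(p)
        expected = [
            g.count("1") if "." not in g else MISSING for g in gts
        ]
        assert gm.values[:, 0].tolist() == expected


class TestHardFilter:
    def _passing(self, **overrides):
        ann = {
            "QD": 10.0, "MQ": 50.0, "MQRankSum": 0.0,
            "ReadPosRankSum": 0.0, "FS": 1.0, "SOR": 1.0,
        }
        qual = overrides.pop("QUAL", 100.0)
        ann.update(overrides)
        return VariantRecord("chr1", 1, "A", "T", qual=qual, annotations=ann)

    def test_fs_violation_rejected_with_reason(self):
        kept, rejected = hard_filter_variants([self._passing(FS=61.0)])
        assert not kept
        assert rejected[0][1] == ["FS"]

    def test_boundary_values_kept_under_strict_inequalities(self):
        rec = self._passing(
            QUAL=30.0, QD=2.0, MQ=4.0, MQRankSum=-12.4,
            ReadPosRankSum=-8.0, FS=60.0, SOR=3.0,
        )
        kept, rejected = hard_filter_variants([rec])
        assert len(kept) == 1 and not rejected

    def test_each_rule_fires_exactly_once_on_toy_vcf(self, tmp_path):
        # 7-record VCF, each record violating exactly one printed rule
        violations = [
            ("QUAL", {"QUAL": 29.0}),
            ("QD", {"QD": 1.9}),
            ("MQ", {"MQ": 3.9}),
            ("MQRankSum", {"MQRankSum": -12.5}),
            ("ReadPosRankSum", {"ReadPosRankSum": -8.1}),
            ("FS", {"FS": 60.1}),
            ("SOR", {"SOR": 3.1}),
        ]
        rows = []
        for i, (_, ov) in enumerate(violations):
            ann = {
                "QD": 10.0, "MQ": 50.0, "MQRankSum": 0.0,
                "ReadPosRankSum": 0.0, "FS": 1.0, "SOR": 1.0,
            }
            qual = ov.get("QUAL", 100.0)
            ann.update({k: v for k, v in ov.items() if k != "QUAL"})
            info = ";".join(f"{k}={v}" for k, v in ann.items())
            rows.append(("chr1", 100 + i, "A", "T", qual, info, ["0/1"] * 3))
        p = make_vcf(tmp_path / "seven.vcf", rows)
        kept, rejected = hard_filter_variants(read_vcf_records(p))
        assert len(kept) == 0 and len(rejected) == 7
        reasons = [tuple(r[1]) for r in rejected]
        assert sorted(reasons) == sorted((v[0],) for v in violations)

    def test_partition_property(self):
        recs = [self._passing(), self._passing(FS=61.0), self._passing(QD=1.0)]
        kept, rejected = hard_filter_variants(recs)
        assert len(kept) + len(rejected) == len(recs)

    def test_strict_mode_errors_on_absent_annotation(self):
        rec = VariantRecord("chr1", 1, "A", "T", qual=100.0, annotations={})
        kept, _ = hard_filter_variants([rec])  # lenient: rule does not fire
        assert len(kept) == 1
        with pytest.raises(GenotypeError, match="absent"):
            hard_filter_variants([rec], strict=True)


class TestSampleLocusQC:
    def _matrix_with_missing(self, n_loci, n_missing):
        vals = np.zeros((2, n_loci), dtype=np.int8)
        vals[0, 1] = 1  # keep a polymorphic locus around
        vals[1, :n_missing] = MISSING
        return GenotypeMatrix(["ok", "gappy"], [f"L{j}" for j in range(n_loci)], vals)

    def test_cutoff_96_is_inclusive_keep(self):
        gm = self._matrix_with_missing(272, 96)
        kept, report = qc_samples(gm, max_missing_count=96)
        assert "gappy" in kept.sample_ids and len(report) == 0

    def test_97_missing_of_272_dropped(self):
        gm = self._matrix_with_missing(272, 97)
        kept, report = qc_samples(gm, max_missing_count=96)
        assert kept.sample_ids == ["ok"]
        assert report.iloc[0]["n_missing"] == 97

    def test_fraction_threshold(self):
        gm = self._matrix_with_missing(100, 51)
        kept, _ = qc_samples(gm, max_missing_frac=0.5)
        assert kept.sample_ids == ["ok"]

    def test_requires_a_threshold(self, toy_gm):
        with pytest.raises(ValueError):
            qc_samples(toy_gm)

    def test_monomorphic_loci_dropped(self):
        vals = np.array([[0, 0, 1], [0, 0, 2], [0, 1, 0]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c"], ["mono", "poly", "poly2"], vals)
        kept, dropped = qc_loci(gm)
        assert dropped == ["mono"]
        assert kept.locus_ids == ["poly", "poly2"]

    def test_288_to_272_locus_reduction(self):
        # 288-locus matrix with 16 constant columns
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, size=(20, 288)).astype(np.int8)
        vals[:, :16] = 1
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(20)], [f"L{j}" for j in range(288)], vals
        )
        kept, dropped = qc_loci(gm)
        assert kept.n_loci == 272 and len(dropped) == 16


class TestFlankFilter:
    def test_neighbor_at_window_edge_excludes(self):
        lm = LocusMeta("x", "chr1", 1000, "A", "T", flanking_variants=[1032])
        assert flank_filter([lm], window_bases=32) == []

    def test_neighbor_beyond_window_keeps(self):
        lm = LocusMeta("x", "chr1", 1000, "A", "T", flanking_variants=[1033, 967])
        assert flank_filter([lm], window_bases=32) == ["x"]

    def test_no_neighbors_keeps(self):
        lm = LocusMeta("x", "chr1", 1000, "A", "T")
        assert flank_filter([lm]) == ["x"]

    def test_negative_window_errors(self):
        with pytest.raises(ValueError):
            flank_filter([], window_bases=-1)

    def test_locus_meta_invariants(self):
        with pytest.raises(GenotypeError):
            LocusMeta("x", "chr1", 0, "A", "T")
        with pytest.raises(GenotypeError):
            LocusMeta("x", "chr1", 5, "A", "A")
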
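"""Variant data model, predictor-call normalization, and file round-trips."""

import math

import pytest

from riskcluster.variants import (
    AnnotationKeys,
    DELETERIOUS,
    MISSING,
    TOLERATED,
    SVRecord,
    SmallVariantRecord,
    normalize_predictor_call,
    read_small_variants,
    read_small_variants_tsv,
    read_svs,
    read_svs_tsv,
    write_records,
    write_small_variants_tsv,
    write_svs_tsv,
)


def _small_eq(a: SmallVariantRecord, b: SmallVariantRecord) -> bool:
    float_ok = all(
        (x is None and y is None) or (x is not None and y is not None
                                      and math.isclose(x, y, rel_tol=1e-6))
        for x, y in [(a.af_1000g, b.af_1000g),
                     (a.af_exac_nontcga, b.af_exac_nontcga),
                     (a.cadd_phred, b.cadd_phred)]
    )
    return float_ok and (a.chrom, a.pos, a.ref, a.alt, a.rsid, a.predictors,
                         a.region, a.gene, a.regulomedb, a.presence) == \
        (b.chrom, b.pos, b.ref, b.alt, b.rsid, b.predictors,
         b.region, b.gene, b.regulomedb, b.presence)


def _sv_eq(a: SVRecord, b: SVRecord) -> bool:
    float_ok = all(
        (x is None and y is None) or (x is not None and y is not None
                                      and math.isclose(x, y, rel_tol=1e-6))
        for x, y in [(a.af_1000g, b.af_1000g), (a.af_gnomad, b.af_gnomad)]
    )
    return float_ok and (a.sv_id, a.chrom, a.start, a.end, a.svtype,
                         a.annotsv_ranking, a.depth_validated, a.gene,
                         a.location, a.mate, a.presence) == \
        (b.sv_id, b.chrom, b.start, b.end, b.svtype, b.annotsv_ranking,
         b.depth_validated, b.gene, b.location, b.mate, b.presence)


class TestPredictorNormalization:
    @pytest.mark.parametrize("tool,code,expected", [
        ("MutationTaster", "A", DELETERIOUS),
        ("MutationTaster", "D", DELETERIOUS),
        ("PolyPhen2", "P", DELETERIOUS),
        ("PolyPhen2", "B", TOLERATED),
        ("PROVEAN", "D", DELETERIOUS),
        ("PROVEAN", "N", TOLERATED),
        ("SIFT", "T", TOLERATED),
        ("SIFT", "?", MISSING),
        ("SIFT", None, MISSING),
    ])
    def test_letter_codes(self, tool, code, expected):
        assert normalize_predictor_call(tool, code) == expected


class TestModelInvariants:
    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            SmallVariantRecord("1", 10, "A", "T", af_1000g=1.5)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            SmallVariantRecord("1", 10, "A", "T", region="promoter")

    def test_bnd_has_no_length(self):
        rec = SVRecord("7", 103463079, 103463080, "BND")
        assert rec.length is None

    def test_del_length_is_span(self):
        rec = SVRecord("13", 110418067, 110419056, "DEL")
        assert rec.length == 989
        assert rec.sv_id == "13_110418067_110419056_DEL_1"

    def test_depth_flag_only_for_del_dup(self):
        rec = SVRecord("1", 100, 200, "INV", depth_validated=True)
        assert rec.depth_validated is None

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError, match="start"):
            SVRecord("1", 200, 100, "DEL")


class TestVCFReading:
    def test_genotype_presence_semantics(self, tmp_path):
        """0/1 carries, ./. is absent."""
        vcf = tmp_path / "two.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=REGION,Number=1,Type=String,Description="r">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\trs1\tA\tT\t.\t.\tREGION=exonic\tGT\t0/1\t./.\n"
        )
        (rec,) = read_small_variants(vcf, ["A", "B"])
        assert rec.presence == (True, False)

    def test_multiallelic_site_splits_per_alt(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\t.\tA\tT,G\t.\t.\t.\tGT\t1/2\t0/2\n"
        )
        recs = read_small_variants(vcf, ["A", "B"])
        assert len(recs) == 2
        assert {(r.alt, r.presence) for r in recs} == {
            ("T", (True, False)), ("G", (True, True))}
        assert recs[0].chrom == recs[1].chrom and recs[0].pos == recs[1].pos

    def test_missing_required_sample_is_hard_error(self, tmp_path):
        vcf = tmp_path / "one.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="samples absent"):
            read_small_variants(vcf, ["A", "MISSING_SUBJECT"])

    def test_del_without_end_is_hard_error(self, tmp_path):
        vcf = tmp_path / "sv.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="lacks END"):
            read_svs(vcf, ["A"])

    def test_bnd_counted_per_record_with_mate_parsed(self, cohort):
        svs = read_svs(cohort.sv_vcf, cohort.subject_order)
        bnds = [r for r in svs if r.svtype == "BND"]
        truth_bnds = [r for r in cohort.sv_records if r.svtype == "BND"]
        assert len(bnds) == len(truth_bnds)  # never merged to n/2
        paired = [r for r in bnds if r.mate_id]
        assert paired, "expected linked mate pairs"
        by_id = {r.sv_id: r for r in bnds}
        for r in paired:
            mate = by_id[r.mate_id]
            assert r.mate == (mate.chrom, mate.start)


class TestRoundTrips:
    def test_small_vcf_round_trip(self, cohort, tmp_path):
        order = cohort.subject_order
        out = tmp_path / "again.vcf"
        first = read_small_variants(cohort.small_vcf, order)
        write_records(first, out, "VCF", subjects=order)
        second = read_small_variants(out, order)
        assert len(first) == len(second)
        assert all(_small_eq(a, b) for a, b in zip(first, second))

    def test_sv_vcf_round_trip(self, cohort, tmp_path):
        order = cohort.subject_order
        out = tmp_path / "again_sv.vcf"
        first = read_svs(cohort.sv_vcf, order)
        write_records(first, out, "VCF", subjects=order)
        second = read_svs(out, order)
        assert len(first) == len(second)
        assert all(_sv_eq(a, b) for a, b in zip(first, second))

    def test_tsv_round_trips(self, cohort, tmp_path):
        small = cohort.small_records
        svs = cohort.sv_records
        write_small_variants_tsv(small, tmp_path / "s.tsv")
        write_svs_tsv(svs, tmp_path / "v.tsv")
        assert all(_small_eq(a, b) for a, b in
                   zip(small, read_small_variants_tsv(tmp_path / "s.tsv")))
        assert all(_sv_eq(a, b) for a, b in zip(svs, read_svs_tsv(tmp_path / "v.tsv")))

    def test_empty_record_list_writes_header_only(self, tmp_path):
        write_records([], tmp_path / "empty.vcf", "VCF", subjects=["A"])
        assert read_small_variants(tmp_path / "empty.vcf", ["A"]) == []
        write_records([], tmp_path / "empty.tsv", "TSV")
        assert read_small_variants_tsv(tmp_path / "empty.tsv") == []

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            write_records([], "out.xlsx", "XLSX")


class TestAnnotationKeys:
    def test_yaml_override(self, tmp_path):
        f = tmp_path / "keys.yaml"
        f.write_text("af_1000g: KG_AF\ncadd_phred: CADD\n")
        keys = AnnotationKeys.from_yaml(f)
        assert keys.af_1000g == "KG_AF" and keys.cadd_phred == "CADD"
        assert keys.sift == "SIFT"  # untouched default

    def test_unknown_key_name_rejected(self, tmp_path):
        f = tmp_path / "keys.yaml"
        f.write_text("no_such_field: X\n")
        with pytest.raises(ValueError, match="unknown annotation-key"):
            AnnotationKeys.from_yaml(f)
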
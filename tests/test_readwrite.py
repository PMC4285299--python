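"""Table and VCF readers/writers and the parameters audit file."""

import pytest

from exomesift.core import ConsequenceClass, GenomicInterval, Zygosity
from exomesift.readwrite import (
    CuratedVariantList,
    FilterParameters,
    SchemaError,
    annotate_observation_counts,
    annotate_with_curated_scores,
    load_parameters,
    read_annotated_table,
    read_gene_panel,
    read_observation_counts,
    read_vcf,
    save_parameters,
    write_annotated_table,
)

VCF_TEXT = """\
##fileformat=VCFv4.1
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr17>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr17\t41245466\t.\tG\tA\t900\t.\t.\tGT:DP:AD\t0/1:120:60,60
chr17\t41245470\trs111\tC\tT\t500\t.\t.\tGT:DP:AD\t1/1:80:0,80
chr2\t1000\t.\tA\tC,T\t300\t.\t.\tGT:DP:AD\t1/2:90:0,45,45
chr2\t2000\t.\tG\tA\t250\t.\t.\tGT:DP\t./.:50
chr2\t3000\t.\tT\tG\t100\t.\t.\tGT\t1
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "sample.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestReadVcf:
    def test_direct_field_mapping(self, vcf_path):
        v = read_vcf(vcf_path)[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr17", 41245466, "G", "A")
        assert v.zygosity is Zygosity.HETEROZYGOUS
        assert (v.quality, v.depth, v.alt_depth) == (900.0, 120, 60)

    def test_homozygous_and_dbsnp_id(self, vcf_path):
        v = read_vcf(vcf_path)[1]
        assert v.zygosity is Zygosity.HOMOZYGOUS
        assert v.dbsnp_id == "rs111"
        assert v.alt_depth == 80

    def test_multiallelic_split(self, vcf_path):
        # oracle: manual split of the two-alt record
        rows = [v for v in read_vcf(vcf_path) if v.pos == 1000]
        assert [(v.alt, v.alt_depth) for v in rows] == [("C", 45), ("T", 45)]
        assert all(v.zygosity is Zygosity.HETEROZYGOUS for v in rows)

    def test_missing_gt_is_unknown_not_error(self, vcf_path):
        v = [x for x in read_vcf(vcf_path) if x.pos == 2000][0]
        assert v.zygosity is Zygosity.UNKNOWN
        assert v.depth == 50

    def test_haploid_call_is_hemizygous(self, vcf_path):
        v = [x for x in read_vcf(vcf_path) if x.pos == 3000][0]
        assert v.zygosity is Zygosity.HEMIZYGOUS

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(ValueError):
            read_vcf(p)


class TestAnnotatedTable:
    def test_round_trip_identity_on_typed_fields(self, tmp_path, variant_factory):
        variants = [
            variant_factory(),
            variant_factory(
                pos=2000,
                maf=0.05,
                dbsnp_id="rs42",
                consequence=ConsequenceClass.INTRONIC,
                splice_distance=-7,
                pathogenicity_score=5.0,
                extras={"note": "seen before"},
            ),
        ]
        p = tmp_path / "t.tsv"
        write_annotated_table(variants, p)
        back = read_annotated_table(p)
        assert back == variants

    def test_missing_sentinels_parse_as_none_not_zero(self, tmp_path, variant_factory):
        p = tmp_path / "t.tsv"
        write_annotated_table([variant_factory(maf=None)], p)
        v = read_annotated_table(p)[0]
        assert v.maf is None
        assert v.pathogenicity_score is None

    def test_signed_splice_distance(self, tmp_path, variant_factory):
        p = tmp_path / "t.tsv"
        write_annotated_table([variant_factory(splice_distance=-7)], p)
        assert read_annotated_table(p)[0].splice_distance == -7

    def test_empty_table_is_not_an_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_annotated_table([], p)
        assert read_annotated_table(p) == []

    def test_missing_columns_named_in_schema_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tpos\tref\n")
        with pytest.raises(SchemaError, match="alt.*gene|gene.*alt"):
            read_annotated_table(p)


class TestCohortAnnotations:
    def test_curated_score_attachment(self, variant_factory):
        v = variant_factory()
        curated = CuratedVariantList({v.key: 5.0})
        out = annotate_with_curated_scores([v], curated)
        assert out[0].pathogenicity_score == 5.0
        assert v.pathogenicity_score is None  # input untouched

    def test_same_position_different_alt_no_attachment(self, variant_factory):
        v = variant_factory(alt="G")
        curated = CuratedVariantList({("chr1", 1000, "A", "T"): 5.0})
        assert annotate_with_curated_scores([v], curated)[0].pathogenicity_score is None

    def test_empty_curated_list_is_identity(self, variant_factory):
        v = variant_factory()
        assert annotate_with_curated_scores([v], CuratedVariantList())[0] == v

    def test_observation_counts_default_zero(self, variant_factory):
        v = variant_factory()
        out = annotate_observation_counts([v], {("chrX", 1, "A", "T"): 17})
        assert out[0].observation_count == 0

    def test_observation_counts_attached(self, variant_factory):
        v = variant_factory()
        assert annotate_observation_counts([v], {v.key: 17})[0].observation_count == 17

    def test_duplicate_count_keys_rejected(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tcount\n"
            "chr1\t1000\tA\tG\t3\n"
            "chr1\t1000\tA\tG\t4\n"
        )
        with pytest.raises(SchemaError, match="duplicate"):
            read_observation_counts(p)


class TestParametersFile:
    def test_default_round_trip(self, tmp_path):
        p = tmp_path / "params.txt"
        params = FilterParameters()
        save_parameters(params, p)
        assert load_parameters(p) == params

    def test_round_trip_with_many_regions_and_panel(self, tmp_path):
        regions = [
            GenomicInterval("chr17", 1 + i * 500, 200 + i * 500, f"ex{i}")
            for i in range(591)
        ]
        params = FilterParameters(
            min_quality=50.0,
            min_depth=30,
            regions=regions,
            gene_panel=frozenset({"BRCA1", "BRCA2"}),
            inheritance_mode="dominant",
            notes="phase 1 rerun",
        )
        p = tmp_path / "params.txt"
        save_parameters(params, p)
        assert load_parameters(p) == params

    def test_unknown_key_named(self, tmp_path):
        p = tmp_path / "params.txt"
        save_parameters(FilterParameters(), p)
        p.write_text(p.read_text() + "frobnicate=1\n")
        with pytest.raises(ValueError, match="frobnicate"):
            load_parameters(p)

    def test_version_mismatch_rejected(self, tmp_path):
        p = tmp_path / "params.txt"
        save_parameters(FilterParameters(), p)
        p.write_text(p.read_text().replace("schema_version=1", "schema_version=99"))
        with pytest.raises(ValueError, match="schema_version"):
            load_parameters(p)

    def test_step_counts_recorded_as_audit_comments(self, tmp_path):
        p = tmp_path / "params.txt"
        save_parameters(FilterParameters(), p, step_counts=[("region", 94, 66)])
        assert "# step region: 94 -> 66" in p.read_text()


def test_gene_panel_reader_uppercases(tmp_path):
    p = tmp_path / "panel.txt"
    p.write_text("# ciliopathy panel\ndnai1\nDNAH5\n\n")
    assert read_gene_panel(p) == frozenset({"DNAI1", "DNAH5"})
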
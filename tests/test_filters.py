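"""Filter cascade semantics: boundaries, inheritance logic, audit report."""

import random

import pytest

from exomesift.core import ConsequenceClass, GenomicInterval, Zygosity
from exomesift.filters import (
    DEFAULT_STEP_ORDER,
    filter_consequence,
    filter_frequency,
    filter_inheritance,
    filter_protein_altering,
    filter_quality,
    filter_regions,
    run_cascade,
)
from exomesift.readwrite import DEFAULT_CONSEQUENCE_KEEP, FilterParameters
from tests.conftest import make_variant

CC = ConsequenceClass
Z = Zygosity


class TestQuality:
    def test_strict_boundary(self):
        kept = filter_quality([make_variant(quality=49.9)], 50, 0)
        assert kept == []
        assert filter_quality([make_variant(quality=50.0)], 50, 0)

    def test_zero_thresholds_are_identity(self):
        vs = [make_variant(quality=0.0, depth=0, alt_depth=0)]
        assert filter_quality(vs, 0, 0) == vs

    def test_matches_independent_row_scan(self):
        rng = random.Random(7)
        vs = [
            make_variant(
                pos=i, quality=rng.uniform(0, 100), depth=rng.randrange(0, 60),
                alt_depth=0,
            )
            for i in range(1, 11)
        ]
        kept = filter_quality(vs, 40, 20)
        oracle = [v for v in vs if v.quality >= 40 and v.depth >= 20]
        assert kept == oracle


class TestRegions:
    def test_panel_membership_case_insensitive(self):
        vs = [make_variant(gene="dnai1"), make_variant(pos=2, gene="TTN")]
        kept = filter_regions(vs, gene_panel={"DNAI1"})
        assert [v.gene for v in kept] == ["dnai1"]

    def test_union_of_regions_and_panel(self):
        a = make_variant(chrom="chr5", pos=150, gene="OTHER")
        b = make_variant(pos=999999, gene="DNAI1")
        c = make_variant(chrom="chr9", pos=5, gene="NOPE")
        region = GenomicInterval("chr5", 100, 200)
        both = filter_regions([a, b, c], regions=[region], gene_panel={"DNAI1"})
        only_r = filter_regions([a, b, c], regions=[region])
        only_p = filter_regions([a, b, c], gene_panel={"DNAI1"})
        assert {v.key for v in both} == {v.key for v in only_r} | {
            v.key for v in only_p
        }

    def test_empty_criteria_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            filter_regions([make_variant()])


class TestConsequenceWindow:
    @pytest.mark.parametrize("distance,kept", [(-10, True), (10, True), (-11, False), (11, False)])
    def test_splice_window_boundary_inclusive(self, distance, kept):
        v = make_variant(consequence=CC.INTRONIC, splice_distance=distance)
        out = filter_consequence([v], DEFAULT_CONSEQUENCE_KEEP, 10)
        assert bool(out) is kept

    def test_window_zero_rescues_only_exonic(self):
        intronic = make_variant(consequence=CC.INTRONIC, splice_distance=-1)
        exonic = make_variant(pos=2, consequence=CC.MISSENSE, splice_distance=0)
        out = filter_consequence([intronic, exonic], DEFAULT_CONSEQUENCE_KEEP, 0)
        assert out == [exonic]

    def test_unknown_distance_not_rescued(self):
        v = make_variant(consequence=CC.INTERGENIC, splice_distance=None)
        assert filter_consequence([v], DEFAULT_CONSEQUENCE_KEEP, 10) == []


class TestFrequency:
    @pytest.mark.parametrize(
        "maf,kept", [(0.10, False), (0.0999, True), (None, True), (0.5, False)]
    )
    def test_boundary_and_missing(self, maf, kept):
        assert bool(filter_frequency([make_variant(maf=maf)], 0.10)) is kept


class TestProteinAltering:
    def test_synonymous_dropped_others_kept(self):
        vs = [
            make_variant(pos=1, consequence=CC.SYNONYMOUS),
            make_variant(pos=2, consequence=CC.MISSENSE),
            make_variant(pos=3, consequence=CC.FRAMESHIFT),
            make_variant(pos=4, consequence=CC.INTRONIC),
        ]
        assert [v.pos for v in filter_protein_altering(vs)] == [2, 3, 4]


class TestInheritance:
    def test_single_het_cannot_be_biallelic(self):
        v = make_variant(zygosity=Z.HETEROZYGOUS)
        assert filter_inheritance([v], "recessive_compound_het") == []

    def test_two_hets_in_gene_possibly_compound(self):
        vs = [
            make_variant(pos=1, zygosity=Z.HETEROZYGOUS),
            make_variant(pos=2, zygosity=Z.HETEROZYGOUS),
        ]
        assert filter_inheritance(vs, "recessive_compound_het") == vs

    def test_homozygous_survives_consanguineous(self):
        v = make_variant(zygosity=Z.HOMOZYGOUS)
        assert filter_inheritance([v], "recessive_consanguineous") == [v]

    def test_unknown_zygosity_dropped_in_active_modes(self):
        v = make_variant(zygosity=Z.UNKNOWN)
        for mode in ("dominant", "recessive_consanguineous", "recessive_compound_het"):
            assert filter_inheritance([v], mode) == []
        assert filter_inheritance([v], "none") == [v]

    def test_matches_group_by_gene_oracle_on_random_table(self):
        rng = random.Random(11)
        genes = [f"G{i}" for i in range(8)]
        vs = [
            make_variant(
                pos=i,
                gene=rng.choice(genes),
                zygosity=rng.choice([Z.HETEROZYGOUS, Z.HOMOZYGOUS, Z.UNKNOWN]),
            )
            for i in range(1, 51)
        ]
        got = {v.key for v in filter_inheritance(vs, "recessive_compound_het")}
        # independent brute-force grouping
        het_count = {}
        for v in vs:
            if v.zygosity is Z.HETEROZYGOUS:
                het_count[v.gene] = het_count.get(v.gene, 0) + 1
        oracle = {
            v.key
            for v in vs
            if v.zygosity is Z.HOMOZYGOUS
            or (v.zygosity is Z.HETEROZYGOUS and het_count[v.gene] >= 2)
        }
        assert got == oracle

    def test_compound_het_is_superset_of_consanguineous(self):
        rng = random.Random(3)
        vs = [
            make_variant(
                pos=i,
                gene=rng.choice(["A", "B"]),
                zygosity=rng.choice([Z.HETEROZYGOUS, Z.HOMOZYGOUS]),
            )
            for i in range(1, 30)
        ]
        wide = {v.key for v in filter_inheritance(vs, "recessive_compound_het")}
        narrow = {v.key for v in filter_inheritance(vs, "recessive_consanguineous")}
        assert narrow <= wide


def _mixed_cohort(n=200, seed=5):
    rng = random.Random(seed)
    vs = []
    for i in range(1, n + 1):
        vs.append(
            make_variant(
                pos=i,
                gene=rng.choice(["DNAI1", "DNAH5", "TTN", "OTHER"]),
                consequence=rng.choice(list(CC)),
                splice_distance=rng.choice([0, -5, 15, -200, None]),
                maf=rng.choice([None, 0.001, 0.05, 0.2]),
                zygosity=rng.choice([Z.HETEROZYGOUS, Z.HOMOZYGOUS]),
                quality=rng.uniform(0, 1000),
                depth=rng.randrange(0, 200),
                alt_depth=0,
            )
        )
    return vs


class TestCascade:
    params = FilterParameters(
        min_quality=100,
        min_depth=10,
        gene_panel=frozenset({"DNAI1", "DNAH5"}),
        inheritance_mode="recessive_compound_het",
    )

    def test_every_step_output_is_subset_of_input(self):
        vs = _mixed_cohort()
        report = run_cascade(vs, self.params)
        ids = {id(v) for v in vs}
        current = set(ids)
        # survivors are the original objects, never copies
        assert all(id(v) in ids for v in report.survivors)
        for step in report.steps:
            assert step.variants_out <= step.variants_in

    def test_counts_chain_and_are_monotone(self):
        report = run_cascade(_mixed_cohort(), self.params)
        for a, b in zip(report.steps, report.steps[1:]):
            assert b.variants_in == a.variants_out
        counts = [report.steps[0].variants_in] + [
            s.variants_out for s in report.steps
        ]
        assert counts == sorted(counts, reverse=True)

    def test_survivors_invariant_to_row_order(self):
        vs = _mixed_cohort()
        shuffled = vs[::-1]
        a = {v.key for v in run_cascade(vs, self.params).survivors}
        b = {v.key for v in run_cascade(shuffled, self.params).survivors}
        assert a == b

    def test_identity_parameters_keep_everything(self):
        vs = _mixed_cohort()
        report = run_cascade(vs, FilterParameters())
        # no region/inheritance configured; quality thresholds 0; but the
        # consequence and frequency steps still apply their defaults
        for step in report.steps:
            assert step.name in ("quality", "consequence", "frequency", "protein_altering")

    def test_empty_input_reports_zero_at_every_step(self):
        report = run_cascade([], self.params)
        assert all((s.variants_in, s.variants_out) == (0, 0) for s in report.steps)
        assert report.survivors == []

    def test_unknown_step_name_rejected(self):
        with pytest.raises(ValueError, match="unknown cascade step"):
            run_cascade([], self.params, step_order=("quality", "wibble"))

    def test_report_write(self, tmp_path):
        report = run_cascade(_mixed_cohort(), self.params)
        rp = tmp_path / "report.tsv"
        sp = tmp_path / "survivors.tsv"
        report.write(rp, sp)
        lines = rp.read_text().splitlines()
        assert lines[0].startswith("step\t")
        assert len(lines) == len(report.steps) + 1

    def test_default_step_order_matches_report_shape(self):
        report = run_cascade(_mixed_cohort(), self.params)
        assert [s.name for s in report.steps] == list(DEFAULT_STEP_ORDER)
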
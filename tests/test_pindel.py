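"""Pindel-style block parsing, event filtering, naming and rendering."""

import dataclasses

import pytest

from exomesift.core import GenomicInterval, TranscriptModel
from exomesift.pindel import (
    PindelEvent,
    PindelParseError,
    duplicate_groups,
    filter_events,
    name_event,
    read_pindel_dir,
    read_pindel_file,
    render_alignment,
    write_pindel_file,
)
from exomesift.synth import make_pindel_events


def _strip_source(ev):
    d = dataclasses.asdict(ev)
    d["source_file"] = ""
    return d


class TestBlockFormat:
    def test_directory_read_recovers_all_generated_events(self, tmp_path):
        events = make_pindel_events(100, seed=5)
        dels = [e for e in events if e.event_type == "D"]
        others = [e for e in events if e.event_type != "D"]
        write_pindel_file(dels, tmp_path / "sample_D")
        write_pindel_file(others, tmp_path / "sample_SI")
        back = read_pindel_dir(tmp_path)
        assert len(back) == len(events)
        assert all(e.event_type == "D" for e in read_pindel_file(tmp_path / "sample_D"))

    def test_round_trip_preserves_every_field(self, tmp_path):
        events = make_pindel_events(40, seed=9)
        p = tmp_path / "x_D"
        write_pindel_file(events, p)
        back = read_pindel_file(p)
        assert [_strip_source(e) for e in back] == [_strip_source(e) for e in events]

    def test_round_trip_is_byte_stable(self, tmp_path):
        events = make_pindel_events(40, seed=9)
        p1, p2 = tmp_path / "a_D", tmp_path / "b_D"
        write_pindel_file(events, p1)
        write_pindel_file(read_pindel_file(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_inserted_sequence_parsed(self, tmp_path):
        ev = PindelEvent(
            index=0, event_type="I", event_length=3, inserted_nt="ACG",
            chrom="chr17", bp_start=100, bp_end=101, supporting_reads=5,
            unique_supporting_reads=5,
        )
        p = tmp_path / "x_SI"
        write_pindel_file([ev], p)
        back = read_pindel_file(p)[0]
        assert back.inserted_nt == "ACG"
        assert back.event_length == 3

    def test_malformed_header_reports_file_and_line(self, tmp_path):
        p = tmp_path / "bad_D"
        p.write_text("#" * 100 + "\n0\tD notanint\tChrID chr1\n")
        with pytest.raises(PindelParseError, match="bad_D.*:2"):
            read_pindel_file(p)

    def test_empty_directory_yields_no_events(self, tmp_path):
        assert read_pindel_dir(tmp_path) == []

    def test_deletion_length_breakpoint_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PindelEvent(
                index=0, event_type="D", event_length=10, inserted_nt="",
                chrom="chr1", bp_start=100, bp_end=105, supporting_reads=1,
                unique_supporting_reads=1,
            )


def _event(supports=10, bp_start=1000, length=50, chrom="chr17"):
    return PindelEvent(
        index=0, event_type="D", event_length=length, inserted_nt="",
        chrom=chrom, bp_start=bp_start, bp_end=bp_start + length + 1,
        supporting_reads=supports, unique_supporting_reads=supports,
    )


class TestFilterEvents:
    def test_support_boundary(self):
        assert filter_events([_event(supports=199)], 200) == []
        assert filter_events([_event(supports=200)], 200)

    def test_one_breakpoint_in_target_is_enough(self):
        # a large deletion is captured as long as one end is in the pull-down
        ev = _event(bp_start=1000, length=510)
        target = [GenomicInterval("chr17", 900, 1010)]
        assert filter_events([ev], 0, target) == [ev]
        assert filter_events([ev], 0, target, require_both_ends=True) == []

    def test_no_criteria_is_identity(self):
        evs = [_event(), _event(supports=1)]
        assert filter_events(evs, 0) == evs

    def test_monotone_in_threshold(self):
        evs = [_event(supports=s) for s in (5, 50, 500)]
        lo = {id(e) for e in filter_events(evs, 10)}
        hi = {id(e) for e in filter_events(evs, 100)}
        assert hi <= lo

    def test_duplicates_marked_not_dropped(self):
        a, b = _event(), _event()
        groups = duplicate_groups([a, b, _event(bp_start=99)])
        assert sorted(len(g) for g in groups.values()) == [1, 2]


@pytest.fixture
def transcript():
    # 23 exons of 100 bp separated by 400 bp introns, plus strand
    exons = [
        GenomicInterval("chr17", 1000 + i * 500, 1099 + i * 500, f"exon{i + 1}")
        for i in range(23)
    ]
    return TranscriptModel("BRCA1", "NM_007294.3", "chr17", "+", exons)


class TestNameEvent:
    def test_deletion_of_one_exon_names_it(self, transcript):
        # exon 22 spans 11500-11599; delete it plus flanking intron bases
        ev = _event(bp_start=11400, length=510)  # deletes 11401..11910
        desc = name_event(ev, transcript)
        assert "510 bp deletion" in desc
        assert "exon 22" in desc
        assert "flanking intronic" in desc

    def test_fully_intronic_deletion_names_intron(self, transcript):
        ev = _event(bp_start=1150, length=50)  # inside intron 1 (1100-1499)
        assert "intron 1" in name_event(ev, transcript)

    def test_multi_exon_deletion_names_range(self, transcript):
        ev = _event(bp_start=990, length=1200)  # removes exons 1-3 region
        assert "exons 1–3" in name_event(ev, transcript)

    def test_minus_strand_numbering(self):
        exons = [
            GenomicInterval("chr2", 1000 + i * 500, 1099 + i * 500) for i in range(3)
        ]
        tm = TranscriptModel("G", "NM_1.1", "chr2", "-", exons)
        ev = _event(bp_start=990, length=120, chrom="chr2")  # genomic exon 1
        assert "exon 3" in name_event(ev, tm)

    def test_chromosome_mismatch_is_an_error(self, transcript):
        with pytest.raises(ValueError, match="chr1.*chr17"):
            name_event(_event(chrom="chr1"), transcript)


class TestRenderAlignment:
    def test_read_shows_gap_across_deletion(self):
        ev = PindelEvent(
            index=0, event_type="D", event_length=3, inserted_nt="",
            chrom="chr1", bp_start=105, bp_end=109, supporting_reads=1,
            unique_supporting_reads=1,
            sample_reads=[("AAAATTTT", 102, "+")],
        )
        block = render_alignment(ev, 100, "G" * 20)
        read_line = block.splitlines()[2]
        assert "AAAA---TTTT" in read_line

    def test_all_lines_same_width(self):
        ev = PindelEvent(
            index=0, event_type="D", event_length=5, inserted_nt="",
            chrom="chr1", bp_start=110, bp_end=116, supporting_reads=2,
            unique_supporting_reads=2,
            sample_reads=[("ACGTACGTACGT", 95, "+"), ("ACGT", 130, "-")],
        )
        lines = render_alignment(ev, 100, "G" * 25).splitlines()
        assert len({len(l) for l in lines}) == 1
        assert lines[2][0] == "<"  # clipped at the left edge
        assert lines[3][-1] == ">"  # clipped at the right edge

    def test_zero_supporting_reads_renders_reference_only(self):
        ev = _event(bp_start=105, length=3)
        ev = dataclasses.replace(ev, bp_end=109, event_length=3)
        lines = render_alignment(ev, 100, "G" * 20).splitlines()
        assert len(lines) == 2  # reference + event marker

    def test_window_must_cover_breakpoints(self):
        ev = _event(bp_start=105, length=50)
        with pytest.raises(ValueError, match="cover"):
            render_alignment(ev, 100, "G" * 20)
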
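"""Domain-type invariants and lossless round trips of the on-disk formats."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qhmap.core import Call, GenomeRegions, GenotypeTrack, Segment, SegmentKind, SnpMarker
from qhmap.io import ParseError, read_calls, read_regions, write_calls, write_regions

from conftest import make_track


class TestTypeInvariants:
    def test_marker_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            SnpMarker("rs1", 23, 100, 1.0)
        with pytest.raises(ValueError):
            SnpMarker("rs1", 1, 0, 1.0)
        with pytest.raises(ValueError):
            SnpMarker("rs1", 1, 100, -0.5)

    def test_track_requires_sorted_unique_bp(self):
        with pytest.raises(ValueError):
            make_track([Call.HOM_A, Call.HET], [0.0, 1.0], pos_bp=[10, 10])
        with pytest.raises(ValueError):
            make_track([Call.HOM_A, Call.HET], [1.0, 0.5], pos_bp=[10, 20])

    def test_segment_needs_positive_bp_extent(self):
        with pytest.raises(ValueError):
            Segment(chrom=1, start_cm=0.0, end_cm=1.0, start_bp=100, end_bp=100)
        seg = Segment(chrom=1, start_cm=1.0, end_cm=3.5, start_bp=100, end_bp=200)
        assert seg.genetic_length_cm == pytest.approx(2.5)

    def test_genome_regions_rejects_overlap(self):
        a = Segment(1, 0.0, 2.0, 0, 200, kind=SegmentKind.RHS)
        b = Segment(1, 1.0, 3.0, 100, 300, kind=SegmentKind.RHS)
        with pytest.raises(ValueError):
            GenomeRegions("s", [a, b], total_autosome_cm=100.0)

    def test_track_zygosity_counts_skip_no_calls(self):
        t = make_track(
            [Call.HOM_A, Call.NO_CALL, Call.HET, Call.HOM_B], [0, 1, 2, 3]
        )
        assert (t.n_called, t.n_het, t.n_hom) == (3, 1, 2)


class TestCallsIO:
    def test_native_round_trip(self, tmp_path):
        t = make_track(
            [Call.HET, Call.HOM_A, Call.HOM_B, Call.NO_CALL, Call.HOM_A],
            [0.0, 0.5, 1.0, 1.5, 2.0],
            chrom=22,
        )
        path = tmp_path / "sample1.tsv"
        write_calls([t], path)
        tracks = read_calls(path)
        assert len(tracks) == 1
        back = tracks[0]
        assert back.sample_id == "sample1"
        assert back.chrom == 22 and len(back) == 5
        np.testing.assert_array_equal(back.calls, t.calls)
        np.testing.assert_array_equal(back.pos_bp, t.pos_bp)
        np.testing.assert_allclose(back.pos_cm, t.pos_cm)
        # byte-level idempotence: write(read(x)) == x
        path2 = tmp_path / "again.tsv"
        write_calls(tracks, path2)
        assert path.read_text() == path2.read_text()

    def test_non_autosomal_rows_dropped(self, tmp_path):
        path = tmp_path / "mix.tsv"
        path.write_text(
            "snp_id\tchrom\tpos_bp\tpos_cm\tcall\n"
            "rs1\t1\t100\t0.1\tAA\n"
            "rs2\tX\t200\t0.2\tAB\n"
            "rs3\tchr2\t300\t0.3\tBB\n"
        )
        tracks = read_calls(path)
        assert sorted(t.chrom for t in tracks) == [1, 2]
        assert sum(len(t) for t in tracks) == 2

    def test_invalid_call_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tchrom\tpos_bp\tpos_cm\tcall\n"
            "rs1\t1\t100\t0.1\tAA\n"
            "rs2\t1\t200\t0.2\tZZ\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_calls(path)

    def test_duplicate_bp_rejected_and_unsorted_sorted(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "snp_id\tchrom\tpos_bp\tpos_cm\tcall\n"
            "rs1\t1\t100\t0.1\tAA\nrs2\t1\t100\t0.1\tBB\n"
        )
        with pytest.raises(ParseError, match="duplicate"):
            read_calls(path)
        path2 = tmp_path / "unsorted.tsv"
        path2.write_text(
            "snp_id\tchrom\tpos_bp\tpos_cm\tcall\n"
            "rs2\t1\t200\t0.2\tBB\nrs1\t1\t100\t0.1\tAA\n"
        )
        (track,) = read_calls(path2)
        assert list(track.pos_bp) == [100, 200]

    def test_plink_like(self, tmp_path):
        (tmp_path / "p1.map").write_text("1 rs1 0.1 100\n1 rs2 0.2 200\nX rsx 0.0 5\n")
        calls = tmp_path / "p1.calls"
        calls.write_text("AA\nAB\nNC\n")
        (track,) = read_calls(calls, format="plink-like")
        assert track.sample_id == "p1" and len(track) == 2
        assert list(track.calls) == [Call.HOM_A, Call.HET]


class TestRegionsIO:
    def test_bed_coordinates_zero_based_half_open(self, tmp_path):
        seg = Segment(1, 0.5, 1.5, 100, 200, n_snps=3, kind=SegmentKind.RHS)
        regions = GenomeRegions("s1", [seg], total_autosome_cm=100.0)
        path = tmp_path / "r.bed"
        write_regions(regions, path)
        data_lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert data_lines[0].startswith("1\t100\t200\t")

    def test_empty_region_set(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_regions(GenomeRegions("s1", [], total_autosome_cm=50.0), path)
        back = read_regions(path)
        assert back.segments == [] and back.total_autosome_cm == pytest.approx(50.0)

    def test_round_trip_preserves_fields(self, tmp_path):
        segs = [
            Segment(2, 0.25, 3.75, 10, 999, n_snps=42, kind=SegmentKind.RHS),
            Segment(5, 10.0, 11.0, 5000, 6000, n_snps=7, kind=SegmentKind.OVERLAP),
        ]
        regions = GenomeRegions("patientA", segs, total_autosome_cm=3454.7)
        path = tmp_path / "r.bed"
        write_regions(regions, path)
        back = read_regions(path)
        assert back.sample_id == "patientA"
        for orig, rt in zip(regions.segments, back.segments):
            assert (orig.chrom, orig.start_bp, orig.end_bp, orig.n_snps, orig.kind) == (
                rt.chrom, rt.start_bp, rt.end_bp, rt.n_snps, rt.kind
            )
            assert rt.start_cm == pytest.approx(orig.start_cm, abs=1e-6)
            assert rt.end_cm == pytest.approx(orig.end_cm, abs=1e-6)


@given(
    data=st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=3),  # chrom
            st.sampled_from(["AA", "AB", "BB", "NC"]),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_fuzzed_tables_round_trip(tmp_path_factory, data):
    """Any well-formed call table survives write/read unchanged."""
    tmp = tmp_path_factory.mktemp("fuzz")
    lines = ["snp_id\tchrom\tpos_bp\tpos_cm\tcall"]
    per_chrom_count: dict[int, int] = {}
    for chrom, call in data:
        i = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = i + 1
        lines.append(f"rs{chrom}_{i}\t{chrom}\t{100 + i * 10}\t{i * 0.1:.4f}\t{call}")
    path = tmp / "fuzz.tsv"
    path.write_text("\n".join(lines) + "\n")
    tracks = read_calls(path)
    out = tmp / "fuzz_out.tsv"
    write_calls(tracks, out)
    tracks2 = read_calls(out)
    assert len(tracks) == len(tracks2)
    for a, b in zip(tracks, tracks2):
        np.testing.assert_array_equal(a.calls, b.calls)
        np.testing.assert_array_equal(a.pos_bp, b.pos_bp)
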
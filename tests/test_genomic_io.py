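"""Catalog parsing, interval arithmetic, coverage and alignment I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strinit import genomic_io as gio
from strinit.genomic_io import (
    MINUS,
    PLUS,
    AlignmentRecord,
    GenomicInterval,
    ParseError,
    SequenceStore,
    StrRecord,
    reverse_complement,
)


# ---------------------------------------------------------------------------
# STR catalog
# ---------------------------------------------------------------------------

class TestStrCatalog:
    def test_worked_example_line(self, tmp_path):
        p = tmp_path / "cat.bed"
        p.write_text("chr1 10001 10468 6 78 Human_STR_1 AACCCT\n")
        (rec,) = gio.read_str_catalog(p)
        assert rec.interval.chrom == "chr1"
        assert (rec.interval.start, rec.interval.end) == (10001, 10468)
        assert rec.period == 6
        assert rec.repeat_count == 78
        assert rec.name == "Human_STR_1"
        assert rec.motif == "AACCCT"
        assert rec.str_class == "AACCCT"  # no canonicalization

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert gio.read_str_catalog(p) == []

    def test_round_trip_random_catalog(self, tmp_path):
        rng = np.random.default_rng(0)
        motifs = ["A", "AC", "AGG", "AGAT", "AACCCT"]
        records = []
        for i in range(100):
            motif = motifs[rng.integers(len(motifs))]
            start = int(rng.integers(0, 10_000))
            rc = int(rng.integers(3, 40))
            records.append(
                StrRecord(
                    GenomicInterval(f"chr{rng.integers(1, 4)}", start,
                                    start + len(motif) * rc, name=f"S{i}"),
                    period=len(motif), repeat_count=float(rc), motif=motif,
                )
            )
        p = tmp_path / "rt.bed"
        gio.write_str_catalog(records, p)
        back = gio.read_str_catalog(p)
        assert len(back) == 100
        for a, b in zip(records, back):
            assert (a.interval.chrom, a.interval.start, a.interval.end) == (
                b.interval.chrom, b.interval.start, b.interval.end)
            assert (a.period, a.repeat_count, a.name, a.motif) == (
                b.period, b.repeat_count, b.name, b.motif)

    @pytest.mark.parametrize(
        "line",
        [
            "chr1 10 20 2 5 name",  # wrong column count
            "chr1 x 20 2 5 name AC",  # non-numeric coordinate
            "chr1 10 20 2 5 name AX",  # non-ACGT motif
        ],
    )
    def test_parse_errors_name_the_line(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1 0 10 2 5 ok AC\n" + line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            gio.read_str_catalog(p)


# ---------------------------------------------------------------------------
# window_overlap
# ---------------------------------------------------------------------------

def _brute_overlap(a, b, w, same_strand=False):
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            if same_strand and x.strand != y.strand:
                continue
            if x.start - w < y.end and y.start < x.end + w:
                out.append((i, j))
    return sorted(out)


class TestWindowOverlap:
    def test_extension_reaches(self):
        a = [GenomicInterval("c", 100, 110)]
        b = [GenomicInterval("c", 114, 115)]
        assert gio.window_overlap(a, b, w=5) == [(0, 0)]

    def test_half_open_touch_is_no_overlap(self):
        a = [GenomicInterval("c", 100, 110)]
        b = [GenomicInterval("c", 115, 116)]
        assert gio.window_overlap(a, b, w=5) == []

    def test_self_identity(self):
        a = [GenomicInterval("c", i * 10, i * 10 + 5) for i in range(1, 6)]
        pairs = gio.window_overlap(a, a, w=0)
        assert set(pairs) >= {(i, i) for i in range(5)}

    def test_negative_w_rejected(self):
        with pytest.raises(ValueError):
            gio.window_overlap([], [], w=-1)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n, m = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            w = int(rng.integers(0, 8))
            def mk(k):
                out = []
                for _ in range(k):
                    s = int(rng.integers(0, 300))
                    out.append(GenomicInterval(f"c{rng.integers(1, 3)}", s,
                                               s + int(rng.integers(1, 20))))
                return out
            a, b = mk(n), mk(m)
            assert gio.window_overlap(a, b, w=w) == _brute_overlap(a, b, w)


# ---------------------------------------------------------------------------
# shuffle_intervals
# ---------------------------------------------------------------------------

class TestShuffle:
    def test_forced_placement(self):
        iv = [GenomicInterval("c", 5, 15)]
        out = gio.shuffle_intervals(iv, {"c": 10}, seed=0)
        assert (out[0].start, out[0].end) == (0, 10)

    def test_lengths_preserved_and_exclusions_respected(self):
        rng = np.random.default_rng(3)
        ivs = []
        for _ in range(1000):
            s = int(rng.integers(0, 5000))
            ivs.append(GenomicInterval("c1", s, s + int(rng.integers(1, 30))))
        excl = [GenomicInterval("c1", i * 500, i * 500 + 200) for i in range(10)]
        out = gio.shuffle_intervals(ivs, {"c1": 6000, "c2": 6000}, excluded=excl,
                                    seed=5)
        assert sorted(iv.length for iv in out) == sorted(iv.length for iv in ivs)
        # brute-force exclusion check
        for o in out:
            for e in excl:
                if o.chrom == e.chrom:
                    assert not (o.start < e.end and e.start < o.end)

    def test_deterministic_given_seed(self):
        ivs = [GenomicInterval("c", i, i + 10) for i in range(0, 100, 10)]
        a = gio.shuffle_intervals(ivs, {"c": 1000}, seed=9)
        b = gio.shuffle_intervals(ivs, {"c": 1000}, seed=9)
        assert [(x.chrom, x.start, x.end) for x in a] == [
            (x.chrom, x.start, x.end) for x in b]

    def test_impossible_placement_raises(self):
        iv = [GenomicInterval("c", 0, 10)]
        with pytest.raises(gio.PlacementError):
            gio.shuffle_intervals(iv, {"c": 10},
                                  excluded=[GenomicInterval("c", 0, 10)], seed=0)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

class TestCoverage:
    def test_expansion(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t5\t8\t2.0\n")
        track = gio.read_coverage(p, PLUS)
        assert [track.value_at("chr1", PLUS, i) for i in (4, 5, 6, 7, 8)] == \
            [0.0, 2.0, 2.0, 2.0, 0.0]

    def test_empty_file_is_zero_track(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("")
        assert gio.read_coverage(p, PLUS).total_mass() == 0.0

    def test_overlapping_records_rejected(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t5\t8\t2.0\nchr1\t7\t9\t1.0\n")
        with pytest.raises(ParseError, match="overlap"):
            gio.read_coverage(p, PLUS)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t5\t8\t-2.0\n")
        with pytest.raises(ParseError):
            gio.read_coverage(p, PLUS)

    def test_mass_conservation_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        track = gio.CoverageTrack()
        mass = 0.0
        pos = 0
        for _ in range(50):
            pos += int(rng.integers(1, 30))
            width = int(rng.integers(1, 5))
            val = float(rng.integers(1, 10))
            track.add("chr1", PLUS, pos, pos + width, val)
            mass += val * width
            pos += width
        assert track.total_mass() == pytest.approx(mass)
        p = tmp_path / "rt.bg"
        gio.write_coverage(track, p, PLUS)
        back = gio.read_coverage(p, PLUS)
        assert back.total_mass() == pytest.approx(mass)
        arr_a = track.array("chr1", PLUS, pos + 10)
        arr_b = back.array("chr1", PLUS, pos + 10)
        np.testing.assert_allclose(arr_a, arr_b)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

class TestSequences:
    def test_forward_and_reverse_slices(self):
        store = SequenceStore({"c": "ACGT"})
        iv = GenomicInterval("c", 0, 4)
        assert gio.extract_sequence(store, iv, PLUS) == "ACGT"
        assert gio.extract_sequence(store, iv, MINUS) == "ACGT"  # palindrome

    def test_out_of_bounds_raises(self):
        store = SequenceStore({"c": "ACGT"})
        with pytest.raises(IndexError):
            store.get("c", 2, 6)

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
    def test_revcomp_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_revcomp_preserves_base_pairing(self, s):
        rc = reverse_complement(s)
        assert len(rc) == len(s)
        assert all(a + b in ("AT", "TA", "CG", "GC")
                   for a, b in zip(s, rc[::-1]))

    def test_fasta_round_trip(self, toy_store, tmp_path):
        p = tmp_path / "g.fa"
        toy_store.to_fasta(p)
        back = SequenceStore.from_fasta(p)
        assert back.get("chrT", 0, 4000) == toy_store.get("chrT", 0, 4000)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _write_sam(path, rows, chrom_sizes={"chr1": 100000}):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for c, s in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{s}\n")
        for r in rows:
            fh.write(r + "\n")


class TestAlignments:
    def test_flag0_position_convention(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, ["r1\t0\tchr1\t1001\t60\t4M\t*\t0\t0\tACGT\tIIII\tMD:Z:4"])
        records, counters = gio.read_alignments(p)
        (rec,) = records
        # 1-based SAM pos 1001 -> 0-based 1000; 5' end interval [1000, 1001)
        assert rec.pos == 1000
        assert rec.strand == PLUS
        assert rec.five_prime_pos == 1000

    def test_flag16_is_minus_strand_with_rightmost_5prime(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, ["r1\t16\tchr1\t1001\t60\t4M\t*\t0\t0\tACGT\tIIII\tMD:Z:4"])
        records, _ = gio.read_alignments(p)
        assert records[0].strand == MINUS
        assert records[0].five_prime_pos == 1003

    def test_mixed_file_counts_match_hand_tally(self, tmp_path):
        rows = []
        # 4 plus, 3 minus, 2 other flags, 1 bad MD
        for i in range(4):
            rows.append(f"p{i}\t0\tchr1\t{100+i}\t60\t3M\t*\t0\t0\tACG\tIII\tMD:Z:3")
        for i in range(3):
            rows.append(f"m{i}\t16\tchr1\t{200+i}\t60\t3M\t*\t0\t0\tACG\tIII\tMD:Z:3")
        rows.append("s0\t4\t*\t0\t0\t*\t*\t0\t0\tACG\tIII")
        rows.append("s1\t256\tchr1\t300\t60\t3M\t*\t0\t0\tACG\tIII\tMD:Z:3")
        rows.append("b0\t0\tchr1\t400\t60\t3M\t*\t0\t0\tACG\tIII\tMD:Z:xx")
        p = tmp_path / "mix.sam"
        _write_sam(p, rows)
        records, counters = gio.read_alignments(p)
        assert counters["plus"] == 4
        assert counters["minus"] == 3
        assert counters["skipped_flag"] == 2
        assert counters["bad_md"] == 1
        assert len(records) == 7

    def test_write_read_round_trip(self, tmp_path):
        recs = [
            AlignmentRecord("chr1", 50, PLUS, "ACGTA", "0G4"),
            AlignmentRecord("chr1", 80, MINUS, "TTTTT", "4A0"),
        ]
        p = tmp_path / "rt.sam"
        gio.write_alignments(recs, p, {"chr1": 1000})
        back, _ = gio.read_alignments(p)
        assert [(r.chrom, r.pos, r.strand, r.seq, r.md) for r in back] == [
            (r.chrom, r.pos, r.strand, r.seq, r.md) for r in recs]
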
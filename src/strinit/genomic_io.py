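"""Readers, writers and interval arithmetic for the genomic dialects the pipeline touches.

Coordinate convention
---------------------
All intervals are stored BED-style: 0-based, half-open ``[start, end)``.
Human-facing 3'-end coordinates are reported 1-based (the last transcribed
base of an STR is ``end`` on the (+) strand and ``start + 1`` on the (−)
strand); the conversion happens only at that boundary, never internally.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from . import __version__

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."
_STRANDS = (PLUS, MINUS, UNSTRANDED)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# MD descriptor: alternating match lengths and substituted reference bases,
# with ^-prefixed runs for deletions (which we only need to recognise, not use).
_MD_RE = re.compile(r"^\d+(?:(?:[ACGTN]|\^[ACGTN]+)\d+)*$")


class ParseError(ValueError):
    """Malformed record in one of the supported dialects."""


class PlacementError(RuntimeError):
    """shuffle_intervals could not place an interval outside the exclusions."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StrRecord:
    """One catalog STR (HipSTR BED dialect: chrom start end period count name motif)."""

    interval: GenomicInterval
    period: int
    repeat_count: float
    motif: str

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be non-empty uppercase ACGT, got {self.motif!r}")
        if self.period != len(self.motif):
            raise ValueError(
                f"period {self.period} != motif length {len(self.motif)} ({self.motif})"
            )

    @property
    def name(self) -> Optional[str]:
        return self.interval.name

    @property
    def str_class(self) -> str:
        # The catalog is already (+)-strand normalized; the class key is the
        # motif as printed, with no further canonicalization.
        return self.motif


@dataclass
class AlignmentRecord:
    """Minimal alignment: mapped tag with an MD-style mismatch descriptor."""

    chrom: str
    pos: int  # 0-based leftmost mapped position
    strand: str
    seq: str  # as stored (reference-strand orientation)
    md: str
    mapq: int = 60

    @property
    def five_prime_pos(self) -> int:
        """0-based genomic position of the tag's 5'-most aligned base."""
        if self.strand == PLUS:
            return self.pos
        return self.pos + len(self.seq) - 1


class SequenceStore:
    """In-memory chrom -> uppercase ACGTN sequence, with stranded slicing."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def get(self, chrom: str, start: int, end: int, strand: str = PLUS) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise IndexError(
                f"slice [{start}, {end}) out of bounds for {chrom} (length {len(seq)})"
            )
        out = seq[start:end]
        return reverse_complement(out) if strand == MINUS else out

    def with_substitution(self, chrom: str, pos: int, base: str) -> "SequenceStore":
        """Copy of the store with one (+)-strand base replaced (0-based pos)."""
        seq = self._seqs[chrom]
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} out of bounds for {chrom}")
        new = dict(self._seqs)
        new[chrom] = seq[:pos] + base + seq[pos + 1 :]
        return SequenceStore(new)


def extract_sequence(store: SequenceStore, interval: GenomicInterval, strand: str = PLUS) -> str:
    """Forward slice for +, reverse complement for −."""
    return store.get(interval.chrom, interval.start, interval.end, strand)


# ---------------------------------------------------------------------------
# STR catalog (HipSTR BED dialect)
# ---------------------------------------------------------------------------

def read_str_catalog(path) -> List[StrRecord]:
    """Parse a 7-column whitespace-delimited STR catalog.

    Columns: chrom, start, end, period, repeat count, name, motif.
    Raises :class:`ParseError` naming the offending line on malformed input.
    """
    records: List[StrRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ParseError(f"line {lineno}: expected 7 columns, got {len(fields)}")
            chrom, start_s, end_s, period_s, count_s, name, motif = fields
            try:
                start, end, period = int(start_s), int(end_s), int(period_s)
                repeat_count = float(count_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
            try:
                records.append(
                    StrRecord(
                        interval=GenomicInterval(chrom, start, end, UNSTRANDED, name),
                        period=period,
                        repeat_count=repeat_count,
                        motif=motif,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return records


def write_str_catalog(records: Iterable[StrRecord], path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# strinit v{__version__} STR catalog (HipSTR BED dialect)\n")
        for r in records:
            count = int(r.repeat_count) if float(r.repeat_count).is_integer() else r.repeat_count
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.period}\t{count}\t{r.name}\t{r.motif}\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def window_overlap(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    w: int = 0,
    same_strand: bool = False,
) -> List[Tuple[int, int]]:
    """All (i, j) with ``[a_i.start - w, a_i.end + w)`` overlapping ``b_j`` by >= 1 bp.

    Mirrors ``bedtools window -w``: the extension applies to the *a* side only.
    Strand is ignored unless ``same_strand`` is set.
    """
    if w < 0:
        raise ValueError("window extension w must be >= 0")
    trees: Dict[Tuple, IntervalTree] = {}
    for j, iv in enumerate(b):
        key = (iv.chrom, iv.strand) if same_strand else (iv.chrom,)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: List[Tuple[int, int]] = []
    for i, iv in enumerate(a):
        key = (iv.chrom, iv.strand) if same_strand else (iv.chrom,)
        tree = trees.get(key)
        if tree is None:
            continue
        lo = max(iv.start - w, 0) if iv.start - w < 0 else iv.start - w
        hits = tree.overlap(lo, iv.end + w)
        pairs.extend((i, hit.data) for hit in hits)
    pairs.sort()
    return pairs


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome_sizes: Mapping[str, int],
    excluded: Sequence[GenomicInterval] = (),
    seed: int = 0,
    max_tries: int = 1000,
) -> List[GenomicInterval]:
    """Length-preserving uniform re-placement avoiding excluded intervals.

    Chromosomes are chosen with probability proportional to the placeable
    space for each interval's length; placement is rejection-sampled against
    the exclusion set. Deterministic given ``seed``. This reimplements the
    *contract* of bedtools shuffle (-excl), not its RNG stream.
    """
    rng = np.random.default_rng(seed)
    excl: Dict[str, IntervalTree] = {}
    for iv in excluded:
        excl.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    chroms = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=np.int64)
    out: List[GenomicInterval] = []
    for iv in intervals:
        length = iv.length
        space = np.maximum(sizes - length + 1, 0)
        total = int(space.sum())
        if total <= 0:
            raise PlacementError(f"no chromosome can hold interval of length {length}")
        probs = space / total
        placed = False
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(0, space[ci]))
            chrom = chroms[ci]
            tree = excl.get(chrom)
            if tree is not None and tree.overlap(start, start + length):
                continue
            out.append(GenomicInterval(chrom, start, start + length, iv.strand, iv.name))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"failed to place interval {iv.name or ''} of length {length} "
                f"after {max_tries} tries"
            )
    return out


# ---------------------------------------------------------------------------
# Coverage (bedGraph, 1-bp binned)
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-chrom, per-strand nonnegative 1-bp signal; absent positions are 0.

    Provenance fields record how many libraries were averaged and which
    mapping-quality filter produced the input.
    """

    def __init__(self, n_libraries: int = 1, quality_filter: str = "Q3"):
        self._data: Dict[Tuple[str, str], np.ndarray] = {}
        self.n_libraries = n_libraries
        self.quality_filter = quality_filter

    def _array(self, chrom: str, strand: str, min_size: int = 0) -> np.ndarray:
        key = (chrom, strand)
        arr = self._data.get(key)
        if arr is None:
            arr = np.zeros(max(min_size, 1), dtype=np.float64)
            self._data[key] = arr
        elif arr.size < min_size:
            arr = np.concatenate([arr, np.zeros(min_size - arr.size)])
            self._data[key] = arr
        return arr

    def keys(self) -> List[Tuple[str, str]]:
        return list(self._data)

    def add(self, chrom: str, strand: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError("coverage values must be nonnegative")
        arr = self._array(chrom, strand, end)
        arr[start:end] += value

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        arr = self._data.get((chrom, strand))
        if arr is None:
            return 0.0
        lo, hi = max(start, 0), min(end, arr.size)
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum())

    def value_at(self, chrom: str, strand: str, pos: int) -> float:
        return self.window_sum(chrom, strand, pos, pos + 1)

    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self._data.values()))

    def array(self, chrom: str, strand: str, size: int) -> np.ndarray:
        """Dense copy of the first ``size`` positions (zero-padded)."""
        out = np.zeros(size)
        arr = self._data.get((chrom, strand))
        if arr is not None:
            n = min(size, arr.size)
            out[:n] = arr[:n]
        return out


def read_coverage(path, strand: str) -> CoverageTrack:
    """Load a 4-column bedGraph onto the given strand of a fresh track.

    Overlapping input records and negative values are errors.
    """
    track = CoverageTrack()
    seen: Dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = fields
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric bedGraph field") from None
            if value < 0:
                raise ParseError(f"line {lineno}: negative coverage value {value}")
            tree = seen.setdefault(chrom, IntervalTree())
            if tree.overlap(start, end):
                raise ParseError(f"line {lineno}: overlapping bedGraph record")
            tree.addi(start, end)
            track.add(chrom, strand, start, end, value)
    return track


def write_coverage(track: CoverageTrack, path, strand: str, header: bool = True) -> None:
    """Emit one strand of a track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        if header:
            fh.write(
                f"# strinit v{__version__} bedGraph strand={strand} "
                f"n_libraries={track.n_libraries} filter={track.quality_filter}\n"
            )
        for (chrom, s), arr in sorted(track._data.items()):
            if s != strand:
                continue
            nz = np.flatnonzero(arr)
            if nz.size == 0:
                continue
            # break into runs of identical nonzero value
            run_start = nz[0]
            prev = nz[0]
            val = arr[nz[0]]
            for p in nz[1:]:
                if p == prev + 1 and arr[p] == val:
                    prev = p
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{val:.10g}\n")
                run_start, prev, val = p, p, arr[p]
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{val:.10g}\n")


# ---------------------------------------------------------------------------
# SAM-like alignments with MD descriptors
# ---------------------------------------------------------------------------

def md_is_valid(md: str) -> bool:
    return bool(_MD_RE.match(md))


def read_alignments(path) -> Tuple[List[AlignmentRecord], Dict[str, int]]:
    """Read a text SAM file, keeping flag-0/16 records with parseable MD tags.

    Returns (records, counters); counters tally skipped flags, missing or
    malformed MD descriptors, and per-strand record counts.
    """
    counters = {"kept": 0, "skipped_flag": 0, "bad_md": 0, "missing_md": 0, "plus": 0, "minus": 0}
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.flag not in (0, 16):
                counters["skipped_flag"] += 1
                continue
            if not read.has_tag("MD"):
                counters["missing_md"] += 1
                continue
            md = str(read.get_tag("MD"))
            if not md_is_valid(md):
                counters["bad_md"] += 1
                continue
            strand = MINUS if read.flag == 16 else PLUS
            records.append(
                AlignmentRecord(
                    chrom=read.reference_name,
                    pos=read.reference_start,
                    strand=strand,
                    seq=read.query_sequence.upper(),
                    md=md,
                    mapq=read.mapping_quality,
                )
            )
            counters["kept"] += 1
            counters["plus" if strand == PLUS else "minus"] += 1
    return records, counters


def write_alignments(
    records: Iterable[AlignmentRecord], path, chrom_sizes: Mapping[str, int]
) -> None:
    """Write records as text SAM (ungapped reads, full-length match CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for i, r in enumerate(records):
            flag = 16 if r.strand == MINUS else 0
            fh.write(
                f"tag{i}\t{flag}\t{r.chrom}\t{r.pos + 1}\t{r.mapq}\t{len(r.seq)}M\t"
                f"*\t0\t0\t{r.seq}\t{'I' * len(r.seq)}\tMD:Z:{r.md}\n"
            )


# ---------------------------------------------------------------------------
# Generic BED helpers (anchor sets such as CAGE peaks)
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/4/6 intervals (strand from column 6 when present)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in (PLUS, MINUS) else UNSTRANDED
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# strinit v{__version__} BED\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )
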
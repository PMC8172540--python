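"""Initiation-signal statistic at STRs, strand orientation, directionality.

The signal at an STR is the mean 5'-end tag count summed over the STR body
extended by 5 bp on each side, normalized by the window length::

    S = sum_{p in [start-5, end+5)} cov[p] / (L + 10),   L = end - start

which makes S insensitive to STR length (uniform coverage c gives S = c).
Every catalog STR is evaluated in both orientations; the directionality
score D = (S+ − S−)/(S+ + S−) is ±1 for strictly one-strand transcription
and 0 for balanced bidirectional transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .genomic_io import (
    MINUS,
    PLUS,
    CoverageTrack,
    GenomicInterval,
    StrRecord,
    reverse_complement,
    shuffle_intervals,
    window_overlap,
)
from . import __version__

FLANK = 5  # bp added on each side of the STR body; fixes the L+10 denominator


@dataclass
class OrientedStr:
    """An STR assigned to one strand, with its 3' end and initiation signal."""

    record: StrRecord
    strand: str
    three_prime_end: int  # 1-based coordinate of the last transcribed base
    signal: float
    motif: str  # effective motif on this strand

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be nonnegative")

    @property
    def str_class(self) -> str:
        return self.motif

    @property
    def interval(self) -> GenomicInterval:
        return self.record.interval

    @property
    def three_prime_index(self) -> int:
        """0-based genomic index of the 3'-end base."""
        return self.three_prime_end - 1


@dataclass
class DirectionalityScore:
    value: Optional[float]  # None when both strand signals are 0

    @property
    def defined(self) -> bool:
        return self.value is not None


def mean_coverage(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-position arithmetic mean of several tracks (absent = 0)."""
    if not tracks:
        raise ValueError("mean_coverage needs at least one track")
    n = len(tracks)
    out = CoverageTrack(n_libraries=sum(t.n_libraries for t in tracks),
                        quality_filter=tracks[0].quality_filter)
    sizes: Dict[Tuple[str, str], int] = {}
    for t in tracks:
        for key, arr in t._data.items():
            sizes[key] = max(sizes.get(key, 0), arr.size)
    for (chrom, strand), size in sizes.items():
        acc = np.zeros(size)
        for t in tracks:
            arr = t._data.get((chrom, strand))
            if arr is not None:
                acc[: arr.size] += arr
        out._array(chrom, strand, size)[:] = acc / n
    return out


def cage_signal(record: StrRecord, cov: CoverageTrack, strand: str) -> float:
    """S = (coverage summed over STR ± 5 bp) / (L + 10).

    The window is clipped at chromosome edges but the nominal denominator
    L + 10 is retained.
    """
    iv = record.interval
    total = cov.window_sum(iv.chrom, strand, iv.start - FLANK, iv.end + FLANK)
    return total / (iv.length + 2 * FLANK)


def orient_str(
    record: StrRecord, cov_plus: CoverageTrack, cov_minus: Optional[CoverageTrack] = None
) -> Tuple[OrientedStr, OrientedStr]:
    """Both orientations of a catalog STR, with per-strand signals.

    ``cov_plus`` may hold both strands (then ``cov_minus`` is omitted) or the
    two strands may come as separate tracks. The (−) orientation's effective
    motif — hence its class key — is the reverse complement of the catalog
    motif.
    """
    cov_m = cov_minus if cov_minus is not None else cov_plus
    iv = record.interval
    s_plus = cage_signal(record, cov_plus, PLUS)
    s_minus = cage_signal(record, cov_m, MINUS)
    plus = OrientedStr(record, PLUS, three_prime_end=iv.end, signal=s_plus,
                       motif=record.motif)
    minus = OrientedStr(record, MINUS, three_prime_end=iv.start + 1, signal=s_minus,
                        motif=reverse_complement(record.motif))
    return plus, minus


def directionality(s_plus: float, s_minus: float) -> DirectionalityScore:
    """D = (S+ − S−) / (S+ + S−); undefined when both signals are 0."""
    if s_plus < 0 or s_minus < 0:
        raise ValueError("strand signals must be nonnegative")
    total = s_plus + s_minus
    if total == 0:
        return DirectionalityScore(None)
    return DirectionalityScore((s_plus - s_minus) / total)


def class_peak_fraction(
    oriented: Sequence[OrientedStr],
    anchors: Sequence[GenomicInterval],
    w: int = FLANK,
) -> Dict[str, Tuple[float, Tuple[float, float], int]]:
    """Per class: fraction of members with >= 1 anchor within w bp, Wilson 95% CI.

    Returns ``{class: (fraction, (lo, hi), n_members)}``; empty classes are
    simply absent.
    """
    intervals = [o.interval for o in oriented]
    hit = set(i for i, _ in window_overlap(intervals, list(anchors), w=w))
    out: Dict[str, Tuple[float, Tuple[float, float], int]] = {}
    by_class: Dict[str, List[int]] = {}
    for i, o in enumerate(oriented):
        by_class.setdefault(o.str_class, []).append(i)
    for cls, idxs in by_class.items():
        n = len(idxs)
        k = sum(1 for i in idxs if i in hit)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        out[cls] = (k / n, (float(lo), float(hi)), n)
    return out


def random_overlap_baseline(
    strs: Sequence[StrRecord],
    anchors: Sequence[GenomicInterval],
    genome_sizes: Mapping[str, int],
    seed: int = 0,
    w: int = FLANK,
) -> float:
    """Fraction of length-matched random intervals (excluding the catalog
    itself) that fall within w bp of an anchor."""
    intervals = [r.interval for r in strs]
    shuffled = shuffle_intervals(intervals, genome_sizes, excluded=intervals, seed=seed)
    if not shuffled:
        return 0.0
    hit = set(i for i, _ in window_overlap(shuffled, list(anchors), w=w))
    return len(hit) / len(shuffled)


def compartment_assignment(expr_nuclear: float, expr_cytoplasmic: float) -> str:
    """Assign an RNA to nucleus / cytoplasm / both / undetected by where it
    is detected (strictly > 0)."""
    if expr_nuclear < 0 or expr_cytoplasmic < 0:
        raise ValueError("expression values must be nonnegative")
    if expr_nuclear > 0 and expr_cytoplasmic > 0:
        return "both"
    if expr_nuclear > 0:
        return "nucleus"
    if expr_cytoplasmic > 0:
        return "cytoplasm"
    return "undetected"


def write_signal_table(oriented: Iterable[OrientedStr], path, header: bool = True) -> None:
    """TSV mirroring the published signal layout: one row per orientation."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# strinit v{__version__} STR signal table (flank={FLANK})\n")
        for o in oriented:
            iv = o.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{o.record.name};{o.motif};{o.strand}\t{o.signal:.6f}\t{o.strand}\n"
            )
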
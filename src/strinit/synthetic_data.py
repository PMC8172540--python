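"""Self-contained synthetic inputs with a known sequence→signal function.

The generator emulates the statistical structure the analysis assumes:

* an STR catalog on a toy genome, placed without overlap on a slot grid;
* class-specific flanking-sequence GC composition (so flank-only
  classification is learnable);
* a documented closed-form signal model: the log expected signal of an
  oriented STR is a class baseline plus additive effects of fixed-offset
  motifs planted in the downstream flank, with multiplicative lognormal
  noise — so tests can compute the Bayes-optimal predictor exactly;
* strand-specific coverage whose mass concentrates in a few bins at the
  3' end, plus unit-count scatter along the STR body (the low-count
  artifact real CAGE shows along repeats);
* directional classes (a strong strand-determining motif planted on one
  orientation only) versus balanced bidirectional classes;
* alignment fixtures with cap-dependent first-base G mismatches;
* SNVs with closed-form true effect signs for concordance analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import (
    MINUS,
    PLUS,
    AlignmentRecord,
    CoverageTrack,
    GenomicInterval,
    SequenceStore,
    StrRecord,
    reverse_complement,
)
from .seq_dataset import DEFAULT_WIDTH, extract_window
from .str_signal import OrientedStr, orient_str
from .variant_effects import VariantRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifEffect:
    """A fixed-offset flank motif with an additive effect on the log signal.

    ``offset`` is the transcript-orientation downstream offset of the motif
    start relative to the 3'-end base (offset 1 = first base after the STR).
    """

    name: str
    motif: str
    offset: int
    effect: float
    prob: float = 0.4


@dataclass(frozen=True)
class ClassSpec:
    motif: str  # catalog (+)-strand repeat unit; also the class key
    flank_gc: float  # GC fraction of the planted flanking background
    baseline: float  # class baseline on the log-signal scale
    directional: bool  # strand-determining motif on one orientation only


DEFAULT_CLASSES = (
    ClassSpec("AC", flank_gc=0.35, baseline=-1.0, directional=False),
    ClassSpec("AG", flank_gc=0.45, baseline=-0.6, directional=False),
    ClassSpec("AAC", flank_gc=0.55, baseline=-0.2, directional=True),
    ClassSpec("AGAT", flank_gc=0.65, baseline=0.2, directional=True),
)

DEFAULT_MOTIFS = (
    MotifEffect("enhancing", "TGACGTCA", offset=10, effect=1.0, prob=0.4),
    MotifEffect("repressing", "CACGTG", offset=25, effect=-0.8, prob=0.4),
)
DIRECTION_MOTIF = MotifEffect("directional", "ACGATTCG", offset=33, effect=3.0, prob=1.0)


@dataclass
class SignalModel:
    """Closed-form sequence→signal map: mu(window) = baseline + motif effects.

    ``log_expected`` scans the downstream half of a 3'-end-centered window
    for each motif at its fixed offset; the expected signal is exp(mu) and
    observed signals are exp(mu + eps), eps ~ N(0, sigma²). ``scatter_rate``
    is the per-bp, per-strand probability of a spurious unit tag count along
    the STR body.
    """

    class_baselines: Dict[str, float]
    motif_effects: Tuple[MotifEffect, ...] = DEFAULT_MOTIFS
    direction_motif: MotifEffect = DIRECTION_MOTIF
    length_effect: float = 0.5  # per (min(L,50)−20)/10; visible in the body only
    sigma: float = 0.35
    scatter_rate: float = 0.02
    peak_offsets: Tuple[int, ...] = (-2, -1, 0, 1, 2)
    peak_weights: Tuple[float, ...] = (0.1, 0.2, 0.4, 0.2, 0.1)

    def all_motifs(self) -> Tuple[MotifEffect, ...]:
        return (*self.motif_effects, self.direction_motif)

    def log_expected(self, window: str, str_class: str, str_length: int = 20) -> float:
        """mu for a full-width window in transcript orientation.

        The length term depends on the repeat body (its extent upstream of
        the 3'-end column), so models seeing only flanks cannot recover it
        — the generative function genuinely uses both body and flanks.
        """
        center = (len(window) - 1) // 2
        mu = self.class_baselines[str_class]
        mu += self.length_effect * (min(str_length, 50) - 24) / 10
        for m in self.all_motifs():
            lo = center + m.offset
            if window[lo : lo + len(m.motif)] == m.motif:
                mu += m.effect
        return mu

    def motif_offset_ranges(self) -> List[Tuple[int, int]]:
        """Transcript-orientation offset ranges [start, end) occupied by the
        planted motifs, relative to the 3'-end base."""
        return [(m.offset, m.offset + len(m.motif)) for m in self.all_motifs()]


def default_signal_model(class_specs: Sequence[ClassSpec] = DEFAULT_CLASSES) -> SignalModel:
    return SignalModel(class_baselines={c.motif: c.baseline for c in class_specs})


@dataclass
class SyntheticWorld:
    store: SequenceStore
    catalog: List[StrRecord]
    truth: pd.DataFrame  # one row per orientation
    plants: pd.DataFrame  # planted motif instances (name, strand, motif, offset)
    signal_model: SignalModel
    class_specs: Tuple[ClassSpec, ...]
    seed: int

    def chrom_sizes(self) -> Dict[str, int]:
        return self.store.chrom_sizes()

    def oriented(self, signals: str = "signal") -> List[OrientedStr]:
        """Truth-table orientations as OrientedStr records (signal column
        selectable: 'signal' observed or 'expected_signal' Bayes)."""
        rows = {(r["name"], r["strand"]): r for _, r in self.truth.iterrows()}
        out = []
        for rec in self.catalog:
            for strand in (PLUS, MINUS):
                r = rows[(rec.name, strand)]
                out.append(
                    OrientedStr(
                        rec,
                        strand,
                        three_prime_end=int(r["three_prime_end"]),
                        signal=max(float(r[signals]), 0.0),
                        motif=rec.motif if strand == PLUS else reverse_complement(rec.motif),
                    )
                )
        return out


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def generate_world(
    n_strs: int = 10_000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    class_specs: Sequence[ClassSpec] = DEFAULT_CLASSES,
    signal_model: Optional[SignalModel] = None,
    repeat_counts: Tuple[int, int] = (4, 12),
    seed: int = 0,
) -> SyntheticWorld:
    """Build a toy genome with planted STRs, flank biases, and motif effects.

    STRs are placed on a per-chromosome slot grid (no overlap, edge margins)
    and assigned to classes round-robin; each orientation's ground-truth mu
    is computed from the final sequence, so the truth table and the genome
    can never disagree. Deterministic per seed.
    """
    if not class_specs:
        raise ValueError("need at least one STR class")
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 1_000_000, "chr2": 1_000_000}
    model = signal_model or default_signal_model(class_specs)
    rng = np.random.default_rng(seed)

    total_len = sum(chrom_lengths.values())
    genome = {c: _random_bases(rng, n, gc=0.5) for c, n in chrom_lengths.items()}
    catalog: List[StrRecord] = []
    plant_rows: List[Dict] = []
    placements: List[Tuple[StrRecord, ClassSpec, str]] = []  # (record, cls, active strand)

    if n_strs > 0:
        # slot grid: flanks (50 bp windows + 60 bp biased background) must fit
        per_chrom = {
            c: int(round(n_strs * L / total_len)) for c, L in chrom_lengths.items()
        }
        # fix rounding drift
        drift = n_strs - sum(per_chrom.values())
        first = next(iter(per_chrom))
        per_chrom[first] += drift
        margin = 200
        max_len = max(len(c.motif) for c in class_specs) * repeat_counts[1]
        idx = 0
        for chrom, L in chrom_lengths.items():
            k = per_chrom[chrom]
            if k == 0:
                continue
            slot = (L - 2 * margin) // k
            if slot < max_len + 130:
                raise ValueError(
                    f"genome too small: slot {slot} bp on {chrom} cannot hold an "
                    f"STR of up to {max_len} bp plus flanks"
                )
            for s in range(k):
                cls = class_specs[idx % len(class_specs)]
                rc = int(rng.integers(repeat_counts[0], repeat_counts[1] + 1))
                body = cls.motif * rc
                length = len(body)
                slot_start = margin + s * slot
                jitter = int(rng.integers(-5, 6))
                start = slot_start + (slot - length) // 2 + jitter
                end = start + length
                # class-specific flanking background, then the repeat body
                genome[chrom][start - 60 : end + 60] = _random_bases(
                    rng, length + 120, gc=cls.flank_gc
                )
                genome[chrom][start:end] = np.array(list(body))
                rec = StrRecord(
                    interval=GenomicInterval(chrom, start, end, name=f"STR_{idx}"),
                    period=len(cls.motif),
                    repeat_count=float(rc),
                    motif=cls.motif,
                )
                active = PLUS if rng.random() < 0.5 else MINUS
                placements.append((rec, cls, active))
                catalog.append(rec)

                # plant flank motifs: downstream flank of the + orientation is
                # genome [end, end+50), of the − orientation [start-50, start)
                def plant(strand: str, m: MotifEffect) -> None:
                    if strand == PLUS:
                        lo = (end - 1) + m.offset
                        genome[chrom][lo : lo + len(m.motif)] = np.array(list(m.motif))
                    else:
                        hi = start - m.offset + 1
                        genome[chrom][hi - len(m.motif) : hi] = np.array(
                            list(reverse_complement(m.motif))
                        )
                    plant_rows.append(
                        {"name": rec.name, "strand": strand, "motif_name": m.name,
                         "offset": m.offset, "effect": m.effect}
                    )

                for m in model.motif_effects:
                    if cls.directional:
                        for strand in (PLUS, MINUS):
                            if rng.random() < m.prob:
                                plant(strand, m)
                    else:
                        # balanced classes carry the same motif content on
                        # both orientations, so directionality is noise-only
                        if rng.random() < m.prob:
                            plant(PLUS, m)
                            plant(MINUS, m)
                if cls.directional:
                    plant(active, model.direction_motif)
                idx += 1

    store = SequenceStore({c: "".join(arr.tolist()) for c, arr in genome.items()})

    truth_rows: List[Dict] = []
    for rec, cls, active in placements:
        iv = rec.interval
        for strand, tpe in ((PLUS, iv.end), (MINUS, iv.start + 1)):
            ostr = OrientedStr(rec, strand, tpe, 0.0,
                               rec.motif if strand == PLUS else reverse_complement(rec.motif))
            window = extract_window(store, ostr, DEFAULT_WIDTH)
            mu = (model.log_expected(window, rec.motif, iv.length)
                  if window is not None else np.nan)
            eps = float(rng.normal(0.0, model.sigma)) if model.sigma > 0 else 0.0
            truth_rows.append(
                {
                    "name": rec.name,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "str_class": rec.motif,
                    "strand": strand,
                    "three_prime_end": tpe,
                    "mu": mu,
                    "expected_signal": float(np.exp(mu)),
                    "signal": float(np.exp(mu + eps)),
                    "directional": cls.directional,
                    "active_strand": active if cls.directional else ".",
                }
            )
    truth = pd.DataFrame(truth_rows)
    plants = pd.DataFrame(plant_rows,
                          columns=["name", "strand", "motif_name", "offset", "effect"])
    return SyntheticWorld(store, catalog, truth, plants, model,
                          tuple(class_specs), seed)


def generate_coverage(world: SyntheticWorld, seed: int = 0) -> CoverageTrack:
    """Strand-specific coverage realizing the truth table's observed signals.

    Each orientation's mass S·(L+10) is spread over a few bins at its 3'
    end (inside the ±5 bp evaluation window); unit-count scatter is added
    along the STR body on both strands at ``scatter_rate`` per bp. With
    scatter_rate = 0 and sigma = 0 the recomputed signal equals the truth
    exactly.
    """
    model = world.signal_model
    rng = np.random.default_rng(seed)
    track = CoverageTrack(n_libraries=1, quality_filter="synthetic")
    sizes = world.chrom_sizes()
    for chrom, size in sizes.items():
        track._array(chrom, PLUS, size)
        track._array(chrom, MINUS, size)
    for _, row in world.truth.iterrows():
        L = int(row["end"]) - int(row["start"])
        mass = float(row["signal"]) * (L + 10)
        c = int(row["three_prime_end"]) - 1
        sgn = 1 if row["strand"] == PLUS else -1
        for off, wgt in zip(model.peak_offsets, model.peak_weights):
            track.add(row["chrom"], row["strand"], c + sgn * off, c + sgn * off + 1,
                      mass * wgt)
    if model.scatter_rate > 0:
        for rec in world.catalog:
            iv = rec.interval
            for strand in (PLUS, MINUS):
                hits = np.flatnonzero(rng.random(iv.length) < model.scatter_rate)
                for h in hits:
                    track.add(iv.chrom, strand, iv.start + int(h), iv.start + int(h) + 1, 1.0)
    return track


def generate_alignments(
    store: SequenceStore,
    anchors: Sequence[GenomicInterval],
    n_per_anchor: int = 10,
    cap_g_rate: float = 0.5,
    read_length: int = 25,
    seed: int = 0,
) -> List[AlignmentRecord]:
    """Tag fixtures whose 5' ends fall inside the anchors; a ``cap_g_rate``
    fraction carry a template-mismatched G at the 5' end (descriptors are
    consistent with the stored read sequences). Rate 0 gives a clean
    control set."""
    if not 0 <= cap_g_rate <= 1:
        raise ValueError("cap_g_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: List[AlignmentRecord] = []
    for anchor in anchors:
        strand = MINUS if anchor.strand == MINUS else PLUS
        size = store.chrom_length(anchor.chrom)
        for _ in range(n_per_anchor):
            p5 = int(rng.integers(anchor.start, anchor.end))
            if strand == PLUS:
                lo, hi = p5, p5 + read_length
            else:
                lo, hi = p5 - read_length + 1, p5 + 1
            if lo < 0 or hi > size:
                continue
            ref = store.get(anchor.chrom, lo, hi, PLUS)
            seq = ref
            md = str(read_length)
            if rng.random() < cap_g_rate:
                if strand == PLUS and ref[0] != "G":
                    seq = "G" + ref[1:]
                    md = f"0{ref[0]}{read_length - 1}"
                elif strand == MINUS and ref[-1] != "C":  # revcomp G
                    seq = ref[:-1] + "C"
                    md = f"{read_length - 1}{ref[-1]}0"
            out.append(AlignmentRecord(anchor.chrom, lo, strand, seq, md))
    return out


def generate_variants(
    world: SyntheticWorld,
    n: int = 400,
    frac_in_motif: float = 0.6,
    sign_noise: float = 0.0,
    seed: int = 0,
) -> Tuple[List[VariantRecord], Dict[str, Tuple[str, int]]]:
    """SNVs near STR 3' ends with closed-form true effects and eQTL slopes.

    A ``frac_in_motif`` fraction hits planted motif instances (nonzero true
    effect); the rest draw offsets from a discrete Laplace-like law
    p(o) ∝ exp(−|o − 5| / 10) on [−15, 45] (peaked just downstream of the
    3' end). The slope equals the true effect, with its sign flipped with
    probability ``sign_noise``. Gene starts are the target orientations' 3'
    ends, so every case passes the promoter filter. Reference alleles always
    match the genome.
    """
    rng = np.random.default_rng(seed)
    model = world.signal_model
    offsets = np.arange(-15, 46)
    probs = np.exp(-np.abs(offsets - 5) / 10.0)
    probs /= probs.sum()
    by_name = {rec.name: rec for rec in world.catalog}
    truth_idx = {(r["name"], r["strand"]): r for _, r in world.truth.iterrows()}
    plants = world.plants
    variants: List[VariantRecord] = []
    gene_starts: Dict[str, Tuple[str, int]] = {}
    seen_pos: set = set()
    for _ in range(n):
        in_motif = (len(plants) > 0) and (rng.random() < frac_in_motif)
        if in_motif:
            row = plants.iloc[int(rng.integers(0, len(plants)))]
            rec = by_name[row["name"]]
            strand = row["strand"]
            m = next(m for m in model.all_motifs() if m.name == row["motif_name"])
            o = int(row["offset"]) + int(rng.integers(0, len(m.motif)))
        else:
            rec = world.catalog[int(rng.integers(0, len(world.catalog)))]
            strand = PLUS if rng.random() < 0.5 else MINUS
            o = int(rng.choice(offsets, p=probs))
        iv = rec.interval
        c = (iv.end - 1) if strand == PLUS else iv.start
        pos0 = c + o if strand == PLUS else c - o
        if not 0 <= pos0 < world.store.chrom_length(iv.chrom) or (iv.chrom, pos0) in seen_pos:
            continue
        seen_pos.add((iv.chrom, pos0))
        ref = world.store.get(iv.chrom, pos0, pos0 + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        # closed-form true effect (alternative − reference) on the log scale
        trow = truth_idx[(rec.name, strand)]
        ostr = OrientedStr(rec, strand, int(trow["three_prime_end"]), 0.0,
                           rec.motif if strand == PLUS else reverse_complement(rec.motif))
        win_ref = extract_window(world.store, ostr, DEFAULT_WIDTH)
        mut_store = world.store.with_substitution(iv.chrom, pos0, alt)
        win_alt = extract_window(mut_store, ostr, DEFAULT_WIDTH)
        effect = (
            model.log_expected(win_alt, rec.motif, iv.length)
            - model.log_expected(win_ref, rec.motif, iv.length)
            if win_ref is not None and win_alt is not None
            else 0.0
        )
        slope = effect
        if sign_noise > 0 and rng.random() < sign_noise:
            slope = -slope
        gene = rec.name
        gene_starts[gene] = (iv.chrom, int(trow["three_prime_end"]))
        variants.append(
            VariantRecord(
                iv.chrom, pos0 + 1, ref, alt,
                {"slope": slope, "gene": gene, "true_effect": effect,
                 "target_strand": strand, "rel_pos": o},
            )
        )
    return variants, gene_starts
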
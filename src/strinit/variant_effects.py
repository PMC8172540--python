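"""Variant scoring against trained models: mutate, re-predict, compare signs.

A single-nucleotide variant is applied to the genome, the 3'-end-centered
window re-extracted (strand-adjusted for (−) orientations), and the model
re-run. For eQTLs the sign of predict(alt) − predict(ref) is compared with
the sign of the measured slope, stratified by the model's prediction error
ε = |predicted − observed| on the reference genome at the cut ε ≤ 0.2, and
tested against chance with a binomial test (one-sided by default: the claim
is directional). ClinVar-style group contrasts use a one-way ANOVA plus all
ordered one-sided Mann–Whitney tests with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnn_engine import ConvNet, TrainedModel
from .genomic_io import MINUS, PLUS, GenomicInterval, SequenceStore, StrRecord
from .interpretation import _model_of
from .seq_dataset import extract_window, one_hot
from .str_signal import OrientedStr

ERROR_CUT = 0.2  # natural-scale prediction-error stratification cut
EQTL_WINDOW = (-15, 30)  # transcript-orientation offsets around the STR 3' end
PROMOTER_WINDOW = 1000  # bp around a gene start
VARIANT_STR_WINDOW = 50  # bp extension for variant↔STR pairing


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    annotation: Dict = field(default_factory=dict)  # significance or slope/gene

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"alleles must be nonempty ACGT, got {allele!r}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class SignConcordanceResult:
    stratum: str
    n_same: int
    n_different: int
    p_value: float

    @property
    def n(self) -> int:
        return self.n_same + self.n_different

    @property
    def concordance(self) -> float:
        return self.n_same / self.n if self.n else float("nan")


def read_variants(path) -> List[VariantRecord]:
    """VCF-like TSV: chrom, pos (1-based), ref, alt, then free-form key=value
    annotation columns (or a single free-text significance column)."""
    out: List[VariantRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, pos, ref, alt = fields[0], int(fields[1]), fields[2], fields[3]
            ann: Dict = {}
            for extra in fields[4:]:
                if "=" in extra:
                    k, v = extra.split("=", 1)
                    try:
                        ann[k] = float(v)
                    except ValueError:
                        ann[k] = v
                else:
                    ann["significance"] = extra
            out.append(VariantRecord(chrom, pos, ref, alt, ann))
    return out


def write_variants(variants: Sequence[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            ann = "\t".join(f"{k}={v2}" for k, v2 in v.annotation.items())
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{ann}\n".rstrip() + "\n")


def map_variants_to_strs(
    variants: Sequence[VariantRecord],
    strs: Sequence[StrRecord],
    w: int = VARIANT_STR_WINDOW,
) -> Tuple[List[Tuple[int, int]], List[int]]:
    """Pairs (variant index, STR index) where the variant lies within the STR
    interval extended by w bp; plus the indices of unpaired STRs."""
    if w < 0:
        raise ValueError("w must be >= 0")
    from .genomic_io import window_overlap

    points = [GenomicInterval(v.chrom, v.pos0, v.pos0 + 1) for v in variants]
    ivs = [r.interval for r in strs]
    pairs = window_overlap(ivs, points, w=w)  # extension on the STR side
    out = sorted((vj, si) for si, vj in pairs)
    paired_strs = {si for _, si in out}
    unpaired = [i for i in range(len(strs)) if i not in paired_strs]
    return out, unpaired


def variant_delta(
    model: Union[ConvNet, TrainedModel],
    store: SequenceStore,
    ostr: OrientedStr,
    variant: VariantRecord,
    width: Optional[int] = None,
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Tuple[Optional[float], Optional[int], str]:
    """Δ = predict(reference) − predict(mutated) plus the variant's position
    relative to the 3'-end base in transcript orientation.

    ``transform`` maps raw model outputs onto the signal scale (e.g. expm1
    for a model trained on log1p targets); the delta's sign is invariant
    under any monotone transform. Returns (delta, relative_position,
    status); status is "ok", "skipped_non_snv", "ref_mismatch" or
    "outside_window".
    """
    net = _model_of(model)
    if width is None:
        width = net.spec.input_width
    if not variant.is_snv:
        return None, None, "skipped_non_snv"
    ref_base = store.get(variant.chrom, variant.pos0, variant.pos0 + 1)
    if ref_base != variant.ref:
        return None, None, "ref_mismatch"
    c = ostr.three_prime_index
    rel = variant.pos0 - c if ostr.strand == PLUS else c - variant.pos0
    half = (width - 1) // 2
    if abs(rel) > half:
        return None, rel, "outside_window"
    ref_win = extract_window(store, ostr, width)
    if ref_win is None:
        return None, rel, "outside_window"
    mut_store = store.with_substitution(variant.chrom, variant.pos0, variant.alt)
    mut_win = extract_window(mut_store, ostr, width)
    pred = net.predict(np.stack([one_hot(ref_win), one_hot(mut_win)]))
    if transform is not None:
        pred = transform(pred)
    return float(pred[0] - pred[1]), rel, "ok"


def signal_group_comparison(
    groups: Mapping[str, Sequence[float]], fdr_alpha: float = 0.05
) -> Dict[str, object]:
    """One-way ANOVA across groups plus all ordered one-sided Mann–Whitney
    tests ("greater"), Benjamini–Hochberg-adjusted across the pairwise tests."""
    labels = list(groups)
    if len(labels) < 2 or any(len(groups[g]) < 2 for g in labels):
        raise ValueError("need >= 2 groups with n >= 2 each")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    f_stat, f_p = stats.f_oneway(*arrays)
    rows = []
    for i, gi in enumerate(labels):
        for j, gj in enumerate(labels):
            if i == j:
                continue
            u_stat, p = stats.mannwhitneyu(arrays[i], arrays[j], alternative="greater")
            rows.append({"greater": gi, "lesser": gj, "U": float(u_stat), "p": float(p)})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p"], alpha=fdr_alpha, method="fdr_bh")[1]
    return {"anova_F": float(f_stat), "anova_p": float(f_p), "pairwise": pw}


def eqtl_sign_concordance(
    model: Union[ConvNet, TrainedModel],
    store: SequenceStore,
    eqtls: Sequence[VariantRecord],
    oriented: Sequence[OrientedStr],
    gene_starts: Mapping[str, Tuple[str, int]],  # gene -> (chrom, 1-based start)
    observed: Optional[Mapping[Tuple[str, str], float]] = None,
    promoter_window: int = PROMOTER_WINDOW,
    sel_window: Tuple[int, int] = EQTL_WINDOW,
    error_cut: float = ERROR_CUT,
    alternative: str = "greater",
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Tuple[List[SignConcordanceResult], pd.DataFrame]:
    """Sign concordance between predicted allele effects and eQTL slopes.

    Pipeline: (1) keep STR orientations whose 3' end lies within
    ``promoter_window`` of the eQTL's target-gene start; (2) keep eQTL SNVs
    within ``sel_window`` (transcript orientation, 0 = the 3'-end base);
    (3) per case compare sign(predict(alt) − predict(ref)) with the slope
    sign; (4) stratify by reference-genome prediction error ε ≤ ``error_cut``;
    (5) one-sided binomial test of the concordant count against p = 0.5 per
    stratum. Cases are deduplicated on (variant, STR, gene). ``observed``
    maps (STR name, strand) to the measured signal (defaults to each
    OrientedStr's own ``signal``); ``transform`` maps raw model outputs to
    the observed-signal scale before the error is taken.
    """
    net = _model_of(model)
    width = net.spec.input_width
    cases = []
    seen = set()
    by_chrom: Dict[str, List[OrientedStr]] = {}
    for o in oriented:
        by_chrom.setdefault(o.interval.chrom, []).append(o)
    for v in eqtls:
        if not v.is_snv or "slope" not in v.annotation:
            continue
        if v.annotation["slope"] == 0:
            # a zero slope carries no direction to compare
            continue
        gene = v.annotation.get("gene")
        if gene is None or gene not in gene_starts:
            continue
        g_chrom, g_start = gene_starts[gene]
        for o in by_chrom.get(v.chrom, []):
            if o.interval.chrom != g_chrom:
                continue
            if abs(o.three_prime_end - g_start) > promoter_window:
                continue
            c = o.three_prime_index
            rel = v.pos0 - c if o.strand == PLUS else c - v.pos0
            if not sel_window[0] <= rel <= sel_window[1]:
                continue
            key = (v.chrom, v.pos, v.alt, o.record.name, o.strand, gene)
            if key in seen:
                continue
            seen.add(key)
            delta, rel2, status = variant_delta(net, store, o, v, width,
                                                transform=transform)
            if status != "ok" or delta == 0:
                continue
            obs = (
                observed[(o.record.name, o.strand)]
                if observed is not None
                else o.signal
            )
            ref_win = extract_window(store, o, width)
            raw_ref = net.predict(one_hot(ref_win)[None, :, :])
            pred_ref = float(transform(raw_ref)[0] if transform is not None
                             else raw_ref[0])
            eps = abs(pred_ref - obs)
            # variant_delta returns reference − mutated; eQTL convention is
            # alternative − reference
            alt_minus_ref = -delta
            cases.append(
                {
                    "variant": f"{v.chrom}:{v.pos}{v.ref}>{v.alt}",
                    "str_name": o.record.name,
                    "strand": o.strand,
                    "gene": gene,
                    "rel_pos": rel,
                    "pred_effect": alt_minus_ref,
                    "slope": float(v.annotation["slope"]),
                    "error": eps,
                    "concordant": np.sign(alt_minus_ref)
                    == np.sign(v.annotation["slope"]),
                }
            )
    table = pd.DataFrame(cases)
    results: List[SignConcordanceResult] = []
    if table.empty:
        return results, table
    for stratum, mask in (
        (f"error<={error_cut}", table["error"] <= error_cut),
        (f"error>{error_cut}", table["error"] > error_cut),
    ):
        sub = table[mask]
        if len(sub) == 0:
            continue
        n_same = int(sub["concordant"].sum())
        n_diff = int(len(sub) - n_same)
        p = stats.binomtest(n_same, len(sub), 0.5, alternative=alternative).pvalue
        results.append(SignConcordanceResult(stratum, n_same, n_diff, float(p)))
    return results, table


def set_enrichment(
    member_labels: Sequence[str], background_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-label two-sided Fisher exact enrichment of a member set against a
    background, BH-adjusted across all labels tested.

    Returns a table with label, counts, odds ratio, p and adjusted p; labels
    with a degenerate 2×2 margin are marked untestable (NaN p).
    """
    members = pd.Series(list(member_labels))
    background = pd.Series(list(background_labels))
    labels = sorted(set(members) | set(background))
    rows = []
    for lab in labels:
        a = int((members == lab).sum())
        b = int(len(members) - a)
        c = int((background == lab).sum())
        d = int(len(background) - c)
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append({"label": lab, "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": np.nan, "p": np.nan})
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"label": lab, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": float(odds), "p": float(p)})
    out = pd.DataFrame(rows)
    testable = out["p"].notna()
    out["p_adj"] = np.nan
    if testable.any():
        out.loc[testable, "p_adj"] = multipletests(
            out.loc[testable, "p"], method="fdr_bh"
        )[1]
    return out
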
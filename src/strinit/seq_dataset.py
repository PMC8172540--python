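"""One-hot sequence windows centered on STR 3' ends, masking, and splits.

Windows are taken in transcript orientation: the center column is the
3'-end base itself, with (width−1)/2 bases upstream and downstream; (−)
strand windows are reverse-complemented. Masking schemes:

``none``
    the raw window;
``downstream7``
    the 7 bases immediately 3' of the STR end replaced by Ns (these can
    still contain repeat-motif bases, trivially learnable);
``flank_only``
    50 bp upstream of the STR 5' start + 9 Ns standing in for the whole STR
    (regardless of its true length) + 7 Ns + 43 bp of downstream flank,
    total 109 positions.

N (and hence any masked base) encodes as an all-zero one-hot column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import MINUS, PLUS, SequenceStore, reverse_complement
from .str_signal import OrientedStr

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MASK_NONE = "none"
MASK_DOWNSTREAM7 = "downstream7"
MASK_FLANK_ONLY = "flank_only"
MASK_SCHEMES = (MASK_NONE, MASK_DOWNSTREAM7, MASK_FLANK_ONLY)

# flank_only layout (in transcript orientation)
FLANK_UP = 50
STR_MASK = 9
DOWN_MASK = 7
FLANK_DOWN = 43
FLANK_ONLY_WIDTH = FLANK_UP + STR_MASK + DOWN_MASK + FLANK_DOWN  # 109

DEFAULT_WIDTH = 101


def one_hot(seq: str) -> np.ndarray:
    """4 × |seq| matrix, rows A,C,G,T; N gives an all-zero column."""
    mat = np.zeros((4, len(seq)), dtype=np.float32)
    for j, base in enumerate(seq):
        if base in _BASE_INDEX:
            mat[_BASE_INDEX[base], j] = 1.0
        elif base != "N":
            raise ValueError(f"unexpected character {base!r} in sequence")
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        s = col.sum()
        if s == 0:
            out.append("N")
        else:
            out.append(BASES[int(col.argmax())])
    return "".join(out)


def extract_window(
    store: SequenceStore, ostr: OrientedStr, width: int = DEFAULT_WIDTH
) -> Optional[str]:
    """Window of ``width`` bases centered on the 3'-end base, in transcript
    orientation; ``None`` when it would extend past a chromosome edge."""
    if width % 2 == 0:
        raise ValueError("window width must be odd")
    half = (width - 1) // 2
    c = ostr.three_prime_index
    chrom = ostr.interval.chrom
    lo, hi = c - half, c + half + 1
    if lo < 0 or hi > store.chrom_length(chrom):
        return None
    return store.get(chrom, lo, hi, ostr.strand)


def flank_only_window(store: SequenceStore, ostr: OrientedStr) -> Optional[str]:
    """109-bp flank-only layout: 50 bp upstream flank, 9+7 Ns, 43 bp downstream."""
    iv = ostr.interval
    if ostr.strand == PLUS:
        lo, hi = iv.start - FLANK_UP, iv.end + FLANK_UP
        if lo < 0 or hi > store.chrom_length(iv.chrom):
            return None
        up = store.get(iv.chrom, lo, iv.start, PLUS)
        down = store.get(iv.chrom, iv.end + DOWN_MASK, iv.end + FLANK_UP, PLUS)
    else:
        lo, hi = iv.start - FLANK_UP, iv.end + FLANK_UP
        if lo < 0 or hi > store.chrom_length(iv.chrom):
            return None
        up = store.get(iv.chrom, iv.end, iv.end + FLANK_UP, MINUS)
        down = store.get(iv.chrom, iv.start - FLANK_UP, iv.start - DOWN_MASK, MINUS)
    return up + "N" * (STR_MASK + DOWN_MASK) + down


def apply_mask(
    seq_window: str,
    ostr: OrientedStr,
    scheme: str,
    store: Optional[SequenceStore] = None,
) -> str:
    """Apply a masking scheme to a 3'-end-centered window.

    ``flank_only`` rebuilds the 109-bp layout from the store (the upstream
    flank lies beyond the STR 5' start, outside the centered window for long
    STRs), so ``store`` is required for that scheme.
    """
    if scheme not in MASK_SCHEMES:
        raise ValueError(f"unknown mask scheme {scheme!r}")
    if scheme == MASK_NONE:
        return seq_window
    if scheme == MASK_DOWNSTREAM7:
        if len(seq_window) % 2 == 0:
            raise ValueError("downstream7 masking needs an odd-width window")
        h = (len(seq_window) - 1) // 2  # center index = 3'-end base
        n_mask = min(DOWN_MASK, len(seq_window) - h - 1)
        return seq_window[: h + 1] + "N" * n_mask + seq_window[h + 1 + n_mask :]
    if store is None:
        raise ValueError("flank_only masking requires the SequenceStore")
    out = flank_only_window(store, ostr)
    if out is None:
        raise ValueError("flank_only window extends past a chromosome edge")
    return out


@dataclass
class SequenceDataset:
    """Encoded examples: X (N,4,W), targets y, and per-example metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame
    width: int
    n_skipped_edge: int = 0

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(
            self.X[idx], self.y[idx], self.meta.iloc[idx].reset_index(drop=True),
            self.width, 0,
        )

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), X=self.X, y=self.y)
        self.meta.to_csv(path.with_suffix(".meta.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "SequenceDataset":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        meta = pd.read_csv(path.with_suffix(".meta.tsv"), sep="\t")
        X = arrs["X"]
        return cls(X, arrs["y"], meta, width=X.shape[2])


def build_dataset(
    store: SequenceStore,
    oriented: Sequence[OrientedStr],
    width: int = DEFAULT_WIDTH,
    mask: str = MASK_NONE,
    targets: Optional[Sequence[float]] = None,
    log1p: bool = False,
) -> SequenceDataset:
    """Encode windows for a set of oriented STRs.

    ``targets`` defaults to each record's signal (natural scale; optional
    log1p transform). Windows crossing a chromosome edge are skipped and
    counted in ``n_skipped_edge``.
    """
    mats: List[np.ndarray] = []
    ys: List[float] = []
    rows: List[Dict] = []
    skipped = 0
    for i, ostr in enumerate(oriented):
        win = extract_window(store, ostr, width)
        if win is None:
            skipped += 1
            continue
        try:
            win = apply_mask(win, ostr, mask, store=store)
        except ValueError:
            skipped += 1
            continue
        y = float(targets[i]) if targets is not None else float(ostr.signal)
        mats.append(one_hot(win))
        ys.append(np.log1p(y) if log1p else y)
        rows.append(
            {
                "name": ostr.record.name,
                "str_class": ostr.str_class,
                "strand": ostr.strand,
                "chrom": ostr.interval.chrom,
                "three_prime_end": ostr.three_prime_end,
            }
        )
    if mats:
        X = np.stack(mats)
    else:
        w = FLANK_ONLY_WIDTH if mask == MASK_FLANK_ONLY else width
        X = np.zeros((0, 4, w), dtype=np.float32)
    return SequenceDataset(
        X, np.asarray(ys, dtype=np.float64), pd.DataFrame(rows), X.shape[2], skipped
    )


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    manifest: Dict = field(default_factory=dict)


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> List[int]:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for k in range(rem):
        sizes[order[k]] += 1
    return sizes


def make_split(
    n: int, fractions: Sequence[float] = (0.7, 0.15, 0.15), seed: int = 0
) -> DatasetSplit:
    """Seeded random train/validation/test partition (largest-remainder sizes)."""
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if any(f < 0 for f in fractions) or fractions[0] <= 0:
        raise ValueError("train fraction must be > 0 and none may be negative")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train, n_val, n_test = _largest_remainder_sizes(n, fractions)
    split = DatasetSplit(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train : n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val :]),
    )
    split.manifest = {
        "n": n,
        "fractions": list(fractions),
        "seed": seed,
        "train_idx": split.train_idx.tolist(),
        "val_idx": split.val_idx.tolist(),
        "test_idx": split.test_idx.tolist(),
    }
    return split


def save_split(split: DatasetSplit, path) -> None:
    with open(path, "w") as fh:
        json.dump(split.manifest, fh)


def load_split(path) -> DatasetSplit:
    with open(path) as fh:
        m = json.load(fh)
    return DatasetSplit(
        np.asarray(m["train_idx"], dtype=int),
        np.asarray(m["val_idx"], dtype=int),
        np.asarray(m["test_idx"], dtype=int),
        manifest=m,
    )


def balance_classes(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices downsampling the majority class to the minority size (seeded).

    For pairwise classification; labels are 0/1.
    """
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    k = min(idx0.size, idx1.size)
    keep = np.concatenate(
        [rng.choice(idx0, k, replace=False), rng.choice(idx1, k, replace=False)]
    )
    return np.sort(keep)


def export_windows_fasta(ds: SequenceDataset, path) -> None:
    """FASTA export of the (decoded) windows for inspection."""
    with open(path, "w") as fh:
        for i in range(len(ds)):
            name = ds.meta.iloc[i]["name"]
            strand = ds.meta.iloc[i]["strand"]
            fh.write(f">{name}|{strand}\n{decode_one_hot(ds.X[i])}\n")
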
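"""Model interpretation: filter influence, PWM scans, in-silico mutagenesis.

Filter influence is measured by zeroing one first-layer filter's activation
map (no retraining, no renormalization) and recomputing the test metric;
the significance threshold comes from retraining the model ten times,
taking the t-based 95% confidence interval of the accuracies, and setting
τ = log2(CI length / 2). Perturbation analysis draws mutation positions
uniformly over the window (all three alternative bases equiprobable) and
summarizes prediction deltas by their variance at each position relative to
the 3'-end column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .cnn_engine import (
    CLASSIFICATION,
    ConvNet,
    EvalReport,
    TrainedModel,
    eval_classification,
    eval_regression,
)
from .seq_dataset import BASES, one_hot


@dataclass
class FilterInfluence:
    filter_index: int
    baseline_metric: float
    ablated_metric: float
    rank: int = 0

    @property
    def influence(self) -> float:
        # a constant ablated predictor (undefined metric) counts as total loss
        ablated = 0.0 if np.isnan(self.ablated_metric) else self.ablated_metric
        return self.baseline_metric - ablated


@dataclass
class InfluenceThreshold:
    accuracies: List[float]
    ci: Tuple[float, float]
    threshold: Optional[float]  # log2(CI length / 2); None if CI length is 0

    @property
    def ci_length(self) -> float:
        return self.ci[1] - self.ci[0]


@dataclass
class Pwm:
    """Position × base probability matrix with a log-odds form."""

    probs: np.ndarray  # (width, 4), rows sum to 1
    pseudocount: float
    background: float = 0.25

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass
class PositionalImpactProfile:
    offsets: np.ndarray  # positions relative to the 3'-end column
    variances: np.ndarray
    counts: np.ndarray


def _model_of(m: Union[ConvNet, TrainedModel]) -> ConvNet:
    return m.model if isinstance(m, TrainedModel) else m


def _metric(model: ConvNet, pred: np.ndarray, y: np.ndarray) -> float:
    if model.spec.task == CLASSIFICATION:
        return eval_classification(pred, y).value
    return eval_regression(pred, y).value


def filter_influence(
    model: Union[ConvNet, TrainedModel], X: np.ndarray, y: np.ndarray
) -> List[FilterInfluence]:
    """Influence of each first-stage filter: baseline metric − metric with the
    filter's activations zeroed, on the same test set, no retraining."""
    net = _model_of(model)
    if net.spec.n_filters < 2:
        raise ValueError("need at least two first-stage filters")
    base = _metric(net, net.predict(X), y)
    records = []
    for f in range(net.spec.n_filters):
        ablated = _metric(net, net.predict(X, ablate_filters=[f]), y)
        records.append(FilterInfluence(f, base, ablated))
    order = np.argsort([-r.influence for r in records], kind="stable")
    for rank, idx in enumerate(order, start=1):
        records[idx].rank = rank
    return records


def threshold_from_ci_length(ci_length: float) -> Optional[float]:
    """τ = log2(CI length / 2); undefined (None) for a zero-length CI."""
    if ci_length <= 0:
        return None
    return float(np.log2(ci_length / 2))


def influence_threshold(accuracies: Sequence[float]) -> InfluenceThreshold:
    """t-based 95% CI of the mean retraining accuracy; τ = log2(CI length / 2)."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need >= 2 retraining accuracies")
    mean = acc.mean()
    sem = acc.std(ddof=1) / np.sqrt(acc.size)
    if sem == 0:
        return InfluenceThreshold(list(acc), (mean, mean), None)
    tcrit = stats.t.ppf(0.975, acc.size - 1)
    ci = (mean - tcrit * sem, mean + tcrit * sem)
    return InfluenceThreshold(list(acc), ci, threshold_from_ci_length(ci[1] - ci[0]))


def influence_log2(records: Sequence[FilterInfluence], floor: float = 1e-6) -> np.ndarray:
    """Influences on the log2 scale for threshold comparison; non-positive
    values are floored at ``floor`` (configurable) before the log."""
    vals = np.array([max(r.influence, floor) for r in records])
    return np.log2(vals)


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def build_pwm(sequences: Sequence[str], pseudocount: float = 0.5) -> Pwm:
    """Column-wise base frequencies with pseudocount from equal-length
    aligned sequences (e.g. −3/+10 bp around donor splice sites)."""
    if not sequences:
        raise ValueError("need at least one sequence")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("sequences must be equal length")
    counts = np.full((width, 4), pseudocount, dtype=float)
    for s in sequences:
        for j, base in enumerate(s.upper()):
            if base in BASES:
                counts[j, BASES.index(base)] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    return Pwm(probs, pseudocount)


def read_jaspar(path) -> Dict[str, Pwm]:
    """JASPAR position-frequency matrices (``>ID name`` then 4 ``A [..]`` rows)."""
    pwms: Dict[str, Pwm] = {}
    name = None
    rows: Dict[str, List[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None and len(rows) == 4:
                    pwms[name] = _pwm_from_counts(rows)
                name = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                nums = line[line.index("[") + 1 : line.index("]")].split() \
                    if "[" in line else line.split()[1:]
                rows[base] = [float(x) for x in nums]
    if name is not None and len(rows) == 4:
        pwms[name] = _pwm_from_counts(rows)
    return pwms


def _pwm_from_counts(rows: Dict[str, List[float]], pseudocount: float = 0.5) -> Pwm:
    counts = np.array([rows[b] for b in BASES]).T + pseudocount
    return Pwm(counts / counts.sum(axis=1, keepdims=True), pseudocount)


def max_score_scan(sequence: str, scorer: Union[Pwm, np.ndarray]) -> float:
    """Maximum over all offsets of the position-wise score sum.

    ``scorer`` is a PWM (scored via its log-odds) or a raw (4, k) kernel
    (convolution-style matrix multiplication). N columns contribute 0.
    """
    if isinstance(scorer, Pwm):
        weights = scorer.log_odds.T  # (4, k)
    else:
        weights = np.asarray(scorer, dtype=float)
    k = weights.shape[1]
    if len(sequence) < k:
        raise ValueError("sequence shorter than scorer width")
    enc = one_hot(sequence.upper()).astype(float)  # (4, L)
    best = -np.inf
    for off in range(len(sequence) - k + 1):
        score = float((enc[:, off : off + k] * weights).sum())
        if score > best:
            best = score
    return best


def filter_pwm_correlation(
    filter_scores: Sequence[float], pwm_scores: Sequence[float]
) -> Tuple[float, int]:
    """Spearman correlation (average-rank ties) between per-sequence filter
    scores and PWM scores, over the caller-supplied hit set."""
    fs = np.asarray(filter_scores, dtype=float)
    ps = np.asarray(pwm_scores, dtype=float)
    if fs.shape != ps.shape or fs.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(fs) == 0 or np.ptp(ps) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho = stats.spearmanr(fs, ps).statistic
    return float(rho), int(fs.size)


# ---------------------------------------------------------------------------
# Perturbation analysis
# ---------------------------------------------------------------------------

def prediction_delta(
    model: Union[ConvNet, TrainedModel], reference: np.ndarray, mutated: np.ndarray
) -> float:
    """Δ = predict(reference) − predict(mutated), for single encoded windows."""
    if reference.shape != mutated.shape:
        raise ValueError("reference and mutated windows must have equal shape")
    net = _model_of(model)
    pred = net.predict(np.stack([reference, mutated]))
    return float(pred[0] - pred[1])


def mutagenesis_profile(
    model: Union[ConvNet, TrainedModel],
    X: np.ndarray,
    mutations_per_window: int = 10,
    seed: int = 0,
    batch_size: int = 2048,
) -> PositionalImpactProfile:
    """Uniform random mutagenesis: positions uniform over the window, the 3
    alternative bases equiprobable; per-position variance of the deltas
    (reference − mutated), indexed relative to the 3'-end (center) column."""
    net = _model_of(model)
    if X.shape[0] < 1:
        raise ValueError("need at least one window")
    rng = np.random.default_rng(seed)
    W = X.shape[2]
    center = (W - 1) // 2
    n = X.shape[0]
    ref_pred = net.predict(X, batch_size=batch_size)
    deltas_by_pos: Dict[int, List[float]] = {p: [] for p in range(W)}
    # build all mutated windows for one replicate round at a time
    for m in range(mutations_per_window):
        positions = rng.integers(0, W, size=n)
        mut = X.copy()
        for i in range(n):
            p = positions[i]
            col = mut[i, :, p]
            ref_base = int(col.argmax()) if col.sum() > 0 else -1
            choices = [b for b in range(4) if b != ref_base]
            new_base = int(rng.choice(choices))
            mut[i, :, p] = 0.0
            mut[i, new_base, p] = 1.0
        mut_pred = net.predict(mut, batch_size=batch_size)
        d = ref_pred - mut_pred
        for i in range(n):
            deltas_by_pos[int(positions[i])].append(float(d[i]))
    offsets = np.arange(W) - center
    variances = np.array(
        [np.var(deltas_by_pos[p]) if deltas_by_pos[p] else 0.0 for p in range(W)]
    )
    counts = np.array([len(deltas_by_pos[p]) for p in range(W)])
    return PositionalImpactProfile(offsets, variances, counts)


def positional_distribution(
    events: Sequence[int], bins: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of event offsets relative to an anchor (counts, bin edges)."""
    ev = np.asarray(events)
    if ev.size == 0:
        raise ValueError("no events")
    if bins is None:
        bins = np.arange(ev.min(), ev.max() + 2)
    counts, edges = np.histogram(ev, bins=bins)
    return counts, edges


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov on raw offset samples: (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need at least one event in each sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
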
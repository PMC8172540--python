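"""Small convolutional sequence-to-signal models, trained in pure numpy.

Architecture (defaults): one convolution stage of 50 filters of width 12
over the 4-row one-hot matrix, ReLU, non-overlapping max-pooling of width
4, then two fully connected stages (64, 16) with dropout 0.30, and a single
output unit — linear for regression (mean-squared-error loss), sigmoid for
classification (binary cross-entropy). The regression and classification
specs differ only in that final unit. Training uses Adam with patience-based
early stopping on the validation loss (default patience 5) and retains the
best-validation weights. Everything is seeded and reproducible run to run.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

REGRESSION = "regression"
CLASSIFICATION = "classification"


@dataclass(frozen=True)
class ModelSpec:
    input_width: int
    n_filters: int = 50
    kernel_width: int = 12
    pool_width: int = 4
    fc_sizes: Tuple[int, ...] = (64, 16)
    dropout: float = 0.30
    task: str = REGRESSION

    def __post_init__(self) -> None:
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_filters < 1:
            raise ValueError("need at least one convolution filter")
        if self.conv_out < 1:
            raise ValueError("kernel wider than input")
        if self.pooled_out < 1:
            raise ValueError("pooling width exceeds convolution output")

    @property
    def conv_out(self) -> int:
        return self.input_width - self.kernel_width + 1

    @property
    def pooled_out(self) -> int:
        return self.conv_out // self.pool_width

    @property
    def flat_size(self) -> int:
        return self.pooled_out * self.n_filters


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EvalReport:
    metric: str
    value: float
    n: int
    note: str = ""


class EarlyStopper:
    """Stop after `patience` consecutive epochs without a new best loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.since_best = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
            self.since_best = 0
        else:
            self.since_best += 1
        return self.since_best >= self.patience


class ConvNet:
    """Feed-forward conv net over one-hot DNA; parameters in a flat dict."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.params: Dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        k = spec.kernel_width
        fan = 4 * k
        self.params["Wc"] = rng.normal(0, np.sqrt(2 / fan), (4 * k, spec.n_filters))
        self.params["bc"] = np.zeros(spec.n_filters)
        sizes = [spec.flat_size, *spec.fc_sizes, 1]
        for li, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            self.params[f"W{li}"] = rng.normal(0, np.sqrt(2 / n_in), (n_in, n_out))
            self.params[f"b{li}"] = np.zeros(n_out)
        self._n_fc = len(sizes) - 1

    # -- forward -----------------------------------------------------------
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _cols(self, X: np.ndarray) -> np.ndarray:
        k = self.spec.kernel_width
        # (N,4,W) -> (N,P,4*k) patch matrix
        v = sliding_window_view(X, k, axis=2)  # (N,4,P,k)
        return np.ascontiguousarray(v.transpose(0, 2, 1, 3)).reshape(
            X.shape[0], self.spec.conv_out, 4 * k
        )

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
        ablate_filters: Optional[Sequence[int]] = None,
    ) -> Tuple[np.ndarray, Dict]:
        spec = self.spec
        if X.shape[1] != 4 or X.shape[2] != spec.input_width:
            raise ValueError(
                f"input shape {X.shape[1:]} incompatible with model width "
                f"(4, {spec.input_width})"
            )
        cache: Dict = {}
        cols = self._cols(X.astype(np.float64, copy=False))
        Z = cols @ self.params["Wc"] + self.params["bc"]  # (N,P,F)
        A = np.maximum(Z, 0.0)
        if ablate_filters is not None:
            A[:, :, list(ablate_filters)] = 0.0
        Q, pw = spec.pooled_out, spec.pool_width
        Ar = A[:, : Q * pw, :].reshape(X.shape[0], Q, pw, spec.n_filters)
        amax = Ar.argmax(axis=2)
        M = np.take_along_axis(Ar, amax[:, :, None, :], axis=2).squeeze(2)
        h = M.reshape(X.shape[0], spec.flat_size)
        cache.update(cols=cols, Z=Z, amax=amax, pooled=h)
        acts = [h]
        masks = []
        for li in range(self._n_fc):
            z = acts[-1] @ self.params[f"W{li}"] + self.params[f"b{li}"]
            if li < self._n_fc - 1:
                a = np.maximum(z, 0.0)
                if train and spec.dropout > 0:
                    mask = (rng.random(a.shape) >= spec.dropout) / (1 - spec.dropout)
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(a)
            else:
                acts.append(z)
        cache.update(acts=acts, masks=masks)
        out = acts[-1][:, 0]
        return out, cache

    def predict(
        self,
        X: np.ndarray,
        batch_size: int = 2048,
        ablate_filters: Optional[Sequence[int]] = None,
    ) -> np.ndarray:
        """Deterministic inference (dropout off); probabilities for classifiers."""
        outs = []
        for lo in range(0, X.shape[0], batch_size):
            z, _ = self.forward(X[lo : lo + batch_size], ablate_filters=ablate_filters)
            outs.append(z)
        out = np.concatenate(outs) if outs else np.zeros(0)
        if self.spec.task == CLASSIFICATION:
            out = 1.0 / (1.0 + np.exp(-out))
        return out

    # -- backward ----------------------------------------------------------
    def _loss_and_dout(self, out: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
        n = out.shape[0]
        if self.spec.task == REGRESSION:
            diff = out - y
            return float(np.mean(diff**2)), 2 * diff / n
        # numerically stable binary cross-entropy on logits
        loss = float(np.mean(np.logaddexp(0.0, out) - y * out))
        sig = 1.0 / (1.0 + np.exp(-out))
        return loss, (sig - y) / n

    def loss(self, X: np.ndarray, y: np.ndarray, batch_size: int = 2048) -> float:
        total, n = 0.0, X.shape[0]
        for lo in range(0, n, batch_size):
            out, _ = self.forward(X[lo : lo + batch_size])
            l, _ = self._loss_and_dout(out, y[lo : lo + batch_size])
            total += l * min(batch_size, n - lo)
        return total / n

    def backward(self, cache: Dict, dout: np.ndarray) -> Dict[str, np.ndarray]:
        spec = self.spec
        grads: Dict[str, np.ndarray] = {}
        acts, masks = cache["acts"], cache["masks"]
        d = dout[:, None]  # (N,1)
        for li in range(self._n_fc - 1, -1, -1):
            a_in = acts[li]
            grads[f"W{li}"] = a_in.T @ d
            grads[f"b{li}"] = d.sum(axis=0)
            d = d @ self.params[f"W{li}"].T
            if li > 0:
                # acts[li] = relu(z)*mask: zero where dropped or z <= 0
                if masks[li - 1] is not None:
                    d = d * masks[li - 1]
                d = d * (acts[li] > 0)
        dh = d  # delta w.r.t. the pooled/flattened features
        N = dh.shape[0]
        Q, pw, F = spec.pooled_out, spec.pool_width, spec.n_filters
        dM = dh.reshape(N, Q, F)
        dAr = np.zeros((N, Q, pw, F))
        np.put_along_axis(dAr, cache["amax"][:, :, None, :], dM[:, :, None, :], axis=2)
        dA = np.zeros((N, spec.conv_out, F))
        dA[:, : Q * pw, :] = dAr.reshape(N, Q * pw, F)
        dZ = dA * (cache["Z"] > 0)
        grads["Wc"] = np.einsum("npk,npf->kf", cache["cols"], dZ)
        grads["bc"] = dZ.sum(axis=(0, 1))
        return grads


@dataclass
class TrainedModel:
    model: ConvNet
    history: List[Dict[str, float]] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def predict(self, X: np.ndarray, **kw) -> np.ndarray:
        return self.model.predict(X, **kw)


def build_model(spec: ModelSpec, seed: int = 0) -> ConvNet:
    """Deterministically initialized, untrained model."""
    return ConvNet(spec, seed=seed)


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: ConvNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Mini-batch Adam with early stopping; best-validation weights retained."""
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    stopper = EarlyStopper(config.patience)
    history: List[Dict[str, float]] = []
    best_params = {k: v.copy() for k, v in model.params.items()}
    n = X_train.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            out, cache = model.forward(X_train[idx], train=True, rng=rng)
            loss, dout = model._loss_and_dout(out, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr too high?)"
                )
            grads = model.backward(cache, dout)
            opt.step(model.params, grads)
            ep_loss += loss
            nb += 1
        val_loss = model.loss(X_val, y_val)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": ep_loss / nb, "val_loss": val_loss})
        stop = stopper.update(val_loss)
        if stopper.since_best == 0:
            best_params = {k: v.copy() for k, v in model.params.items()}
        if stop:
            break
    model.params = best_params
    return TrainedModel(model, history, stopped_epoch=len(history),
                        best_epoch=stopper.best_epoch)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def eval_regression(predictions: np.ndarray, targets: np.ndarray) -> EvalReport:
    """Spearman rank correlation (average ranks for ties)."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape or predictions.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(predictions) == 0 or np.ptp(targets) == 0:
        return EvalReport("spearman", float("nan"), predictions.size,
                          note="undefined: constant vector")
    rho = stats.spearmanr(predictions, targets).statistic
    return EvalReport("spearman", float(rho), predictions.size)


def eval_classification(scores: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Exact AUC = P(score_pos > score_neg) + ½·P(tie), via average ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties exactly
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return EvalReport("auc", float(auc), scores.size)


def randomized_baseline(
    targets: np.ndarray, reps: int = 10, seed: int = 0, permute: bool = True
) -> List[float]:
    """|Spearman| between targets and seeded permutations of themselves.

    ``permute=False`` forces the identity permutation (test hook).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    targets = np.asarray(targets, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        perm = rng.permutation(targets) if permute else targets
        out.append(abs(float(stats.spearmanr(targets, perm).statistic)))
    return out


def grid_search(
    space: Mapping[str, Sequence],
    base_spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> Tuple[ModelSpec, pd.DataFrame]:
    """Train every combination in the (finite) space with the shared seed;
    select by validation metric. Returns (best spec, full leaderboard)."""
    keys = list(space)
    if not keys or any(len(space[k]) == 0 for k in keys):
        raise ValueError("empty search space")
    rows = []
    best: Tuple[float, Optional[ModelSpec]] = (-np.inf, None)
    for combo in itertools.product(*(space[k] for k in keys)):
        spec = replace(base_spec, **dict(zip(keys, combo)))
        model = build_model(spec, seed=config.seed)
        tm = train(model, X_train, y_train, X_val, y_val, config)
        pred = tm.predict(X_val)
        if spec.task == REGRESSION:
            metric = eval_regression(pred, y_val).value
        else:
            metric = eval_classification(pred, y_val).value
        rows.append({**dict(zip(keys, combo)), "val_metric": metric,
                     "epochs": tm.stopped_epoch})
        if np.isfinite(metric) and metric > best[0]:
            best = (metric, spec)
    leaderboard = pd.DataFrame(rows).sort_values("val_metric", ascending=False)
    return best[1], leaderboard.reset_index(drop=True)


def cross_apply(
    models: Mapping[str, TrainedModel],
    test_sets: Mapping[str, Tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """metric[i][j] = model trained on class i evaluated on class j's test set.

    Width-incompatible cells are NaN; the matrix is not assumed symmetric.
    """
    classes_i = list(models)
    classes_j = list(test_sets)
    mat = pd.DataFrame(index=classes_i, columns=classes_j, dtype=float)
    for ci, tm in models.items():
        for cj, (X, y) in test_sets.items():
            if X.shape[2] != tm.spec.input_width:
                mat.loc[ci, cj] = np.nan
                continue
            pred = tm.predict(X)
            if tm.spec.task == REGRESSION:
                mat.loc[ci, cj] = eval_regression(pred, y).value
            else:
                mat.loc[ci, cj] = eval_classification(pred, y).value
    return mat


# ---------------------------------------------------------------------------
# Persistence (versioned npz archive: spec + weights + log)
# ---------------------------------------------------------------------------

def save_model(tm: TrainedModel, path) -> None:
    meta = {
        "format_version": 1,
        "spec": asdict(tm.spec),
        "history": tm.history,
        "stopped_epoch": tm.stopped_epoch,
        "best_epoch": tm.best_epoch,
    }
    np.savez(Path(path), _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **tm.model.params)


def load_model(path) -> TrainedModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrs = np.load(path)
    meta = json.loads(bytes(arrs["_meta"]).decode())
    spec_d = meta["spec"]
    spec_d["fc_sizes"] = tuple(spec_d["fc_sizes"])
    spec = ModelSpec(**spec_d)
    model = ConvNet(spec, seed=0)
    for k in model.params:
        model.params[k] = arrs[k]
    return TrainedModel(model, meta["history"], meta["stopped_epoch"], meta["best_epoch"])
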
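"""Model construction, training, evaluation metrics and search utilities."""

import numpy as np
import pytest
from scipy import stats

from strinit import cnn_engine as ce
from strinit import seq_dataset as sq


def _toy_data(n=400, width=21, seed=0, planted=True):
    """Tiny regression set with two planted fixed-position 4-mers whose
    additive effects (3 and 1.5) give four well-separated target levels."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 4, width), dtype=np.float32)
    y = np.zeros(n)
    m1, m2 = sq.one_hot("TGAC"), sq.one_hot("CATG")
    for i in range(n):
        s = rng.integers(0, 4, size=width)
        X[i, s, np.arange(width)] = 1.0
        if planted:
            if rng.random() < 0.5:
                X[i, :, 6:10] = m1
                y[i] += 3.0
            if rng.random() < 0.5:
                X[i, :, 13:17] = m2
                y[i] += 1.5
        y[i] += rng.normal(0, 0.05)
    return X, y


SMALL = ce.ModelSpec(input_width=21, n_filters=8, kernel_width=6, pool_width=2,
                     fc_sizes=(16,), dropout=0.1)
FAST = ce.TrainConfig(max_epochs=80, batch_size=64, seed=3, learning_rate=5e-3)


class TestBuildModel:
    def test_task_changes_nothing_but_last_unit(self):
        reg = ce.build_model(SMALL, seed=1)
        clf = ce.build_model(ce.ModelSpec(**{**SMALL.__dict__, "task": "classification"}),
                             seed=1)
        assert reg.param_count() == clf.param_count()

    def test_same_seed_bit_identical_weights(self):
        a, b = ce.build_model(SMALL, seed=7), ce.build_model(SMALL, seed=7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_forward_smoke_on_zero_matrix(self):
        model = ce.build_model(SMALL, seed=0)
        out = model.predict(np.zeros((1, 4, 21), dtype=np.float32))
        assert np.isfinite(out).all()

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            ce.ModelSpec(input_width=10, kernel_width=12)
        with pytest.raises(ValueError):
            ce.ModelSpec(input_width=13, kernel_width=12, pool_width=4)
        with pytest.raises(ValueError):
            ce.ModelSpec(input_width=21, dropout=1.0)

    def test_numeric_gradients_match_backprop(self):
        # spot-check a few coordinates of each parameter tensor
        rng = np.random.default_rng(2)
        spec = ce.ModelSpec(input_width=9, n_filters=3, kernel_width=4,
                            pool_width=2, fc_sizes=(5,), dropout=0.0)
        model = ce.build_model(spec, seed=4)
        X = rng.random((6, 4, 9))
        y = rng.random(6)
        out, cache = model.forward(X)
        _, dout = model._loss_and_dout(out, y)
        grads = model.backward(cache, dout)
        eps = 1e-6
        for k in model.params:
            flat = model.params[k].reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = model._loss_and_dout(model.forward(X)[0], y)[0]
                flat[idx] = orig - eps
                lm = model._loss_and_dout(model.forward(X)[0], y)[0]
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k].reshape(-1)[idx] == pytest.approx(num, abs=1e-5)


class TestTrain:
    def test_constant_targets_converge_to_constant(self):
        X, _ = _toy_data(200, planted=False)
        y = np.full(200, 1.7)
        model = ce.build_model(SMALL, seed=0)
        tm = ce.train(model, X[:150], y[:150], X[150:], y[150:], FAST)
        assert min(h["val_loss"] for h in tm.history) < 0.05
        assert np.allclose(tm.predict(X[:10]), 1.7, atol=0.25)

    def test_planted_motif_recovered(self):
        X, y = _toy_data(600, seed=1)
        model = ce.build_model(SMALL, seed=0)
        tm = ce.train(model, X[:400], y[:400], X[400:500], y[400:500], FAST)
        rep = ce.eval_regression(tm.predict(X[500:]), y[500:])
        assert rep.value > 0.8

    def test_training_reproducible_run_to_run(self):
        X, y = _toy_data(200)
        losses = []
        for _ in range(2):
            model = ce.build_model(SMALL, seed=5)
            tm = ce.train(model, X[:150], y[:150], X[150:], y[150:],
                          ce.TrainConfig(max_epochs=5, batch_size=64, seed=6))
            losses.append([h["val_loss"] for h in tm.history])
        np.testing.assert_allclose(losses[0], losses[1], rtol=1e-6)

    def test_empty_sets_rejected(self):
        X, y = _toy_data(10)
        model = ce.build_model(SMALL, seed=0)
        with pytest.raises(ValueError):
            ce.train(model, X[:0], y[:0], X, y, FAST)


class TestEarlyStopper:
    def test_strictly_worsening_stops_after_patience(self):
        stopper = ce.EarlyStopper(patience=5)
        assert stopper.update(1.0) is False  # epoch 1: the best so far
        stops = [stopper.update(1.0 + 0.1 * k) for k in range(1, 6)]
        assert stops == [False, False, False, False, True]
        assert stopper.epoch == 6  # 1 + patience
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = ce.EarlyStopper(patience=2)
        for loss in (1.0, 1.1, 0.9, 1.0):
            assert stopper.update(loss) is False
        assert stopper.update(1.0) is True
        assert stopper.best_epoch == 3

    def test_patience_validation(self):
        with pytest.raises(ValueError):
            ce.TrainConfig(patience=0)


@pytest.fixture(scope="module")
def model():
    return ce.build_model(SMALL, seed=8)


class TestPredict:

    def test_deterministic(self, model):
        X, _ = _toy_data(30)
        np.testing.assert_array_equal(model.predict(X), model.predict(X))

    def test_batched_equals_one_by_one(self, model):
        X, _ = _toy_data(30)
        batched = model.predict(X)
        single = np.concatenate([model.predict(X[i:i + 1]) for i in range(30)])
        np.testing.assert_allclose(batched, single, rtol=1e-10)

    def test_permutation_equivariance(self, model):
        X, _ = _toy_data(30)
        perm = np.random.default_rng(0).permutation(30)
        np.testing.assert_allclose(model.predict(X)[perm],
                                   model.predict(X[perm]), rtol=1e-10)

    def test_width_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 4, 33), dtype=np.float32))


def _spearman_oracle(a, b):
    """Brute-force rank formula with average ranks (Pearson on ranks)."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = np.array(v)[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + j + 1) / 2
            i = j
        return r
    ra, rb = ranks(a), ranks(b)
    return np.corrcoef(ra, rb)[0, 1]


class TestEvalRegression:
    def test_perfect_and_inverted(self):
        assert ce.eval_regression([1, 2, 3], [10, 20, 30]).value == 1
        assert ce.eval_regression([1, 2, 3], [3, 2, 1]).value == -1

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.integers(0, 10, size=20).astype(float)  # ties likely
            b = rng.integers(0, 10, size=20).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            got = ce.eval_regression(a, b).value
            assert got == pytest.approx(_spearman_oracle(a, b), abs=1e-12)

    def test_constant_vector_reported_undefined(self):
        rep = ce.eval_regression([1, 1, 1], [1, 2, 3])
        assert np.isnan(rep.value) and "undefined" in rep.note


def _auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvalClassification:
    def test_perfect_separation(self):
        assert ce.eval_classification([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).value == 1

    def test_all_tied_is_half(self):
        assert ce.eval_classification([0.5] * 6, [1, 0, 1, 0, 1, 0]).value == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            scores = rng.integers(0, 6, size=30).astype(float)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            got = ce.eval_classification(scores, labels).value
            assert got == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ce.eval_classification([0.5, 0.6], [1, 1])


class TestRandomizedBaseline:
    def test_null_scale(self):
        rng = np.random.default_rng(14)
        targets = rng.random(10_000)
        vals = ce.randomized_baseline(targets, reps=10, seed=0)
        assert max(vals) < 0.05

    def test_identity_permutation_hook(self):
        vals = ce.randomized_baseline(np.arange(50, dtype=float), reps=1,
                                      seed=0, permute=False)
        assert vals[0] == pytest.approx(1.0)

    def test_seeded(self):
        t = np.random.default_rng(15).random(500)
        assert ce.randomized_baseline(t, 5, seed=9) == \
            ce.randomized_baseline(t, 5, seed=9)


class TestGridSearch:
    def test_single_point_space(self):
        X, y = _toy_data(200)
        cfg = ce.TrainConfig(max_epochs=3, batch_size=64, seed=0)
        best, board = ce.grid_search({"n_filters": [8]}, SMALL,
                                     X[:120], y[:120], X[120:], y[120:], cfg)
        assert best.n_filters == 8 and len(board) == 1

    def test_2x2_space_trains_four_and_selects_max(self):
        X, y = _toy_data(200)
        cfg = ce.TrainConfig(max_epochs=3, batch_size=64, seed=0)
        best, board = ce.grid_search(
            {"n_filters": [4, 8], "kernel_width": [4, 6]}, SMALL,
            X[:120], y[:120], X[120:], y[120:], cfg)
        assert len(board) == 4
        top = board.iloc[0]
        assert best.n_filters == top["n_filters"]
        assert board["val_metric"].max() == top["val_metric"]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            ce.grid_search({}, SMALL, *(np.zeros((2, 4, 21)), np.zeros(2)) * 2)


class TestCrossApply:
    def test_1x1_reduces_to_eval(self):
        X, y = _toy_data(300, seed=4)
        model = ce.build_model(SMALL, seed=0)
        tm = ce.train(model, X[:200], y[:200], X[200:250], y[200:250], FAST)
        mat = ce.cross_apply({"a": tm}, {"a": (X[250:], y[250:])})
        assert mat.loc["a", "a"] == pytest.approx(
            ce.eval_regression(tm.predict(X[250:]), y[250:]).value)

    def test_width_mismatch_marked_missing(self):
        X, y = _toy_data(100)
        model = ce.build_model(SMALL, seed=0)
        tm = ce.train(model, X[:60], y[:60], X[60:80], y[60:80],
                      ce.TrainConfig(max_epochs=2, batch_size=32, seed=0))
        X2 = np.zeros((10, 4, 31), dtype=np.float32)
        mat = ce.cross_apply({"a": tm}, {"a": (X[80:], y[80:]),
                                         "b": (X2, np.zeros(10))})
        assert np.isfinite(mat.loc["a", "a"])
        assert np.isnan(mat.loc["a", "b"])

    def test_both_orders_computed(self):
        X, y = _toy_data(300, seed=5)
        Xb, yb = _toy_data(300, seed=6)
        cfg = ce.TrainConfig(max_epochs=3, batch_size=64, seed=0)
        ta = ce.train(ce.build_model(SMALL, seed=0), X[:200], y[:200],
                      X[200:250], y[200:250], cfg)
        tb = ce.train(ce.build_model(SMALL, seed=1), Xb[:200], yb[:200],
                      Xb[200:250], yb[200:250], cfg)
        mat = ce.cross_apply({"a": ta, "b": tb},
                             {"a": (X[250:], y[250:]), "b": (Xb[250:], yb[250:])})
        assert mat.shape == (2, 2)
        assert np.isfinite(mat.values.astype(float)).all()


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_data(200)
        model = ce.build_model(SMALL, seed=0)
        tm = ce.train(model, X[:150], y[:150], X[150:], y[150:],
                      ce.TrainConfig(max_epochs=3, batch_size=64, seed=0))
        p = tmp_path / "model.npz"
        ce.save_model(tm, p)
        back = ce.load_model(p)
        assert back.spec == tm.spec
        assert back.stopped_epoch == tm.stopped_epoch
        np.testing.assert_allclose(back.predict(X[:20]), tm.predict(X[:20]))
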
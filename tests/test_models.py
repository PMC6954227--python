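import numpy as np
import pytest

from ictalscope.evaluation import roc_auc
from ictalscope.models import (
    ArchitectureSpec,
    TrainingConfig,
    _softmax,
    _xent,
    build_classifier,
    load_model,
    predict_proba,
    save_model,
    train,
)

TINY_CONV = (
    {"filters": 3, "kernel": 3, "pool": 2},
    {"filters": 4, "kernel": 3, "pool": 2},
)


def numeric_gradient_error(spec, shape, n=5, probes=4):
    """Max relative error between backprop and central finite differences."""
    rng = np.random.default_rng(0)
    clf = build_classifier(spec, shape)
    clf.init_params(rng)
    X = rng.standard_normal((n, *shape))
    y = rng.integers(0, 2, n)
    logits = clf._forward(X, train=False)
    p = _softmax(logits)
    d = p.copy()
    d[np.arange(n), y] -= 1
    d /= n
    clf._backward(d)
    grads = [g.copy() for g in clf.gradients()]
    errs = []
    probe_rng = np.random.default_rng(1)
    for P, G in zip(clf.parameters(), grads):
        for _ in range(probes):
            idx = tuple(probe_rng.integers(0, s) for s in P.shape)
            eps, old = 1e-6, P[idx]
            P[idx] = old + eps
            lp = _xent(clf._forward(X, train=False), y)
            P[idx] = old - eps
            lm = _xent(clf._forward(X, train=False), y)
            P[idx] = old
            num = (lp - lm) / (2 * eps)
            errs.append(abs(num - G[idx]) / max(abs(num), abs(G[idx]), 1e-8))
    return max(errs)


class TestBackpropagation:
    """Analytic gradients of every family agree with finite differences."""

    @pytest.mark.parametrize(
        "spec,shape",
        [
            (ArchitectureSpec("fcnn", hidden_sizes=(8, 4), dropout=0.0), (12,)),
            (ArchitectureSpec("cnn1d", hidden_sizes=(6, 4), dropout=0.0, conv_blocks=TINY_CONV), (16,)),
            (ArchitectureSpec("cnn2d", hidden_sizes=(6, 4), dropout=0.0, conv_blocks=TINY_CONV), (8, 10)),
            (ArchitectureSpec("rnn_lstm", lstm_units=5), (10,)),
        ],
        ids=["fcnn", "cnn1d", "cnn2d", "rnn"],
    )
    def test_gradient_check(self, spec, shape):
        assert numeric_gradient_error(spec, shape) < 1e-4


class TestArchitectures:
    def test_output_probabilities_sum_to_one(self, rng):
        for fam, shape in [("fcnn", (20,)), ("rnn_lstm", (10,)), ("cnn2d", (8, 10))]:
            spec = ArchitectureSpec(fam, hidden_sizes=(6, 4), conv_blocks=TINY_CONV)
            clf = build_classifier(spec, shape)
            clf.init_params(rng)
            p = clf.predict_proba(rng.standard_normal((7, *shape)))
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(p >= 0)

    def test_fcnn_parameter_count_closed_form(self):
        clf = build_classifier(ArchitectureSpec("fcnn", hidden_sizes=(256, 64)), (500,))
        expected = (500 * 256 + 256) + (256 * 64 + 64) + (64 * 2 + 2)
        assert clf.n_parameters() == expected

    def test_rnn_sequence_lengths(self):
        clf = build_classifier(ArchitectureSpec("rnn_lstm"), (100,))
        assert clf._adapt(np.zeros((3, 100))).shape == (3, 50, 2)
        clf500 = build_classifier(ArchitectureSpec("rnn_lstm"), (500,))
        assert clf500._adapt(np.zeros((2, 500))).shape == (2, 250, 2)

    @pytest.mark.parametrize(
        "fam,shape",
        [("rnn_lstm", (15,)), ("cnn2d", (100,)), ("fcnn", (8, 10)), ("cnn1d", (8, 10))],
    )
    def test_incompatible_family_shape_rejected(self, fam, shape):
        with pytest.raises(ValueError):
            build_classifier(ArchitectureSpec(fam, conv_blocks=TINY_CONV), shape)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("transformer")


@pytest.fixture(scope="module")
def separable_fixture():
    rng = np.random.default_rng(7)
    X = np.concatenate([rng.standard_normal((80, 16)) + 2.0, rng.standard_normal((80, 16)) - 2.0])
    y = np.array([1] * 80 + [0] * 80)
    return X, y


@pytest.fixture(scope="module")
def trained_on_separable(separable_fixture):
    X, y = separable_fixture
    clf = build_classifier(ArchitectureSpec("fcnn", hidden_sizes=(12, 6)), (16,))
    clf, history = train(clf, X, y, TrainingConfig(max_epochs=25, minibatch=32, seed=0))
    return clf, history


class TestTraining:
    def test_separable_clusters_reach_auc_099(self, separable_fixture, trained_on_separable):
        X, y = separable_fixture
        clf, _ = trained_on_separable
        assert roc_auc(clf.predict_p_seizure(X), y).auc >= 0.99

    def test_history_bounded_by_max_epochs(self, trained_on_separable):
        _, history = trained_on_separable
        assert 1 <= len(history) <= 25
        assert {"epoch", "train_loss", "val_loss"} <= set(history[0])

    def test_shuffled_labels_give_chance_auc(self, separable_fixture):
        """Destroying the labels leaves nothing to learn: held-out AUC ~ 0.5."""
        X, y = separable_fixture
        rng = np.random.default_rng(3)
        aucs = []
        for seed in (0, 1, 2):
            ys = rng.permutation(y)
            Xtr, Xte = X[:120], X[120:]
            ytr, yte = ys[:120], ys[120:]
            clf = build_classifier(ArchitectureSpec("fcnn", hidden_sizes=(12, 6)), (16,))
            clf, _ = train(clf, Xtr, ytr, TrainingConfig(max_epochs=10, minibatch=32, seed=seed))
            aucs.append(roc_auc(clf.predict_p_seizure(Xte), yte).auc)
        assert 0.40 <= float(np.median(aucs)) <= 0.60

    def test_single_class_data_rejected(self, rng):
        clf = build_classifier(ArchitectureSpec("fcnn", hidden_sizes=(4,)), (5,))
        with pytest.raises(ValueError, match="single class"):
            train(clf, rng.random((10, 5)), np.ones(10, int))

    def test_training_is_deterministic_given_seed(self, separable_fixture):
        X, y = separable_fixture
        outs = []
        for _ in range(2):
            clf = build_classifier(ArchitectureSpec("fcnn", hidden_sizes=(12, 6)), (16,))
            clf, _ = train(clf, X, y, TrainingConfig(max_epochs=5, minibatch=32, seed=9))
            outs.append(clf.predict_p_seizure(X))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_early_stopping_restores_best_params(self, separable_fixture):
        X, y = separable_fixture
        clf = build_classifier(ArchitectureSpec("fcnn", hidden_sizes=(12, 6)), (16,))
        clf, history = train(clf, X, y, TrainingConfig(max_epochs=40, patience_epochs=2, seed=1))
        # if stopped early, it stopped exactly patience epochs after the best one
        if len(history) < 40:
            best = min(h["val_loss"] for h in history)
            assert history[-1]["val_loss"] >= best


class TestInference:
    def test_duplicate_rows_identical_scores(self, trained_on_separable, rng):
        clf, _ = trained_on_separable
        row = rng.standard_normal(16)
        X = np.stack([row, row, row])
        s = clf.predict_p_seizure(X)
        assert s[0] == s[1] == s[2]

    def test_scores_in_unit_interval(self, trained_on_separable, rng):
        clf, _ = trained_on_separable
        s = clf.predict_p_seizure(rng.standard_normal((50, 16)) * 10)
        assert np.all((s >= 0) & (s <= 1))

    def test_dropout_off_at_inference(self, trained_on_separable, rng):
        clf, _ = trained_on_separable
        X = rng.standard_normal((20, 16))
        np.testing.assert_array_equal(clf.predict_p_seizure(X), clf.predict_p_seizure(X))

    def test_class1_cluster_scores_higher(self, separable_fixture, trained_on_separable):
        X, y = separable_fixture
        clf, _ = trained_on_separable
        s = clf.predict_p_seizure(X)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_predict_proba_wrapper_preserves_order(self, trained_on_separable, rng):
        clf, _ = trained_on_separable
        X = rng.standard_normal((9, 16))
        scored = predict_proba(clf, X, segments=list(range(9)))
        assert [s.segment for s in scored] == list(range(9))
        np.testing.assert_allclose([s.p_seizure for s in scored], clf.predict_p_seizure(X))

    def test_shape_mismatch_rejected(self, trained_on_separable, rng):
        clf, _ = trained_on_separable
        with pytest.raises(ValueError, match="shape"):
            predict_proba(clf, rng.standard_normal((4, 17)))


class TestCheckpointing:
    def test_save_load_roundtrip(self, tmp_path, trained_on_separable, rng):
        clf, _ = trained_on_separable
        save_model(clf, tmp_path / "m", meta={"modality": "raw500"})
        back = load_model(tmp_path / "m")
        X = rng.standard_normal((11, 16))
        np.testing.assert_array_equal(back.predict_p_seizure(X), clf.predict_p_seizure(X))
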
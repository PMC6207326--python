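import numpy as np
import pytest

import semgkit as sk
from semgkit.network import CnnConfig, LossWeights
from semgkit.recording import EmgRecording
from semgkit.train import (
    EvalReport,
    SequenceDataset,
    ablation_table,
    TrainConfig,
    build_sequence_dataset,
    evaluate,
    make_splits,
    run_ablation,
    select_windows,
    train_on_arrays,
)

TINY = dict(cnn=CnnConfig(conv_channels=4, local_channels=4, fc_sizes=(16, 16, 8)),
            lstm_hidden=16, attention_dim=16)


def _rec(n_classes=2, trials_per_class=3, seed=0, kind="amplitude"):
    specs = sk.simulate.default_gesture_specs(n_classes, 6, kind=kind)
    cfg = sk.SimConfig(n_channels=6, trials_per_class=trials_per_class,
                       trial_s=1.0, seed=seed)
    return sk.simulate_dataset(specs, cfg)


def _trial_rec(n_trials, labels):
    """One-frame-per... compact recording with given per-trial labels."""
    frames = 10
    rng = np.random.default_rng(0)
    data = rng.normal(size=(frames * n_trials, 2))
    lab = np.repeat(labels, frames)
    tid = np.repeat(np.arange(n_trials), frames)
    return EmgRecording(data=data, rate=100.0, labels=lab, trial_id=tid)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def test_fraction_split_ceil_rule():
    rec = _trial_rec(10, np.ones(10, dtype=int))
    train, test = make_splits(rec, "by_trial_fraction")
    assert (len(train), len(test)) == (7, 3)
    assert train == list(range(7))  # earliest trials first


def test_first_rep_train_split():
    rec = _trial_rec(9, np.repeat([1, 2, 3], 3))
    train, test = make_splits(rec, "first_rep_train")
    assert len(train) == 3 and len(test) == 6
    assert set(train).isdisjoint(test)


def test_leave_one_trial_out_folds():
    rec = _trial_rec(10, np.ones(10, dtype=int))
    folds = make_splits(rec, "leave_one_trial_out")
    assert len(folds) == 10
    all_test = []
    for train, test in folds:
        assert len(test) == 1
        assert set(train).isdisjoint(test)
        assert sorted(train + test) == list(range(10))
        all_test += test
    assert sorted(all_test) == list(range(10))


def test_split_disjointness_every_scheme():
    rec = _rec(n_classes=3, trials_per_class=4)
    for scheme in ("by_trial_fraction", "first_rep_train"):
        train, test = make_splits(rec, scheme)
        assert set(train).isdisjoint(test)
        assert sorted(train + test) == sorted(t for t, _ in rec.trials())


def test_split_errors():
    rec = _trial_rec(2, np.array([1, 2]))
    with pytest.raises(ValueError):
        make_splits(rec, "first_rep_train")
    with pytest.raises(ValueError):
        make_splits(rec, "nonsense")


# ---------------------------------------------------------------------------
# sequence dataset
# ---------------------------------------------------------------------------


def test_build_sequence_dataset_shapes():
    rec = _rec()
    windows = sk.sliding_windows(rec, 200.0, 100.0)
    fcfg = sk.FeatureConfig(feature_names=("MAV", "RMS"))
    img = build_sequence_dataset(windows, "feature_signal1", 5, feature_cfg=fcfg)
    M = sk.images.sequence_length(6)
    assert img.X.shape == (len(windows), 5, 2, 1, M)
    vec = build_sequence_dataset(windows, "raw_vector", 5)
    assert vec.X.shape == (len(windows), 5, 4 * 6)  # N=4 frames x 6 channels
    assert set(vec.y) == {0, 1}
    np.testing.assert_array_equal(vec.classes, [1, 2])


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(mode="rnn_only", representation="raw1")
    with pytest.raises(ValueError):
        TrainConfig(mode="hybrid", representation="raw_vector")
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _quick_dataset(kind="amplitude", T=4, rep="raw1", n_classes=2):
    rec = _rec(n_classes=n_classes, kind=kind)
    windows = sk.sliding_windows(rec, 200.0, 100.0)
    fcfg = sk.FeatureConfig(feature_names=("MAV", "RMS", "WL"))
    return build_sequence_dataset(windows, rep, T, feature_cfg=fcfg)


def test_training_loss_decreases_on_separable_data():
    data = _quick_dataset()
    cfg = TrainConfig(epochs=6, batch_size=16, learning_rate=0.05, seed=0,
                      T=4, mode="hybrid_attention", representation="raw1", **TINY)
    result = train_on_arrays(data, cfg)
    assert result.loss_log[-1] < result.loss_log[0]


def test_training_seed_reproducible():
    data = _quick_dataset()
    cfg = TrainConfig(epochs=2, batch_size=16, seed=3, T=4,
                      mode="hybrid", representation="raw1", **TINY)
    a = train_on_arrays(data, cfg)
    b = train_on_arrays(data, cfg)
    for p, q in zip(a.model.parameters(), b.model.parameters()):
        np.testing.assert_array_equal(p.data, q.data)
    assert a.loss_log == b.loss_log


def test_strong_l2_shrinks_weights():
    data = _quick_dataset()
    base = dict(epochs=4, batch_size=16, seed=0, T=4, mode="hybrid",
                representation="raw1", **TINY)
    free = train_on_arrays(data, TrainConfig(loss=LossWeights(lam=0.0), **base))
    tied = train_on_arrays(data, TrainConfig(loss=LossWeights(lam=10.0), **base))
    norm = lambda r: sum(float((w.data**2).sum()) for w in r.model.weight_parameters())
    assert norm(tied) < 0.1 * norm(free)


def test_single_class_data_errors():
    data = _quick_dataset()
    solo = SequenceDataset(X=data.X[data.y == 0], y=data.y[data.y == 0],
                                    trial_ids=data.trial_ids[data.y == 0],
                                    classes=data.classes)
    cfg = TrainConfig(epochs=1, T=4, mode="hybrid", representation="raw1", **TINY)
    with pytest.raises(ValueError):
        train_on_arrays(solo, cfg)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


class _StubModel:
    """Deterministic fake classifier: predicts from a fixed table."""

    def __init__(self, probs):
        self._probs = np.asarray(probs)

    def forward(self, X, training=False):
        from semgkit.network import ModelOutput
        from semgkit.tensor import Tensor
        n = X.shape[0]
        p = self._probs[:n]
        self._probs = self._probs[n:]
        return ModelOutput(per_step_probs=Tensor(np.repeat(p[:, None, :], 2, axis=1)))


def _stub_data(y, trials):
    X = np.zeros((len(y), 2, 1))
    return SequenceDataset(X=X, y=np.asarray(y),
                                    trial_ids=np.asarray(trials),
                                    classes=np.array([1, 2]))


def test_accuracy_three_of_four_windows():
    probs = np.array([[0.9, 0.1], [0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
    report = evaluate(_StubModel(probs), _stub_data([0, 0, 1, 1], [0, 0, 1, 1]))
    assert report.window_accuracy == pytest.approx(75.0)
    assert report.confusion.sum() == 4
    # Eq-style recount from the confusion matrix
    assert report.window_accuracy == pytest.approx(
        100.0 * np.trace(report.confusion) / report.confusion.sum()
    )


def test_accuracy_all_correct_and_trial_vote():
    probs = np.array([[0.6, 0.4], [0.6, 0.4], [0.4, 0.6]])
    # trial 0: windows split 2-vs-1 with equal confidences -> majority class 0
    report = evaluate(_StubModel(probs), _stub_data([0, 0, 0], [0, 0, 0]))
    assert report.trial_accuracy == pytest.approx(100.0)
    all_good = np.array([[0.9, 0.1], [0.1, 0.9]])
    report2 = evaluate(_StubModel(all_good), _stub_data([0, 1], [0, 1]))
    assert report2.window_accuracy == pytest.approx(100.0)


def test_evaluate_empty_errors():
    with pytest.raises(ValueError):
        evaluate(_StubModel(np.zeros((0, 2))), _stub_data([], []))


# ---------------------------------------------------------------------------
# ablation grid
# ---------------------------------------------------------------------------


def test_ablation_grid_cardinality_and_determinism():
    rec = _rec(n_classes=2, trials_per_class=3)
    windows = sk.sliding_windows(rec, 200.0, 100.0)
    tr, te = make_splits(rec, "by_trial_fraction")
    cfg = TrainConfig(epochs=2, batch_size=16, seed=0, **TINY)
    kwargs = dict(
        modes=["cnn_only", "hybrid"], representations=["raw1", "signal1"],
        T_values=[2], base_cfg=cfg,
    )
    rows = run_ablation(select_windows(windows, tr), select_windows(windows, te),
                        **kwargs)
    assert len(rows) == 4
    rows2 = run_ablation(select_windows(windows, tr), select_windows(windows, te),
                         **kwargs)
    assert [r["window_accuracy"] for r in rows] == [r["window_accuracy"] for r in rows2]
    table = ablation_table(rows)
    assert table.count("\n") == 4


def test_ablation_invalid_combination():
    rec = _rec(n_classes=2, trials_per_class=3)
    windows = sk.sliding_windows(rec, 200.0, 100.0)
    tr, te = make_splits(rec, "by_trial_fraction")
    cfg = TrainConfig(epochs=1, seed=0, **TINY)
    with pytest.raises(ValueError):
        run_ablation(select_windows(windows, tr), select_windows(windows, te),
                     modes=["rnn_only"], representations=["raw1"], T_values=[2],
                     base_cfg=cfg, skip_invalid=False)
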
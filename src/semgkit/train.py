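"""Training loop, split protocols, window/trial evaluation, ablation grid.

The classifier is trained by mini-batch SGD with momentum on the
composite loss. Evaluation reports accuracy as
``100 * correct / total`` at two levels: per window, and per trial
(averaging the softmax outputs of all windows of a trial before the
argmax, mirroring the average-pooling rule used within a window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from semgkit.features import FeatureConfig
from semgkit.images import (
    ChannelSequence,
    build_channel_sequence,
    activity_image1,
    activity_image2,
    feature_flatten_image,
    feature_signal_image1,
    feature_signal_image2,
    hd_grid_image,
    raw_image1,
    raw_image2,
    signal_image1,
    signal_image2,
)
from semgkit.network import (
    CnnConfig,
    HybridModel,
    LossWeights,
    ModelConfig,
    total_loss,
)
from semgkit.recording import EmgRecording
from semgkit.segment import Window, split_subsegments

VECTOR_REPRESENTATIONS = ("raw_vector", "feature_vector")
IMAGE_REPRESENTATIONS = (
    "raw1", "raw2", "signal1", "signal2", "activity1", "activity2",
    "feature_signal1", "feature_signal2", "feature_flatten", "hd_grid",
)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _trial_table(rec: EmgRecording) -> tuple[np.ndarray, np.ndarray]:
    """(trial ids, trial labels) in recording order."""
    tids, labels = [], []
    for tid, sl in rec.trials():
        tids.append(tid)
        labels.append(int(rec.labels[sl.start]))
    return np.array(tids), np.array(labels)


def make_splits(rec: EmgRecording, scheme: str, fraction: float = 2.0 / 3.0):
    """Disjoint train/test trial-id sets.

    ``scheme``:

    * ``"by_trial_fraction"`` — per class, the earliest
      ``ceil(fraction * n)`` trials train, the rest test;
    * ``"first_rep_train"`` — the first trial of each class trains, all
      remaining repetitions test;
    * ``"leave_one_trial_out"`` — returns a list of
      ``(train_ids, test_ids)`` folds, fold r testing on the r-th
      repetition of every class.
    """
    tids, labels = _trial_table(rec)
    by_class = {lab: sorted(tids[labels == lab]) for lab in np.unique(labels)}

    if scheme == "by_trial_fraction":
        train, test = [], []
        for lab, ts in by_class.items():
            k = int(np.ceil(fraction * len(ts)))
            train += ts[:k]
            test += ts[k:]
        if not test:
            raise ValueError("fraction leaves no test trials")
        return sorted(train), sorted(test)
    if scheme == "first_rep_train":
        if min(len(ts) for ts in by_class.values()) < 2:
            raise ValueError("first_rep_train needs at least 2 repetitions per class")
        train = [ts[0] for ts in by_class.values()]
        test = [t for ts in by_class.values() for t in ts[1:]]
        return sorted(train), sorted(test)
    if scheme == "leave_one_trial_out":
        n_reps = min(len(ts) for ts in by_class.values())
        if n_reps < 2:
            raise ValueError("leave-one-trial-out needs at least 2 repetitions per class")
        folds = []
        for r in range(n_reps):
            test = [ts[r] for ts in by_class.values()]
            train = [t for ts in by_class.values() for t in ts if t not in set(test)]
            folds.append((sorted(train), sorted(test)))
        return folds
    raise ValueError(f"unknown split scheme {scheme!r}")


def select_windows(windows: list[Window], trial_ids) -> list[Window]:
    keep = set(int(t) for t in trial_ids)
    return [w for w in windows if w.trial_id in keep]


# ---------------------------------------------------------------------------
# sequence datasets
# ---------------------------------------------------------------------------

_IMAGE_BUILDERS = {
    "raw1": lambda d, ctx: raw_image1(d).tensor,
    "raw2": lambda d, ctx: raw_image2(d).tensor,
    "signal1": lambda d, ctx: signal_image1(d, ctx["seq"]).tensor,
    "signal2": lambda d, ctx: signal_image2(d, ctx["seq"]).tensor,
    "activity1": lambda d, ctx: activity_image1(d, ctx["seq"]).tensor,
    "activity2": lambda d, ctx: activity_image2(d, ctx["seq"]).tensor,
    "feature_signal1": lambda d, ctx: feature_signal_image1(d, ctx["fcfg"], ctx["seq"]).tensor,
    "feature_signal2": lambda d, ctx: feature_signal_image2(d, ctx["fcfg"], ctx["seq"]).tensor,
    "feature_flatten": lambda d, ctx: feature_flatten_image(d, ctx["fcfg"]).tensor,
    "hd_grid": lambda d, ctx: hd_grid_image(d, ctx["grid"]).tensor,
}


@dataclass
class SequenceDataset:
    """Model-ready arrays: X (n, T, ...), class indices y, trial ids."""

    X: np.ndarray
    y: np.ndarray
    trial_ids: np.ndarray
    classes: np.ndarray  # original gesture labels, index -> label

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def input_shape(self):
        shape = self.X.shape[2:]
        return shape if len(shape) > 1 else (shape[0],)


def build_sequence_dataset(
    windows: list[Window],
    representation: str,
    T: int,
    feature_cfg: FeatureConfig | None = None,
    seq: ChannelSequence | None = None,
    grid: tuple[int, int] | None = None,
    classes=None,
) -> SequenceDataset:
    """Convert windows into per-subsegment sequences of images/vectors.

    ``representation`` is one of the image kinds, or ``"raw_vector"`` /
    ``"feature_vector"`` which produce flat per-subsegment vectors for
    the RNN-only mode.
    """
    if not windows:
        raise ValueError("no windows given")
    if representation not in IMAGE_REPRESENTATIONS + VECTOR_REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    from semgkit.features import extract_features  # local import to avoid cycle

    C = windows[0].n_channels
    needs_seq = representation in (
        "signal1", "signal2", "activity1", "activity2",
        "feature_signal1", "feature_signal2",
    )
    if needs_seq and seq is None:
        seq = build_channel_sequence(C)
    ctx = {"seq": seq, "fcfg": feature_cfg, "grid": grid}
    if representation == "hd_grid" and grid is None:
        raise ValueError("hd_grid representation requires a grid")

    seqs = []
    for w in windows:
        subsegs = split_subsegments(w, T)
        if representation == "raw_vector":
            steps = [s.data.ravel() for s in subsegs]
        elif representation == "feature_vector":
            steps = [extract_features(s, feature_cfg).values.ravel() for s in subsegs]
        else:
            build = _IMAGE_BUILDERS[representation]
            steps = [build(s.data, ctx) for s in subsegs]
        seqs.append(np.stack(steps))
    X = np.stack(seqs)
    labels = np.array([w.label for w in windows])
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    index = {int(lab): i for i, lab in enumerate(classes)}
    y = np.array([index[int(lab)] for lab in labels])
    trial_ids = np.array([w.trial_id for w in windows])
    return SequenceDataset(X=X, y=y, trial_ids=trial_ids, classes=classes)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Training-run configuration (optimizer, model size, representation)."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    lr_decay: float = 0.5
    decay_every: int = 10
    seed: int = 0
    T: int = 10
    mode: str = "hybrid_attention"
    representation: str = "feature_signal1"
    loss: LossWeights = field(default_factory=LossWeights)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    lstm_hidden: int = 512
    attention_dim: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode == "rnn_only":
            if self.representation not in VECTOR_REPRESENTATIONS:
                raise ValueError("rnn_only consumes raw_vector or feature_vector input")
        elif self.representation in VECTOR_REPRESENTATIONS:
            raise ValueError(f"mode {self.mode!r} needs an image representation")


@dataclass
class TrainResult:
    model: HybridModel
    loss_log: list[float]
    classes: np.ndarray


def train_on_arrays(data: SequenceDataset, cfg: TrainConfig) -> TrainResult:
    """Fit the configured model on a prepared sequence dataset."""
    if np.unique(data.y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    model_cfg = ModelConfig(
        mode=cfg.mode,
        num_classes=len(data.classes),
        input_shape=data.input_shape,
        T=cfg.T,
        cnn=cfg.cnn,
        lstm_hidden=cfg.lstm_hidden,
        attention_dim=cfg.attention_dim,
        seed=cfg.seed,
    )
    model = HybridModel(model_cfg)
    params = model.parameters()
    weight_params = model.weight_parameters()
    velocity = [np.zeros_like(p.data) for p in params]
    rng = np.random.default_rng(cfg.seed + 1)
    lr = cfg.learning_rate
    n = data.n_samples
    log: list[float] = []
    for epoch in range(cfg.epochs):
        if epoch > 0 and cfg.decay_every and epoch % cfg.decay_every == 0:
            lr *= cfg.lr_decay
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out = model.forward(data.X[idx], training=True)
            loss = total_loss(out, data.y[idx], cfg.loss, weight_params)
            value = float(loss)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            for p in params:
                p.zero_grad()
            loss.backward()
            for p, v in zip(params, velocity):
                g = p.grad if p.grad is not None else 0.0
                v *= cfg.momentum
                v -= lr * g
                p.data += v
            epoch_loss += value * len(idx)
        log.append(epoch_loss / n)
    return TrainResult(model=model, loss_log=log, classes=data.classes)


def train(
    windows: list[Window],
    cfg: TrainConfig,
    feature_cfg: FeatureConfig | None = None,
    seq: ChannelSequence | None = None,
    grid: tuple[int, int] | None = None,
) -> TrainResult:
    """Build the configured representation from windows and fit the model."""
    data = build_sequence_dataset(
        windows, cfg.representation, cfg.T, feature_cfg=feature_cfg, seq=seq, grid=grid
    )
    return train_on_arrays(data, cfg)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Accuracies in percent plus window-level confusion counts."""

    window_accuracy: float
    trial_accuracy: float | None
    confusion: np.ndarray  # (G, G), rows = true class index
    classes: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.confusion.sum())


def _pooled_probs(model: HybridModel, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Per-sample class probabilities used for prediction: the attention
    (g1) path when present, otherwise the average-pooled per-step
    softmax."""
    probs = []
    for start in range(0, X.shape[0], batch_size):
        out = model.forward(X[start : start + batch_size], training=False)
        if out.attention_probs is not None:
            probs.append(out.attention_probs.data)
        else:
            probs.append(out.per_step_probs.data.mean(axis=1))
    return np.concatenate(probs)


def evaluate(model: HybridModel, data: SequenceDataset, batch_size: int = 256) -> EvalReport:
    """Window- and trial-level accuracy (Eq. `100 * correct / total`)."""
    if data.n_samples == 0:
        raise ValueError("empty test set")
    probs = _pooled_probs(model, data.X, batch_size)
    pred = np.argmax(probs, axis=1)
    G = len(data.classes)
    confusion = np.zeros((G, G), dtype=int)
    np.add.at(confusion, (data.y, pred), 1)
    window_acc = 100.0 * np.trace(confusion) / data.n_samples

    trial_correct = trial_total = 0
    for tid in np.unique(data.trial_ids):
        mask = data.trial_ids == tid
        true = np.unique(data.y[mask])
        if true.size != 1:
            continue
        trial_pred = int(np.argmax(probs[mask].mean(axis=0)))
        trial_correct += int(trial_pred == int(true[0]))
        trial_total += 1
    trial_acc = 100.0 * trial_correct / trial_total if trial_total else None
    return EvalReport(
        window_accuracy=float(window_acc),
        trial_accuracy=trial_acc,
        confusion=confusion,
        classes=data.classes,
    )


# ---------------------------------------------------------------------------
# ablation grid
# ---------------------------------------------------------------------------


def run_ablation(
    train_windows: list[Window],
    test_windows: list[Window],
    modes: list[str],
    representations: list[str],
    T_values: list[int],
    base_cfg: TrainConfig,
    feature_cfg: FeatureConfig | None = None,
    grid: tuple[int, int] | None = None,
    skip_invalid: bool = True,
) -> list[dict]:
    """Train/evaluate every valid (mode, representation, T) cell.

    All cells share the same windows and the same seed (from
    ``base_cfg``), so rows are directly comparable. Invalid cells
    (an RNN-only mode with an image representation or vice versa) are
    skipped when ``skip_invalid`` else raise. Returns one result dict
    per cell with window/trial accuracy in percent.
    """
    rows: list[dict] = []
    seq_cache: dict[int, ChannelSequence] = {}
    for mode in modes:
        for rep in representations:
            valid = (mode == "rnn_only") == (rep in VECTOR_REPRESENTATIONS)
            if not valid:
                if skip_invalid:
                    continue
                raise ValueError(f"invalid combination mode={mode!r} representation={rep!r}")
            for T in T_values:
                cfg = replace(base_cfg, mode=mode, representation=rep, T=T)
                C = train_windows[0].n_channels
                seq = seq_cache.setdefault(C, build_channel_sequence(C))
                train_data = build_sequence_dataset(
                    train_windows, rep, T, feature_cfg=feature_cfg, seq=seq, grid=grid
                )
                result = train_on_arrays(train_data, cfg)
                test_data = build_sequence_dataset(
                    test_windows, rep, T, feature_cfg=feature_cfg, seq=seq, grid=grid,
                    classes=result.classes,
                )
                report = evaluate(result.model, test_data)
                rows.append(
                    {
                        "mode": mode,
                        "representation": rep,
                        "T": T,
                        "window_accuracy": report.window_accuracy,
                        "trial_accuracy": report.trial_accuracy,
                        "final_loss": result.loss_log[-1],
                    }
                )
    return rows


def ablation_table(rows: list[dict]) -> str:
    """Render ablation rows as a tab-separated table."""
    header = ["mode", "representation", "T", "window_accuracy", "trial_accuracy"]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r["mode"], r["representation"], str(r["T"]),
                    f"{r['window_accuracy']:.1f}",
                    "-" if r["trial_accuracy"] is None else f"{r['trial_accuracy']:.1f}",
                ]
            )
        )
    return "\n".join(lines)
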
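"""Attention-based hybrid CNN-RNN classifier for sEMG images.

Architecture (full-size defaults): two 3x3 convolutional layers (64
kernels, stride 1, same padding), two locally-connected layers with 64
unshared 1x1 kernels, three fully-connected layers (512, 512, 128
outputs), batch normalization after every conv/LC/FC map (before the
ReLU nonlinearity), dropout 0.5 on the first two FC layers. The CNN is
applied per subsegment image I_t, producing feature vectors F_t that
feed a single-layer LSTM (512 hidden units, dropout 0.5 on its output).
Each hidden state h_t goes through a shared G-way head + softmax (the
per-step g2 path, supervised by target replication); an attention layer

    M_t = tanh(W_h h_t),  alpha_t = softmax_t(w^T M_t),  r = sum_t alpha_t h_t

pools the hidden states into r, classified by its own G-way head + softmax
(the g1 path). The composite loss is

    loss = alpha * (1/T) * l(g1(X), y)
         + beta * (1/T) * sum_t l(g2(X_t), y)
         + lambda * ||w||^2

with l the cross-entropy and ||w||^2 the squared norm of all trainable
weight matrices/kernels (biases and batch-norm parameters excluded).

Ablation modes: ``cnn_only`` (per-subsegment CNN + softmax head, no
recurrence), ``rnn_only`` (subsegment vectors fed straight to the LSTM,
no CNN), ``hybrid`` (CNN -> LSTM -> per-step heads) and
``hybrid_attention`` (hybrid plus the attention path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from semgkit.tensor import Tensor, concat, conv2d_same3, einsum2, softmax, stack

PROB_EPS = 1e-12
MODES = ("cnn_only", "rnn_only", "hybrid", "hybrid_attention")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnnConfig:
    """Per-subsegment CNN feature extractor configuration.

    Defaults follow the full-size layer table: 2 conv layers x 64 3x3
    kernels, 2 locally-connected layers x 64 1x1 kernels, FC sizes
    (512, 512, 128), batch norm everywhere, dropout 0.5 on FC1/FC2.
    """

    conv_channels: int = 64
    n_conv: int = 2
    local_channels: int = 64
    n_local: int = 2
    fc_sizes: tuple[int, ...] = (512, 512, 128)
    dropout: float = 0.5


@dataclass(frozen=True)
class LossWeights:
    """Weights (alpha, beta, lam) of the composite loss."""

    alpha: float = 1.0
    beta: float = 1.0
    lam: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.lam < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("at least one of alpha, beta must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build a :class:`HybridModel`.

    ``input_shape`` is the per-subsegment image shape (color, W, H) for
    image modes, or the per-subsegment vector length for ``rnn_only``.
    ``attention_dim`` defaults to the LSTM hidden size.
    """

    mode: str
    num_classes: int
    input_shape: tuple
    T: int
    cnn: CnnConfig = field(default_factory=CnnConfig)
    lstm_hidden: int = 512
    lstm_dropout: float = 0.5
    attention_dim: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class ModelOutput:
    """Forward-pass outputs, kept as graph tensors for the loss.

    ``per_step_probs``: (B, T, G) simplex rows (the g2 path);
    ``attention_probs``: (B, G) or None (the g1 path);
    ``attention_weights``: (B, T) or None.
    """

    per_step_probs: Tensor
    attention_probs: Tensor | None = None
    attention_weights: Tensor | None = None

    @property
    def T(self) -> int:
        return self.per_step_probs.shape[-2]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def weight_parameters(self) -> list[Tensor]:
        """Parameters included in the L2 regularization term."""
        return []


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _param(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]

    def weight_parameters(self):
        return [self.W]


class Conv3x3(Layer):
    def __init__(self, rng, c_in: int, c_out: int):
        self.W = _param(rng, (c_out, c_in, 3, 3), c_in * 9)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_same3(x, self.W, self.b)

    def parameters(self):
        return [self.W, self.b]

    def weight_parameters(self):
        return [self.W]


class Local1x1(Layer):
    """Locally-connected layer: 1x1 kernels with unshared spatial weights."""

    def __init__(self, rng, c_in: int, c_out: int, h: int, w: int):
        self.W = _param(rng, (c_out, c_in, h, w), c_in)
        self.b = Tensor(np.zeros((c_out, h, w)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return einsum2("bihw,oihw->bohw", x, self.W) + self.b

    def parameters(self):
        return [self.W, self.b]

    def weight_parameters(self):
        return [self.W]


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis.

    Training mode normalizes with batch statistics and updates running
    moments; evaluation mode uses the running moments, making inference
    deterministic.
    """

    def __init__(self, n_features: int, feature_axis: int = 1, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.feature_axis = feature_axis
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(a for a in range(x.ndim) if a != self.feature_axis)
        bshape = [1] * x.ndim
        bshape[self.feature_axis] = -1
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(bshape))
            var = Tensor(self.running_var.reshape(bshape))
            xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)

    def parameters(self):
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------


@dataclass
class LstmParams:
    """Gate weights acting on the concatenation [h_{t-1}, F_t]."""

    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    W_c: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_c: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, hidden: int) -> "LstmParams":
        fan = n_in + hidden
        make_w = lambda: _param(rng, (fan, hidden), fan)
        make_b = lambda: Tensor(np.zeros(hidden), requires_grad=True)
        return cls(make_w(), make_w(), make_w(), make_w(), make_b(), make_b(), make_b(), make_b())

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[1]

    def parameters(self):
        return [self.W_i, self.W_f, self.W_o, self.W_c,
                self.b_i, self.b_f, self.b_o, self.b_c]

    def weight_parameters(self):
        return [self.W_i, self.W_f, self.W_o, self.W_c]


def lstm_step(F_t, state, p: LstmParams):
    """One LSTM update.

    ``F_t``: (B, n_in) input; ``state``: (h, c) each (B, hidden).
    Gates: i, f, o = sigmoid(W [h, F] + b); candidate c_hat = tanh(...);
    c_t = f * c_{t-1} + i * c_hat; h_t = o * tanh(c_t).
    """
    h_prev, c_prev = state
    z = concat([h_prev, F_t] if isinstance(F_t, Tensor) else
               [h_prev, Tensor(np.asarray(F_t, dtype=float))], axis=1)
    i = (z @ p.W_i + p.b_i).sigmoid()
    f = (z @ p.W_f + p.b_f).sigmoid()
    o = (z @ p.W_o + p.b_o).sigmoid()
    c_hat = (z @ p.W_c + p.b_c).tanh()
    c = f * c_prev + i * c_hat
    h = o * c.tanh()
    return h, c


@dataclass
class AttentionParams:
    """Projection W_h and scoring vector w of the attention layer."""

    W_h: Tensor
    w: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, hidden: int, proj: int) -> "AttentionParams":
        return cls(_param(rng, (hidden, proj), hidden), _param(rng, (proj, 1), proj))

    def parameters(self):
        return [self.W_h, self.w]

    def weight_parameters(self):
        return [self.W_h, self.w]


def attention_pool(hs, p: AttentionParams):
    """Softmax-weighted pooling of hidden states.

    ``hs``: list of T tensors (B, hidden). Returns (r, alpha) with
    r = sum_t alpha_t h_t of shape (B, hidden) and alpha (B, T) on the
    simplex.
    """
    H = stack([h if isinstance(h, Tensor) else Tensor(h) for h in hs], axis=1)  # (B,T,hid)
    M = einsum2("bth,hp->btp", H, p.W_h).tanh()
    scores = einsum2("btp,po->bto", M, p.w).reshape(H.shape[0], H.shape[1])  # (B,T)
    alpha = softmax(scores, axis=1)
    r = einsum2("bt,bth->bh", alpha, H)
    return r, alpha


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class HybridModel:
    """The configurable hybrid CNN-RNN gesture classifier (all four modes)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        mode, cnn = config.mode, config.cnn
        self._layers: list[Layer] = []

        if mode == "rnn_only":
            if not np.isscalar(config.input_shape) and len(np.atleast_1d(config.input_shape)) > 1:
                raise ValueError("rnn_only consumes per-subsegment vectors, not images")
            self.feature_dim = int(np.atleast_1d(config.input_shape)[0])
        else:
            c, h, w = config.input_shape
            self.convs = [
                Conv3x3(rng, c if i == 0 else cnn.conv_channels, cnn.conv_channels)
                for i in range(cnn.n_conv)
            ]
            self.conv_bns = [BatchNorm(cnn.conv_channels) for _ in range(cnn.n_conv)]
            self.locals_ = [
                Local1x1(
                    rng,
                    cnn.conv_channels if i == 0 else cnn.local_channels,
                    cnn.local_channels, h, w,
                )
                for i in range(cnn.n_local)
            ]
            self.local_bns = [BatchNorm(cnn.local_channels) for _ in range(cnn.n_local)]
            flat = cnn.local_channels * h * w
            self.fcs = []
            self.fc_bns = []
            n_in = flat
            for n_out in cnn.fc_sizes:
                self.fcs.append(Dense(rng, n_in, n_out))
                self.fc_bns.append(BatchNorm(n_out))
                n_in = n_out
            self.feature_dim = cnn.fc_sizes[-1]
            self._layers += self.convs + self.conv_bns + self.locals_ + self.local_bns
            self._layers += self.fcs + self.fc_bns

        if mode in ("rnn_only", "hybrid", "hybrid_attention"):
            self.lstm = LstmParams.init(rng, self.feature_dim, config.lstm_hidden)
            head_in = config.lstm_hidden
        else:
            self.lstm = None
            head_in = self.feature_dim
        self.head = Dense(rng, head_in, config.num_classes)

        if mode == "hybrid_attention":
            proj = config.attention_dim or config.lstm_hidden
            self.attention = AttentionParams.init(rng, config.lstm_hidden, proj)
            self.attention_head = Dense(rng, config.lstm_hidden, config.num_classes)
        else:
            self.attention = None
            self.attention_head = None

    # -- parameter access ---------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self._layers:
            params += layer.parameters()
        if self.lstm is not None:
            params += self.lstm.parameters()
        params += self.head.parameters()
        if self.attention is not None:
            params += self.attention.parameters() + self.attention_head.parameters()
        return params

    def weight_parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self._layers:
            params += layer.weight_parameters()
        if self.lstm is not None:
            params += self.lstm.weight_parameters()
        params += self.head.weight_parameters()
        if self.attention is not None:
            params += self.attention.weight_parameters()
            params += self.attention_head.weight_parameters()
        return params

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward -------------------------------------------------------
    def _dropout(self, x: Tensor, p: float, training: bool) -> Tensor:
        if not training or p <= 0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def cnn_forward(self, images, training: bool = False) -> Tensor:
        """CNN feature extractor: (B, c, h, w) images -> (B, feature_dim)."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=float))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        for conv, bn in zip(self.convs, self.conv_bns):
            x = bn(conv(x), training).relu()
        for lc, bn in zip(self.locals_, self.local_bns):
            x = bn(lc(x), training).relu()
        x = x.reshape(x.shape[0], -1)
        n_fc = len(self.fcs)
        for i, (fc, bn) in enumerate(zip(self.fcs, self.fc_bns)):
            x = bn(fc(x), training).relu()
            if i < n_fc - 1:  # dropout on FC1/FC2 only
                x = self._dropout(x, self.config.cnn.dropout, training)
        return x

    def forward(self, X, training: bool = False) -> ModelOutput:
        """Run the configured mode on a batch of subsegment sequences.

        ``X``: (B, T, c, h, w) image sequences, or (B, T, d) vectors for
        ``rnn_only``. Returns a :class:`ModelOutput` whose tensors stay
        attached to the autodiff graph (so losses can backpropagate).
        """
        X = np.asarray(X, dtype=float)
        mode = self.config.mode
        if mode == "rnn_only":
            if X.ndim == 2:
                X = X[None]
            B, T, d = X.shape
            feats = [Tensor(X[:, t]) for t in range(T)]
        else:
            if X.ndim == 4:
                X = X[None]
            B, T = X.shape[:2]
            flat = Tensor(X.reshape(B * T, *X.shape[2:]))
            F = self.cnn_forward(flat, training)  # (B*T, feat)
            F = F.reshape(B, T, self.feature_dim)
            feats = [F[:, t] for t in range(T)]

        if mode == "cnn_only":
            step_probs = [softmax(self.head(f), axis=1) for f in feats]
            return ModelOutput(per_step_probs=stack(step_probs, axis=1))

        h = Tensor(np.zeros((B, self.config.lstm_hidden)))
        c = Tensor(np.zeros((B, self.config.lstm_hidden)))
        hs = []
        for t in range(T):
            h, c = lstm_step(feats[t], (h, c), self.lstm)
            hs.append(self._dropout(h, self.config.lstm_dropout, training))
        step_probs = stack([softmax(self.head(ht), axis=1) for ht in hs], axis=1)
        if mode == "hybrid_attention":
            r, alpha = attention_pool(hs, self.attention)
            attn_probs = softmax(self.attention_head(r), axis=1)
            return ModelOutput(
                per_step_probs=step_probs, attention_probs=attn_probs,
                attention_weights=alpha,
            )
        return ModelOutput(per_step_probs=step_probs)

    __call__ = forward


# ---------------------------------------------------------------------------
# losses and predictors
# ---------------------------------------------------------------------------


def _as_prob_tensor(probs) -> Tensor:
    return probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))


def cross_entropy(probs, y):
    """-log p(true class), clamped at 1e-12; batch inputs are averaged.

    ``probs``: (G,) or (B, G) simplex rows; ``y``: class index / indices.
    Returns a scalar Tensor (use ``float()`` for the value).
    """
    p = _as_prob_tensor(probs)
    if p.ndim == 1:
        p = p.reshape(1, -1)
    y = np.atleast_1d(np.asarray(y, dtype=int))
    picked = p[np.arange(p.shape[0]), y]
    return -(picked.clip_min(PROB_EPS).log()).mean()


def attention_loss(out: ModelOutput, y, T: int | None = None):
    """(1/T) * cross-entropy of the attention (g1) path."""
    if out.attention_probs is None:
        raise ValueError("model output has no attention path")
    T = out.T if T is None else T
    return cross_entropy(out.attention_probs, y) * (1.0 / T)


def target_replication_loss(out: ModelOutput, y):
    """(1/T) * sum_t cross-entropy of each per-step (g2) prediction."""
    p = out.per_step_probs if isinstance(out, ModelOutput) else _as_prob_tensor(out)
    if p.ndim == 2:  # single sample (T, G)
        p = p.reshape(1, *p.shape)
    T = p.shape[1]
    terms = [cross_entropy(p[:, t], y) for t in range(T)]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / T)


def l2_penalty(weight_params):
    total = None
    for w in weight_params:
        term = (w**2).sum()
        total = term if total is None else total + term
    return total if total is not None else Tensor(0.0)


def total_loss(out: ModelOutput, y, weights: LossWeights, weight_params=()):
    """Composite loss: alpha * attention + beta * target replication +
    lam * sum of squared trainable weights (biases/BN excluded)."""
    loss = Tensor(0.0)
    if weights.alpha > 0 and out.attention_probs is not None:
        loss = loss + attention_loss(out, y) * weights.alpha
    if weights.beta > 0:
        loss = loss + target_replication_loss(out, y) * weights.beta
    if weights.lam > 0:
        loss = loss + l2_penalty(weight_params) * weights.lam
    return loss


def _argmax_lowest(p: np.ndarray, axis: int = -1) -> np.ndarray:
    # np.argmax already returns the first (lowest) index on ties
    return np.argmax(p, axis=axis)


def predict_average_pool(out: ModelOutput | np.ndarray):
    """Label by average-pooling the per-step softmax outputs.

    Ties go to the lowest class index. Accepts a ModelOutput or a
    (T, G) / (B, T, G) probability array; returns int or int array.
    """
    p = out.per_step_probs.data if isinstance(out, ModelOutput) else np.asarray(out)
    mean = p.mean(axis=-2)
    labels = _argmax_lowest(mean)
    return int(labels) if mean.ndim == 1 else labels


def predict_attention(out: ModelOutput | np.ndarray):
    """Label from the attention (g1) path softmax; lowest index on ties."""
    if isinstance(out, ModelOutput):
        if out.attention_probs is None:
            raise ValueError("model output has no attention path")
        p = out.attention_probs.data
    else:
        p = np.asarray(out)
    labels = _argmax_lowest(p)
    return int(labels) if p.ndim == 1 else labels
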
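import math

import numpy as np
import pytest

from semgkit.network import (
    AttentionParams,
    CnnConfig,
    HybridModel,
    LossWeights,
    LstmParams,
    ModelConfig,
    ModelOutput,
    attention_loss,
    attention_pool,
    cross_entropy,
    lstm_step,
    predict_attention,
    predict_average_pool,
    target_replication_loss,
    total_loss,
)
from semgkit.tensor import Tensor


def _t(x, grad=False):
    return Tensor(np.asarray(x, dtype=float), requires_grad=grad)


def _lstm_params(n_in, hidden, fill=0.0):
    z = lambda shape: Tensor(np.full(shape, fill), requires_grad=True)
    return LstmParams(
        W_i=z((n_in + hidden, hidden)), W_f=z((n_in + hidden, hidden)),
        W_o=z((n_in + hidden, hidden)), W_c=z((n_in + hidden, hidden)),
        b_i=z(hidden), b_f=z(hidden), b_o=z(hidden), b_c=z(hidden),
    )


# ---------------------------------------------------------------------------
# LSTM step
# ---------------------------------------------------------------------------


def test_lstm_zero_weights_give_zero_state(rng):
    p = _lstm_params(3, 2, fill=0.0)
    h0 = _t(np.zeros((4, 2)))
    c0 = _t(np.zeros((4, 2)))
    h, c = lstm_step(rng.normal(size=(4, 3)), (h0, c0), p)
    np.testing.assert_array_equal(h.data, 0.0)
    np.testing.assert_array_equal(c.data, 0.0)


def test_lstm_ranges(rng):
    p = _lstm_params(3, 5, fill=0.7)
    h = _t(np.zeros((2, 5)))
    c = _t(np.zeros((2, 5)))
    for _ in range(4):
        h, c = lstm_step(rng.normal(size=(2, 3)), (h, c), p)
    assert np.all(np.abs(h.data) < 1.0)


def test_lstm_scalar_manual_oracle():
    """1-dim LSTM with hand-set weights vs an explicit spreadsheet-style
    computation, to 1e-12."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    wi, wf, wo, wc = (0.5, 0.3), (-0.2, 0.4), (0.1, -0.6), (0.7, 0.2)
    bi, bf, bo, bc = 0.05, -0.1, 0.2, 0.0
    p = LstmParams(
        W_i=_t([[wi[0]], [wi[1]]]), W_f=_t([[wf[0]], [wf[1]]]),
        W_o=_t([[wo[0]], [wo[1]]]), W_c=_t([[wc[0]], [wc[1]]]),
        b_i=_t([bi]), b_f=_t([bf]), b_o=_t([bo]), b_c=_t([bc]),
    )
    h_prev, c_prev, x = 0.3, -0.4, 0.9
    h, c = lstm_step(np.array([[x]]), (_t([[h_prev]]), _t([[c_prev]])), p)
    i = sig(h_prev * wi[0] + x * wi[1] + bi)
    f = sig(h_prev * wf[0] + x * wf[1] + bf)
    o = sig(h_prev * wo[0] + x * wo[1] + bo)
    c_hat = math.tanh(h_prev * wc[0] + x * wc[1] + bc)
    c_exp = f * c_prev + i * c_hat
    h_exp = o * math.tanh(c_exp)
    assert c.data[0, 0] == pytest.approx(c_exp, abs=1e-12)
    assert h.data[0, 0] == pytest.approx(h_exp, abs=1e-12)


# ---------------------------------------------------------------------------
# attention pooling
# ---------------------------------------------------------------------------


def test_attention_single_step_is_identity(rng):
    p = AttentionParams.init(np.random.default_rng(0), hidden=4, proj=3)
    h1 = rng.normal(size=(2, 4))
    r, alpha = attention_pool([h1], p)
    np.testing.assert_allclose(r.data, h1, atol=1e-12)
    np.testing.assert_allclose(alpha.data, 1.0, atol=1e-12)


def test_attention_identical_states_uniform_weights(rng):
    p = AttentionParams.init(np.random.default_rng(0), hidden=4, proj=4)
    h = rng.normal(size=(3, 4))
    r, alpha = attention_pool([h, h, h, h], p)
    np.testing.assert_allclose(alpha.data, 0.25, atol=1e-12)
    np.testing.assert_allclose(r.data, h, atol=1e-12)


def test_attention_manual_softmax_oracle():
    """T=3, 2-dim hidden states with hand-set parameters vs an explicit
    softmax computation, to 1e-12."""
    Wh = np.array([[0.5, -0.3], [0.2, 0.8]])
    w = np.array([[1.0], [-0.5]])
    hs = [np.array([[0.4, -0.2]]), np.array([[1.0, 0.5]]), np.array([[-0.3, 0.9]])]
    p = AttentionParams(W_h=_t(Wh), w=_t(w))
    r, alpha = attention_pool([_t(h) for h in hs], p)
    scores = [float((np.tanh(h @ Wh) @ w)[0, 0]) for h in hs]
    e = np.exp(np.array(scores) - max(scores))
    a_exp = e / e.sum()
    r_exp = sum(a * h for a, h in zip(a_exp, hs))
    np.testing.assert_allclose(alpha.data[0], a_exp, atol=1e-12)
    np.testing.assert_allclose(r.data, r_exp, atol=1e-12)
    np.testing.assert_allclose(alpha.data.sum(), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def test_cross_entropy_uniform_and_certain():
    uniform = np.full(52, 1.0 / 52)
    assert float(cross_entropy(uniform, 0)) == pytest.approx(math.log(52), abs=1e-10)
    certain = np.zeros(5)
    certain[3] = 1.0
    assert float(cross_entropy(certain, 3)) == pytest.approx(0.0, abs=1e-10)


def test_cross_entropy_matches_indicator_sum(rng):
    for _ in range(20):
        logits = rng.normal(size=6)
        p = np.exp(logits) / np.exp(logits).sum()
        y = int(rng.integers(6))
        brute = -sum((1.0 if i == y else 0.0) * math.log(p[i]) for i in range(6))
        assert float(cross_entropy(p, y)) == pytest.approx(brute, abs=1e-12)


def test_cross_entropy_clamps_zero_probability():
    p = np.zeros(4)
    p[0] = 1.0
    val = float(cross_entropy(p, 2))
    assert val == pytest.approx(-math.log(1e-12))


def _output(per_step, attn=None):
    return ModelOutput(
        per_step_probs=_t(per_step),
        attention_probs=None if attn is None else _t(attn),
    )


def test_attention_loss_scales_inversely_with_T(rng):
    probs = rng.dirichlet(np.ones(4))
    base = float(cross_entropy(probs, 1))
    out1 = ModelOutput(per_step_probs=_t(np.tile(probs, (1, 1, 1))), attention_probs=_t(probs))
    assert float(attention_loss(out1, 1, T=1)) == pytest.approx(base, abs=1e-12)
    assert float(attention_loss(out1, 1, T=2)) == pytest.approx(base / 2, abs=1e-12)
    assert float(attention_loss(out1, 1, T=4)) == pytest.approx(base / 4, abs=1e-12)


def test_target_replication_perfect_and_identical(rng):
    T, G = 5, 4
    perfect = np.zeros((1, T, G))
    perfect[:, :, 2] = 1.0
    assert float(target_replication_loss(_output(perfect), 2)) == pytest.approx(0.0, abs=1e-10)
    p = rng.dirichlet(np.ones(G))
    identical = np.tile(p, (1, T, 1))
    assert float(target_replication_loss(_output(identical), 1)) == pytest.approx(
        float(cross_entropy(p, 1)), abs=1e-12
    )


def test_target_replication_matches_brute_sum(rng):
    T, G = 4, 5
    probs = rng.dirichlet(np.ones(G), size=T)
    y = 3
    brute = sum(-math.log(probs[t, y]) for t in range(T)) / T
    assert float(target_replication_loss(_output(probs[None]), y)) == pytest.approx(
        brute, abs=1e-12
    )


def test_total_loss_components_and_linearity(rng):
    probs = rng.dirichlet(np.ones(3), size=(1, 2))
    attn = rng.dirichlet(np.ones(3))[None]
    out = _output(probs, attn)
    w = [_t(rng.normal(size=(2, 2)), grad=True)]
    reg = float(sum((w[0].data ** 2).sum() for _ in [0]))
    att = float(attention_loss(out, 0))
    tar = float(target_replication_loss(out, 0))

    def L(a, b, lam):
        return float(total_loss(out, 0, LossWeights(alpha=a, beta=b, lam=lam), w))

    assert L(1.0, 0.0, 0.0) == pytest.approx(att, abs=1e-12)
    assert L(0.0, 1.0, 0.0) == pytest.approx(tar, abs=1e-12)
    assert L(1.0, 1.0, 2.0) == pytest.approx(att + tar + 2.0 * reg, abs=1e-10)
    # linearity in each coefficient (equal finite differences)
    for f in (lambda a: L(a, 0.7, 0.1), lambda b: L(0.7, b, 0.1),
              lambda l: L(0.7, 0.7, l)):
        d1 = f(1.0) - f(0.5)
        d2 = f(1.5) - f(1.0)
        assert d1 == pytest.approx(d2, abs=1e-10)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(alpha=0.0, beta=0.0)
    with pytest.raises(ValueError):
        LossWeights(alpha=-1.0)


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


def test_predict_average_pool_example_and_tie():
    probs = np.array([[0.6, 0.4], [0.1, 0.9]])  # mean [0.35, 0.65]
    assert predict_average_pool(probs) == 1
    agree = np.tile([0.2, 0.1, 0.7], (4, 1))
    assert predict_average_pool(agree) == 2
    tie = np.array([[0.5, 0.5]])
    assert predict_average_pool(tie) == 0  # lowest index wins


def test_predict_attention_paths():
    out = ModelOutput(
        per_step_probs=_t(np.tile([0.9, 0.1], (1, 3, 1))),
        attention_probs=_t([[0.2, 0.8]]),
    )
    assert predict_attention(out) == 1
    assert predict_average_pool(out) == 0
    assert predict_attention(np.array([0.4, 0.4, 0.2])) == 0
    no_attn = _output(np.tile([0.9, 0.1], (1, 3, 1)))
    with pytest.raises(ValueError):
        predict_attention(no_attn)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

_TINY_CNN = CnnConfig(conv_channels=4, local_channels=4, fc_sizes=(8, 8, 6), dropout=0.5)


def _model(mode, input_shape=(2, 1, 9), T=3, G=4, seed=0):
    return HybridModel(ModelConfig(
        mode=mode, num_classes=G, input_shape=input_shape, T=T,
        cnn=_TINY_CNN, lstm_hidden=5, attention_dim=5, seed=seed,
    ))


def test_cnn_forward_feature_length_and_eval_determinism(rng):
    m = _model("cnn_only")
    img = rng.normal(size=(3, 2, 1, 9))
    f1 = m.cnn_forward(img, training=False).data
    f2 = m.cnn_forward(img, training=False).data
    assert f1.shape == (3, 6)  # last FC size
    np.testing.assert_array_equal(f1, f2)


@pytest.mark.parametrize("mode", ["cnn_only", "rnn_only", "hybrid", "hybrid_attention"])
def test_all_modes_run_and_obey_simplex_invariants(rng, mode):
    G, T, B = 4, 3, 5
    if mode == "rnn_only":
        m = _model(mode, input_shape=(7,))
        X = rng.normal(size=(B, T, 7))
    else:
        m = _model(mode)
        X = rng.normal(size=(B, T, 2, 1, 9))
    out = m.forward(X, training=False)
    p = out.per_step_probs.data
    assert p.shape == (B, T, G)
    np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
    assert (p >= 0).all()
    if mode == "hybrid_attention":
        assert out.attention_probs.data.shape == (B, G)
        np.testing.assert_allclose(out.attention_probs.data.sum(axis=1), 1.0, atol=1e-6)
        assert out.attention_weights.data.shape == (B, T)
        np.testing.assert_allclose(out.attention_weights.data.sum(axis=1), 1.0, atol=1e-6)
    else:
        assert out.attention_probs is None


def test_cnn_only_single_step_is_plain_cnn_classifier(rng):
    m = _model("cnn_only", T=1)
    X = rng.normal(size=(2, 1, 2, 1, 9))
    out = m.forward(X, training=False)
    direct = m.cnn_forward(X[:, 0], training=False)
    from semgkit.tensor import softmax as sm
    expected = sm(m.head(direct), axis=1).data
    np.testing.assert_allclose(out.per_step_probs.data[:, 0], expected, atol=1e-12)


def test_eval_forward_bit_stable(rng):
    m = _model("hybrid_attention")
    X = rng.normal(size=(2, 3, 2, 1, 9))
    a = m.forward(X, training=False)
    b = m.forward(X, training=False)
    np.testing.assert_array_equal(a.per_step_probs.data, b.per_step_probs.data)
    np.testing.assert_array_equal(a.attention_probs.data, b.attention_probs.data)


def test_same_seed_same_parameters():
    a, b = _model("hybrid", seed=7), _model("hybrid", seed=7)
    for p, q in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(p.data, q.data)


def test_parameter_count_matches_closed_form():
    """Hand-derived parameter count, incl. per-location LC weights."""
    c_in, h, w = 2, 1, 9
    k, fc = 4, (8, 8, 6)
    G, hid, proj, T = 4, 5, 5, 3
    conv = (k * c_in * 9 + k) + (k * k * 9 + k)
    conv_bn = 2 * (2 * k)
    lc = 2 * (k * k * h * w + k * h * w)
    lc_bn = 2 * (2 * k)
    flat = k * h * w
    dense = (flat * fc[0] + fc[0]) + (fc[0] * fc[1] + fc[1]) + (fc[1] * fc[2] + fc[2])
    fc_bn = sum(2 * n for n in fc)
    lstm = 4 * ((fc[2] + hid) * hid + hid)
    head = hid * G + G
    attn = hid * proj + proj
    attn_head = hid * G + G
    expected = conv + conv_bn + lc + lc_bn + dense + fc_bn + lstm + head + attn + attn_head
    assert _model("hybrid_attention").num_parameters() == expected


def test_invalid_configs_error():
    with pytest.raises(ValueError):
        ModelConfig(mode="transformer", num_classes=3, input_shape=(2, 1, 9), T=2)
    with pytest.raises(ValueError):
        ModelConfig(mode="hybrid", num_classes=1, input_shape=(2, 1, 9), T=2)
    with pytest.raises(ValueError):
        HybridModel(ModelConfig(mode="rnn_only", num_classes=3, input_shape=(2, 1, 9), T=2))


# ---------------------------------------------------------------------------
# gradient check (tiny model)
# ---------------------------------------------------------------------------


def test_total_loss_gradient_matches_finite_differences(rng):
    """Finite-difference gradient of the composite loss on a tiny
    hybrid-attention model matches reverse-mode autodiff to 1e-4
    relative (dropout disabled; training-mode batch statistics)."""
    cfg = ModelConfig(
        mode="hybrid_attention", num_classes=3, input_shape=(2, 1, 5), T=2,
        cnn=CnnConfig(conv_channels=3, local_channels=3, fc_sizes=(4, 4, 3), dropout=0.0),
        lstm_hidden=2, lstm_dropout=0.0, attention_dim=2, seed=0,
    )
    m = HybridModel(cfg)
    X = rng.normal(size=(4, 2, 2, 1, 5))
    y = np.array([0, 1, 2, 0])
    lw = LossWeights(alpha=1.0, beta=1.0, lam=1e-3)

    def loss_value():
        return float(total_loss(m.forward(X, training=True), y, lw, m.weight_parameters()))

    params = m.parameters()
    for p in params:
        p.zero_grad()
    loss = total_loss(m.forward(X, training=True), y, lw, m.weight_parameters())
    loss.backward()
    h = 1e-5
    check_rng = np.random.default_rng(1)
    for p in params:
        grad = p.grad if p.grad is not None else np.zeros_like(p.data)
        for flat in check_rng.choice(p.data.size, size=min(3, p.data.size), replace=False):
            idx = np.unravel_index(flat, p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + h
            lp = loss_value()
            p.data[idx] = orig - h
            lm = loss_value()
            p.data[idx] = orig
            fd = (lp - lm) / (2 * h)
            rel = abs(fd - grad[idx]) / max(abs(fd), abs(grad[idx]), 1e-6)
            assert rel < 1e-4, f"grad mismatch at {p.shape}{idx}: fd={fd} ad={grad[idx]}"
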
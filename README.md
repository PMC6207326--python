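# semgkit

Gesture recognition from multi-channel surface electromyography (sEMG),
for researchers prototyping myoelectric pattern-recognition pipelines:
signal preprocessing and overlapped windowing, classical time-domain
features, a family of signal-to-image representations for sparse
multi-channel and high-density grid recordings, and an attention-based
hybrid CNN-RNN classifier — all runnable end-to-end on a bundled,
seed-deterministic synthetic sEMG generator, with no external database
or GPU required.

## The method

A window **X** of L frames x C channels is split into T consecutive
subsegments **X**_t (N = floor(L/T) frames each). Each subsegment is
rendered as a small image **I**_t and a CNN (3x3 convolutions,
locally-connected 1x1 layers with unshared weights, three FC layers,
batch norm throughout, dropout on the first two FC layers) maps it to a
feature vector **F**_t. An LSTM consumes the sequence
{**F**_1, ..., **F**_T}; each hidden state h_t feeds a shared G-way
softmax head, and an attention layer pools the hidden states:

    M_t = tanh(W_h h_t),   alpha_t = softmax_t(w^T M_t),   r = sum_t alpha_t h_t

with r classified by its own G-way softmax. Training minimizes

    loss = alpha * (1/T) * l(g1(X), y)  +  beta * (1/T) * sum_t l(g2(X_t), y)  +  lambda * ||w||^2

where g1 is the attention path, g2 the per-step path, l the
cross-entropy, and ||w||^2 the squared norm of the trainable weights.
Ablation modes `cnn_only`, `rnn_only`, `hybrid` and `hybrid_attention`
isolate each stage.

The key representation is the **signal image**: channels are rearranged
into an Eulerian-circuit sequence over the complete channel graph so
that *every pair of channels is adjacent at least once* (length
C^2/2 + 1 for even C — 51 for 10 channels), letting 3x3 kernels see all
pairwise channel relations. **feature-signal-image1** applies the same
rearrangement to per-channel feature vectors (MAV, RMS, WL, ZC, SSC,
WAMP, sample entropy, AR and cepstral coefficients, configurable) instead
of raw frames. Raw reshapes, 2-D-DFT "activity" images, flat feature
vectors and row-major high-density grid images complete the family.

The network runs on a small reverse-mode autodiff engine over float64
NumPy arrays included in the package (`semgkit.tensor`); gradient
correctness is pinned by finite-difference checks in the test suite.

## Worked example

`examples/03_train_classifier.py` trains the attention-based hybrid
CNN-RNN on the default synthetic dataset (4 gesture classes, 10
channels, 100 Hz, 10 trials per class) using feature-signal-image1 with
T = 10 subsegments per 200 ms window and a 2/3-by-trial split:

```text
train 812 windows, test 348 windows
per-window input: (10, 4, 1, 51) (T x color x W x H)
per-epoch loss: 1.915 1.624 1.111 0.764 0.648 0.593 0.548 0.550 0.541 0.523
held-out window accuracy: 99.1%
held-out trial accuracy:  100.0%
confusion (rows = true class):
[[87  0  0  0]
 [ 1 85  1  0]
 [ 0  0 87  0]
 [ 1  0  0 86]]
```

Each per-window input is a sequence of ten 4 x 1 x 51 images — four
features per channel laid out on the length-51 all-pairs-adjacent
channel sequence. The accuracies are Eq.-style
`100 * correct / total` on trials the model never saw during training;
the trial label aggregates all window predictions of a repetition.

The other examples cover the generator and windowing arithmetic
(`01_simulate_and_segment.py`), every image representation and its shape
(`02_image_representations.py`), and the architecture x representation
ablation grid on correlation-coded data where only channel-pair
structure distinguishes classes (`04_ablation_grid.py`).

A thin CLI mirrors the library: `semg simulate | segment | featurize |
imagify | train | ablate | sequence` (see `semg --help`).

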
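# Methods

`semgkit` implements window-based gesture classification from
multi-channel surface EMG: preprocessing, segmentation, a bank of
classical time-domain features, a family of signal-to-image
representations, and an attention-based hybrid CNN-RNN classifier with a
composite loss, all exercised end-to-end on a bundled synthetic
generator. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Signal model and segmentation

A recording is a frames x channels matrix with sampling rate, per-frame
gesture labels (0 = rest) and per-frame trial indices; trials are
contiguous frame runs with a single label. Preprocessing follows the
standard myoelectric chain: zero-phase Butterworth low-pass (order 4 by
default; the cutoff is a required argument because no single value suits
all recording setups), full-wave rectification, and integer decimation
with an anti-alias filter. Two details worth knowing:

* The decimator's anti-alias stage (order-8 Chebyshev, zero-phase, as in
  `scipy.signal.decimate`) has a passband ripple that leaves DC about
  1.1% low after the two passes. `antialias=False` gives exact frame
  dropping, which also commutes exactly with window extraction;
  filtering before or after windowing cannot agree exactly at window
  edges, so the commutation property only holds for the pure-decimation
  path.
* Windows are half-open `[start, start + L)` at 0-based frame indices,
  generated strictly within trials (a window never straddles a trial
  boundary, so mixed-label windows cannot arise), and inherit the
  trial's label. A trial of F frames yields `floor((F - L) / S) + 1`
  windows at stride S.

Each window X is split into T consecutive, non-overlapping subsegments
X_t of `N = floor(L / T)` frames; trailing frames are dropped. The
subsegments are the RNN's time steps. Non-overlap is the one choice that
keeps `T * N <= L` for every T up to L, and it makes the
split-then-concatenate identity exact.

## Feature bank

Per channel: MAV, RMS, WL (amplitude), ZC, SSC, WAMP (threshold counts,
thresholds default 0), sample entropy (m = 2, tolerance 0.2 x channel
sd, Chebyshev distance, matches counted with <=, population sd; a
configurable cap — default 10 — stands in for the infinite value when no
m+1 template pair matches), and AR / cepstral coefficients of
configurable order (default 4 each). The feature set is
configuration-driven — an ordered, duplicate-free name list — because
published "time-domain feature set" recipes vary; the default set
{MAV, WL, ZC, SSC, RMS, SampEn, CC(4), AR(4)} has per-channel dimension
D = 14.

AR uses the Yule-Walker equations with biased autocorrelation estimates
under the prediction convention `x_t ~ sum_k a_k x_{t-k}`. The cepstral
coefficients apply the standard myoelectric recursion to those
coefficients (`c_1 = -a_1`, then
`c_n = -a_n - sum_l (1 - l/n) a_l c_{n-l}`); the sign convention is
stated in the code because the recursion flips with it.

Short subsegments constrain the usable set: at N = 2 frames only
MAV/RMS/WL/ZC/WAMP are defined, which is why the worked examples use
{MAV, RMS, WL, ZC} when T = 10 splits a 20-frame window.

## Image representations

For sparse multi-channel recordings a window (or subsegment) of L frames
x C channels becomes a (color, width, height) tensor:

* **raw-image1 / raw-image2** — lossless reshapes L x 1 x C and
  1 x L x C.
* **signal-image1 / signal-image2** — the channel axis is replaced by a
  rearranged channel sequence in which every unordered channel pair is
  adjacent at least once, so small square kernels can see every pairwise
  channel relation. The sequence is an Eulerian circuit of the complete
  graph K_C — augmented with the perfect matching (0,1), (2,3), ... when
  C is even to make all degrees even — traversed by Hierholzer's
  algorithm with lowest-index-neighbor tie-breaking from channel 0.
  This is deterministic, guarantees all-pairs adjacency, and has length
  C^2/2 + 1 (even C) or C(C-1)/2 + 1 (odd C): 51 for C = 10.
* **activity-image1 / activity-image2** — magnitude of the 2-D DFT taken
  over the (frame, rearranged-channel) plane of the corresponding
  signal-image. The axis convention (2-D transform over that plane) is a
  design choice; the representation is checked against a naive
  double-loop DFT.
* **feature-signal-image1 / 2** — the per-channel feature vectors
  (C x D) laid out on the same all-pairs-adjacent sequence, feature axis
  as color: D x 1 x M and 1 x D x M. The D-as-color orientation mirrors
  frames-as-color in the raw/signal images.
* **feature-flatten-image** — 1 x 1 x (C*D), channels concatenated
  row-major; the baseline that discards adjacency structure.
* **hd-grid-image** — high-density electrode grids map channel k to grid
  cell (k div cols, k mod cols), giving L x rows x cols. Real arrays'
  electrode maps are the caller's responsibility; the synthetic grid
  generator uses the same row-major convention.

## Classifier

Per subsegment image, a CNN: two 3x3 convolutions (stride 1, same
padding, so spatial size survives to the locally-connected stage), two
locally-connected layers with unshared 1x1 kernels, then three
fully-connected layers; batch normalization after every linear map,
before the ReLU; dropout 0.5 on the first two FC layers. Full-size layer
widths are 64/64/64/64 kernels and 512-512-128 FC outputs; all widths
are configurable, and the bundled experiments use compact variants
(e.g. 16 kernels, 64-64-32) sized for single-CPU training. ReLU and the
BN-before-nonlinearity placement are the contemporaneous defaults; both
are configuration-independent implementation choices.

The T per-subsegment feature vectors feed a single-layer LSTM (standard
gates on the concatenation [h_{t-1}, F_t]; 512 hidden units full-size,
dropout 0.5 on its outputs). Each hidden state goes through a shared
G-way softmax head (the per-step path); an attention layer computes
M_t = tanh(W_h h_t), alpha = softmax_t(w^T M_t), r = sum_t alpha_t h_t,
and r goes through its own G-way head (the attention path). The
projection width of W_h defaults to the hidden size.

Ablation modes: `cnn_only` (heads directly on CNN features, prediction
by average-pooling the per-step softmax), `rnn_only` (flattened
subsegment vectors straight into the LSTM), `hybrid` (CNN -> LSTM ->
per-step heads, average-pool prediction) and `hybrid_attention` (adds
the attention path, which is also its inference rule).

The loss is `alpha * (1/T) * CE(attention path) + beta * (1/T) *
sum_t CE(per-step path) + lambda * ||w||^2` with defaults alpha = beta =
1, lambda = 1e-4. The 1/T factor on the attention term is kept exactly
as written even though it only rescales one term. The L2 norm covers
weight matrices and kernels but not biases or batch-norm parameters.
Probabilities are clamped at 1e-12 inside the cross-entropy. At least
one of alpha, beta must be positive. Argmax ties resolve to the lowest
class index.

## Training and evaluation

Mini-batch SGD with momentum 0.9 and step decay (halve every 10 epochs
by default); everything — epochs, batch size, learning rate, decay — is
configuration. All randomness (parameter init, dropout masks, batch
shuffling) keys off one seed, so identical config + seed reproduces
parameters bit-for-bit. Batch norm uses batch statistics in training and
running moments at evaluation, making inference deterministic.

Split protocols operate on trial ids per class: earliest
`ceil(fraction * n)` trials to train (fraction 2/3 default),
first-repetition-train, and leave-one-trial-out folds. Accuracy is
`100 * correct / total`, reported per window and per trial; the trial
label is the argmax of the mean softmax over the trial's windows, the
same averaging rule used across subsegments within a window.

The network stack runs on a small in-package reverse-mode autodiff
engine over float64 NumPy arrays (`semgkit.tensor`). The 3x3 convolution
is im2col + BLAS matmul; the locally-connected and attention
contractions are two-operand einsums with analytically derived adjoint
einsums. Gradient correctness is pinned by a finite-difference check
(central differences, h = 1e-5, agreement to 1e-4 relative) on a tiny
end-to-end model.

## Synthetic data

Each gesture class is an amplitude-modulated correlated-noise process:
a trapezoidal attack-hold-release envelope with per-channel peaks, a
band-limited Gaussian carrier (Butterworth band-pass, standardized per
channel, mixed by the Cholesky factor of a class-specific SPD
correlation matrix), plus white baseline noise whose variance is the
mean hold-phase envelope power divided by `snr` (default 20, a clean
laboratory recording). Per-channel hold-phase RMS is then the spec peak
times `sqrt(1 + 1/snr)`, which is what the generator tests assert.

This construction deliberately is not a physiological motor-unit
simulation: there are no action-potential shapes, no recruitment or
firing-rate structure, no electrode lift-off or motion artifacts, and
within the hold phase the process is stationary. What it does provide,
controllably, are the two statistical handles the representations rely
on — class-specific per-channel amplitude (exercising MAV/RMS/WL-based
features and images) and class-specific inter-channel correlation
(exercising the all-pairs-adjacent rearrangement). Passing the
end-to-end tests therefore shows that the pipeline recovers planted
amplitude and correlation structure, not that any accuracy level carries
over to recorded human sEMG.

Spec factories: `default_gesture_specs(G, C, kind)` with `kind`
"amplitude" (raised-cosine peak patterns per class, mild common
neighbour correlation), "correlation" (identical flat peaks, strongly
correlated class-specific distant channel pairs — chosen disjoint so the
matrix stays SPD), or "both". `default_hd_specs` places one 2-D Gaussian
activation centre per class on the electrode grid with a
distance-decaying (exponential-kernel) correlation.

## Study problem sizes

The bundled experiments are sized for a single CPU:

* End-to-end recovery: the default fixture (4 classes, 10 channels,
  100 Hz, 10 trials per class, 3 s trials), 200 ms windows at 100 ms
  step, T = 10, features {MAV, RMS, WL, ZC}, compact model (16 kernels,
  FC 64-64-32, LSTM 64), 10 epochs. Held-out window accuracy lands
  around 99% against the >= 95% assertion.
* Ablation grid: correlation-coded data (8 trials per class, 2 s
  trials), T = 5, an even smaller model (8 kernels, FC 32-32-16,
  LSTM 48), 25 epochs, 2 modes x 2 representations x 5 seeds. The
  asserted orderings are means over seeds: signal-image1 over
  raw-image1, and hybrid over CNN-only.

## Known limitations

* The synthetic generator omits every physiological and instrumental
  nuisance listed above; results quantify pipeline correctness, not
  field performance.
* `rnn_only` consumes flattened subsegment vectors; it shares no
  parameters with the CNN modes, so cross-mode comparisons are
  architecture comparisons, not nested-model tests.
* The engine is single-threaded NumPy; full-size layer widths (64
  kernels, 512-wide FC/LSTM) train only at toy dataset scale.
* Batch-norm running statistics are updated with a fixed momentum of
  0.1 and are not part of the loss; very small batches make evaluation
  statistics noisy.
* The high-density path reshapes channels row-major; mapping a real
  array's electrode layout to that order is out of scope.
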
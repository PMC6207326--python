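"""sEMG image representations for sparse multi-channel and grid recordings.

A window (or subsegment) of L frames x C channels is re-expressed as a
small "image" tensor of shape (color, width, height) so that
convolutional models can be applied:

* ``raw-image1`` / ``raw-image2`` — lossless reshapes, L x 1 x C and
  1 x L x C.
* ``signal-image1`` / ``signal-image2`` — the channel axis is replaced
  by a rearranged channel sequence in which every pair of distinct
  channels appears adjacently at least once, so 3x3 kernels can see all
  pairwise channel relations. The sequence is an Eulerian circuit of the
  complete graph over channels (plus a perfect matching when C is even,
  to make all degrees even), giving length C^2/2 + 1 for even C and
  C(C-1)/2 + 1 for odd C >= 3.
* ``activity-image1`` / ``activity-image2`` — magnitude of the 2-D DFT
  of the corresponding signal-image plane.
* ``feature-signal-image1/2`` and ``feature-flatten-image`` — the same
  constructions applied to per-channel feature vectors instead of raw
  frames.
* ``hd-grid-image`` — high-density electrode grids mapped to
  L x rows x cols with channels laid out row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from semgkit.features import FeatureConfig, extract_features
from semgkit.segment import Subsegment, Window

IMAGE_KINDS = (
    "raw1",
    "raw2",
    "signal1",
    "signal2",
    "activity1",
    "activity2",
    "feature_signal1",
    "feature_signal2",
    "feature_flatten",
    "hd_grid",
)


@dataclass(frozen=True)
class ChannelSequence:
    """A channel ordering in which every channel pair is adjacent at least once."""

    order: tuple[int, ...]
    n_channels: int

    def __len__(self) -> int:
        return len(self.order)


def sequence_length(C: int) -> int:
    """Closed-form length of the all-pairs-adjacent channel sequence."""
    if C % 2 == 0:
        return C * C // 2 + 1
    return C * (C - 1) // 2 + 1


def build_channel_sequence(C: int) -> ChannelSequence:
    """Deterministic all-pairs-adjacent channel rearrangement.

    Construct the complete graph K_C over channels 0..C-1; when C is
    even (all vertex degrees odd) add the perfect matching
    (0,1), (2,3), ... so every degree becomes even; then traverse an
    Eulerian circuit with Hierholzer's algorithm, always taking the
    lowest-index available neighbor, starting from channel 0. Every edge
    of K_C is traversed, so every unordered channel pair is adjacent
    somewhere in the output.
    """
    if C < 2:
        raise ValueError("need at least 2 channels for a channel sequence")
    # multigraph adjacency as neighbor -> multiplicity
    adj: list[dict[int, int]] = [dict() for _ in range(C)]

    def add_edge(u: int, v: int) -> None:
        adj[u][v] = adj[u].get(v, 0) + 1
        adj[v][u] = adj[v].get(u, 0) + 1

    for u in range(C):
        for v in range(u + 1, C):
            add_edge(u, v)
    if C % 2 == 0:
        for u in range(0, C, 2):
            add_edge(u, u + 1)

    stack = [0]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            u = min(adj[v])
            for a, b in ((v, u), (u, v)):
                adj[a][b] -= 1
                if adj[a][b] == 0:
                    del adj[a][b]
            stack.append(u)
        else:
            circuit.append(stack.pop())
    order = tuple(reversed(circuit))
    assert len(order) == sequence_length(C)
    return ChannelSequence(order=order, n_channels=C)


@dataclass
class SemgImage:
    """An image-shaped view of a window: (color, width, height) tensor."""

    tensor: np.ndarray
    kind: str
    source_id: int | None = None

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("image tensor must be 3-D (color, width, height)")
        if self.kind not in IMAGE_KINDS:
            raise ValueError(f"unknown image kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape


def _seg_data(w: Window | Subsegment | np.ndarray) -> np.ndarray:
    data = w if isinstance(w, np.ndarray) else w.data
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected frames x channels data")
    return data


def raw_image1(w: Window | Subsegment | np.ndarray) -> SemgImage:
    """L x 1 x C lossless reshape: frames become color channels."""
    data = _seg_data(w)
    L, C = data.shape
    return SemgImage(tensor=data.reshape(L, 1, C), kind="raw1")


def raw_image2(w: Window | Subsegment | np.ndarray) -> SemgImage:
    """1 x L x C lossless reshape: a single-color frame-by-channel plane."""
    data = _seg_data(w)
    L, C = data.shape
    return SemgImage(tensor=data.reshape(1, L, C), kind="raw2")


def _rearranged_plane(data: np.ndarray, seq: ChannelSequence) -> np.ndarray:
    if data.shape[1] != seq.n_channels:
        raise ValueError(
            f"window has {data.shape[1]} channels but sequence was built for {seq.n_channels}"
        )
    return data[:, list(seq.order)]


def signal_image1(w, seq: ChannelSequence) -> SemgImage:
    """L x 1 x M image whose height axis follows the rearranged channel sequence."""
    plane = _rearranged_plane(_seg_data(w), seq)
    L, M = plane.shape
    return SemgImage(tensor=plane.reshape(L, 1, M), kind="signal1")


def signal_image2(w, seq: ChannelSequence) -> SemgImage:
    """1 x L x M variant of :func:`signal_image1` (axes exchanged)."""
    plane = _rearranged_plane(_seg_data(w), seq)
    L, M = plane.shape
    return SemgImage(tensor=plane.reshape(1, L, M), kind="signal2")


def activity_image1(w, seq: ChannelSequence) -> SemgImage:
    """2-D DFT magnitude of the signal-image plane, shaped L x 1 x M."""
    plane = _rearranged_plane(_seg_data(w), seq)
    mag = np.abs(np.fft.fft2(plane))
    L, M = mag.shape
    return SemgImage(tensor=mag.reshape(L, 1, M), kind="activity1")


def activity_image2(w, seq: ChannelSequence) -> SemgImage:
    """2-D DFT magnitude of the signal-image plane, shaped 1 x L x M."""
    plane = _rearranged_plane(_seg_data(w), seq)
    mag = np.abs(np.fft.fft2(plane))
    L, M = mag.shape
    return SemgImage(tensor=mag.reshape(1, L, M), kind="activity2")


def _feature_plane(
    w, cfg: FeatureConfig | None, seq: ChannelSequence
) -> np.ndarray:
    fm = extract_features(w, cfg)
    if fm.n_channels != seq.n_channels:
        raise ValueError(
            f"segment has {fm.n_channels} channels but sequence was built for {seq.n_channels}"
        )
    # (D, M): feature axis replaces the frame axis of signal-image
    return fm.values[list(seq.order)].T


def feature_signal_image1(
    w, cfg: FeatureConfig | None = None, seq: ChannelSequence | None = None
) -> SemgImage:
    """D x 1 x M image: per-channel feature vectors laid out on the
    all-pairs-adjacent channel sequence, feature axis as color."""
    if seq is None:
        seq = build_channel_sequence(_seg_data(w).shape[1])
    plane = _feature_plane(w, cfg, seq)
    D, M = plane.shape
    return SemgImage(tensor=plane.reshape(D, 1, M), kind="feature_signal1")


def feature_signal_image2(
    w, cfg: FeatureConfig | None = None, seq: ChannelSequence | None = None
) -> SemgImage:
    """1 x D x M axis-exchanged variant of :func:`feature_signal_image1`."""
    if seq is None:
        seq = build_channel_sequence(_seg_data(w).shape[1])
    plane = _feature_plane(w, cfg, seq)
    D, M = plane.shape
    return SemgImage(tensor=plane.reshape(1, D, M), kind="feature_signal2")


def feature_flatten_image(w, cfg: FeatureConfig | None = None) -> SemgImage:
    """1 x 1 x (C*D) image: all channel feature vectors flattened row-major."""
    fm = extract_features(w, cfg)
    return SemgImage(tensor=fm.values.reshape(1, 1, -1), kind="feature_flatten")


def hd_grid_image(w, grid: tuple[int, int]) -> SemgImage:
    """L x rows x cols grid image for high-density recordings.

    Channel k maps to grid cell (k // cols, k % cols); ``rows * cols``
    must equal the channel count.
    """
    data = _seg_data(w)
    L, C = data.shape
    rows, cols = grid
    if rows * cols != C:
        raise ValueError(f"grid {rows}x{cols} does not match {C} channels")
    return SemgImage(tensor=data.reshape(L, rows, cols), kind="hd_grid")
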
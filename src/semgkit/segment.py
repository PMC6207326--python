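"""Sliding-window segmentation and subsegment splitting.

A classified sample X is an L-frame, C-channel window cut from a single
trial. For sequence modelling each window is further split into T
consecutive, non-overlapping subsegments X_t of N = floor(L / T) frames;
any trailing L - T*N frames are dropped. Frame indexing is 0-based and
windows are half-open [start, start + L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from semgkit.recording import EmgRecording


@dataclass
class Window:
    """One gesture sample: L frames x C channels from a single trial."""

    data: np.ndarray
    label: int
    trial_id: int
    rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("window data must be an L x C matrix with L >= 1")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class Subsegment:
    """The t-th of T consecutive pieces of a window (N frames x C channels)."""

    data: np.ndarray
    index: int  # 1-based position t in 1..T

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("subsegment data must be an N x C matrix with N >= 1")
        if self.index < 1:
            raise ValueError("subsegment index is 1-based")


def _frames(duration_ms: float, rate: float, what: str) -> int:
    n = duration_ms * rate / 1000.0
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValueError(f"{what} of {duration_ms} ms is not a whole positive frame count at {rate} Hz")
    return n_int


def sliding_windows(
    rec: EmgRecording, window_ms: float, step_ms: float
) -> list[Window]:
    """Overlapped windowing, generated strictly within trials.

    Each trial of F frames yields ``floor((F - L) / S) + 1`` windows of
    L frames at stride S; windows never straddle a trial boundary, and
    each inherits the trial's (single) gesture label.

    Raises
    ------
    ValueError
        If the window is longer than the shortest trial, if the
        durations are not whole frame counts at the recording rate, or
        if a trial carries mixed labels.
    """
    L = _frames(window_ms, rec.rate, "window")
    S = _frames(step_ms, rec.rate, "step")
    windows: list[Window] = []
    for tid, sl in rec.trials():
        trial_labels = np.unique(rec.labels[sl])
        if trial_labels.size != 1:
            raise ValueError(f"trial {tid} carries mixed labels {trial_labels}")
        label = int(trial_labels[0])
        F = sl.stop - sl.start
        if F < L:
            raise ValueError(f"window of {L} frames exceeds trial {tid} of {F} frames")
        for start in range(0, F - L + 1, S):
            windows.append(
                Window(
                    data=rec.data[sl.start + start : sl.start + start + L],
                    label=label,
                    trial_id=tid,
                    rate=rec.rate,
                )
            )
    return windows


def split_subsegments(w: Window, T: int) -> list[Subsegment]:
    """Split a window into T equal, non-overlapping subsegments.

    N = floor(L / T) frames each; the trailing ``L - T * N`` frames are
    dropped, so concatenating the subsegments reproduces the first
    ``T * N`` frames of the window exactly.
    """
    L = w.n_frames
    if not 1 <= T <= L:
        raise ValueError(f"subsegment count T={T} must lie in 1..L={L}")
    N = L // T
    return [Subsegment(data=w.data[t * N : (t + 1) * N], index=t + 1) for t in range(T)]
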
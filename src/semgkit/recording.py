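"""Container and I/O for multi-channel sEMG recordings.

A recording is a frames x channels real matrix with a sampling rate,
per-frame gesture labels (0 = rest) and per-frame trial indices. Two
on-disk formats are supported: a self-describing delimited text format
(one frame per row, channels as columns, a comment header carrying the
sampling rate and identifiers) and a MAT container with named arrays
``data``, ``rate``, ``label``, ``trial``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io


@dataclass
class EmgRecording:
    """A multi-channel surface-EMG recording.

    Parameters
    ----------
    data : ndarray, shape (frames, channels)
        Signal samples, in mV or normalized units.
    rate : float
        Sampling frequency in Hz. Must be positive.
    labels : ndarray of int, shape (frames,)
        Per-frame gesture id; 0 denotes rest. Constant within a trial.
    trial_id : ndarray of int, shape (frames,)
        Per-frame trial index. Trials are contiguous frame runs.
    session_id, subject_id : int
        Bookkeeping identifiers.
    """

    data: np.ndarray
    rate: float
    labels: np.ndarray
    trial_id: np.ndarray
    session_id: int = 0
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a frames x channels matrix with at least one frame and channel")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        if self.labels.shape != (self.n_frames,):
            raise ValueError("labels must have one entry per frame")
        if self.trial_id.shape != (self.n_frames,):
            raise ValueError("trial_id must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def trials(self) -> list[tuple[int, slice]]:
        """Contiguous trial runs as ``(trial_id, frame_slice)`` pairs, in order."""
        tid = self.trial_id
        boundaries = np.flatnonzero(np.diff(tid)) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [len(tid)]))
        return [(int(tid[a]), slice(int(a), int(b))) for a, b in zip(starts, stops)]


_HEADER_KEYS = ("rate", "session", "subject")


def write_recording(rec: EmgRecording, path: str | Path) -> None:
    """Write a recording as delimited text (full float precision)."""
    path = Path(path)
    cols = np.column_stack([rec.labels, rec.trial_id, rec.data])
    header = (
        "semgkit recording v1\n"
        f"rate: {rec.rate!r}\n"
        f"session: {rec.session_id}\n"
        f"subject: {rec.subject_id}\n"
        "columns: label trial " + " ".join(f"ch{c}" for c in range(rec.n_channels))
    )
    fmt = ["%d", "%d"] + ["%.17g"] * rec.n_channels
    np.savetxt(path, cols, fmt=fmt, header=header)


def _read_delimited(path: Path) -> EmgRecording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    if "rate" not in meta:
        raise ValueError(f"{path}: missing 'rate' in header")
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected columns label, trial, ch0..")
    return EmgRecording(
        data=raw[:, 2:],
        rate=float(meta["rate"]),
        labels=raw[:, 0].astype(int),
        trial_id=raw[:, 1].astype(int),
        session_id=int(meta.get("session", 0)),
        subject_id=int(meta.get("subject", 0)),
    )


def _read_mat(path: Path) -> EmgRecording:
    mat = scipy.io.loadmat(path)
    missing = [k for k in ("data", "rate", "label", "trial") if k not in mat]
    if missing:
        raise ValueError(f"{path}: MAT container missing arrays {missing}")
    data = np.atleast_2d(np.asarray(mat["data"], dtype=float))
    return EmgRecording(
        data=data,
        rate=float(np.asarray(mat["rate"]).ravel()[0]),
        labels=np.asarray(mat["label"]).ravel().astype(int),
        trial_id=np.asarray(mat["trial"]).ravel().astype(int),
        session_id=int(np.asarray(mat.get("session", 0)).ravel()[0]),
        subject_id=int(np.asarray(mat.get("subject", 0)).ravel()[0]),
    )


def read_recording(path: str | Path, format: str = "delimited") -> EmgRecording:
    """Read a recording from ``path``.

    ``format`` is ``"delimited"`` (text, see :func:`write_recording`) or
    ``"mat"`` (MAT container with named arrays data/rate/label/trial).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "mat":
        return _read_mat(path)
    raise ValueError(f"unknown format {format!r}; expected 'delimited' or 'mat'")


def write_recording_mat(rec: EmgRecording, path: str | Path) -> None:
    """Write a recording as a MAT container with named arrays."""
    scipy.io.savemat(
        str(path),
        {
            "data": rec.data,
            "rate": rec.rate,
            "label": rec.labels,
            "trial": rec.trial_id,
            "session": rec.session_id,
            "subject": rec.subject_id,
        },
    )
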
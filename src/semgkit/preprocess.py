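"""Preprocessing: Butterworth low-pass, full-wave rectification, decimation.

Filtering is zero-phase (forward-backward) so that gesture labels stay
aligned with the frames they describe.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import scipy.signal

from semgkit.recording import EmgRecording


def lowpass_filter(rec: EmgRecording, cutoff: float, order: int = 4) -> EmgRecording:
    """Zero-phase Butterworth low-pass, applied per channel.

    Parameters
    ----------
    cutoff : float
        Cut-off frequency in Hz; must satisfy ``0 < cutoff < rate / 2``.
    order : int
        Filter order of the underlying one-pass design (the effective
        order of the forward-backward filter is doubled).
    """
    nyq = rec.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = scipy.signal.butter(order, cutoff, btype="low", fs=rec.rate, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.data, axis=0)
    return replace(rec, data=filtered)


def rectify(rec: EmgRecording) -> EmgRecording:
    """Full-wave rectification: elementwise absolute value."""
    return replace(rec, data=np.abs(rec.data))


def downsample(rec: EmgRecording, target_rate: float, antialias: bool = True) -> EmgRecording:
    """Integer decimation to ``target_rate``, labels decimated identically.

    The decimation factor ``rate / target_rate`` must be a whole number.
    With ``antialias=True`` (default) an order-8 zero-phase Chebyshev
    low-pass is applied before frame dropping, as in
    :func:`scipy.signal.decimate`; ``antialias=False`` keeps every k-th
    frame untouched, which commutes exactly with window extraction.
    """
    if target_rate > rec.rate:
        raise ValueError("target_rate must not exceed the recording rate")
    factor_f = rec.rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise ValueError(
            f"rate {rec.rate} is not an integer multiple of target_rate {target_rate}"
        )
    if factor == 1:
        return replace(rec)
    if antialias:
        data = scipy.signal.decimate(rec.data, factor, axis=0, zero_phase=True)
    else:
        data = rec.data[::factor]
    return EmgRecording(
        data=data,
        rate=target_rate,
        labels=rec.labels[::factor],
        trial_id=rec.trial_id[::factor],
        session_id=rec.session_id,
        subject_id=rec.subject_id,
    )
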
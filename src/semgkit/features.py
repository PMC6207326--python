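"""Classical time-domain sEMG features, computed per channel.

The bank covers the amplitude features MAV, RMS, WL, the threshold-count
features ZC, SSC, WAMP, sample entropy (SampEn), and model-based
features: autoregressive coefficients (AR) and the cepstral coefficients
(CC) derived from them. The set, its order, thresholds and model orders
are all configuration-driven so any published time-domain feature-set
recipe built from these members can be expressed.

Sign conventions
----------------
``feature_ar`` fits the prediction form ``x_t ~ sum_k a_k x_{t-k}`` by
Yule-Walker and returns the prediction coefficients ``a``. The cepstral
recursion follows the standard myoelectric-feature definition applied to
those coefficients:

    c_1 = -a_1
    c_n = -a_n - sum_{l=1}^{n-1} (1 - l/n) a_l c_{n-l},  1 < n <= p
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from semgkit.segment import Subsegment, Window

#: canonical default feature set (amplitude + counts + entropy + AR/CC models)
DEFAULT_FEATURES = ("MAV", "WL", "ZC", "SSC", "RMS", "SampEn", "CC", "AR")

_KNOWN = {"MAV", "RMS", "WL", "ZC", "SSC", "WAMP", "SampEn", "AR", "CC"}


@dataclass(frozen=True)
class FeatureConfig:
    """Which features to extract, in which order, and their hyperparameters.

    ``sampen_r`` is a tolerance expressed as a multiple of the channel's
    standard deviation; ``sampen_cap`` is returned when no template pair
    matches at length m+1 (SampEn would be infinite).
    ``ar_on_singular`` selects the behaviour on a singular
    autocorrelation (constant input): ``"raise"`` or ``"zeros"``.
    """

    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    wamp_threshold: float = 0.0
    sampen_m: int = 2
    sampen_r: float = 0.2
    sampen_cap: float = 10.0
    ar_order: int = 4
    cc_order: int = 4
    ar_on_singular: str = "raise"

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise ValueError("feature_names must be non-empty")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be duplicate-free")
        unknown = set(self.feature_names) - _KNOWN
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}; known: {sorted(_KNOWN)}")
        for name in ("zc_threshold", "ssc_threshold", "wamp_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampen_m < 1 or self.sampen_r <= 0:
            raise ValueError("sampen_m must be >= 1 and sampen_r > 0")
        if self.ar_order < 1 or self.cc_order < 1:
            raise ValueError("AR/CC orders must be >= 1")

    def dimension(self, name: str) -> int:
        """Number of values feature ``name`` contributes per channel."""
        if name == "AR":
            return self.ar_order
        if name == "CC":
            return self.cc_order
        return 1

    @property
    def total_dimension(self) -> int:
        """D, the per-channel feature-vector length."""
        return sum(self.dimension(n) for n in self.feature_names)


@dataclass
class ChannelFeatureMatrix:
    """Per-channel feature values: C channels x D features."""

    values: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def _as_1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    return x


def feature_mav(x) -> float:
    """Mean absolute value."""
    return float(np.mean(np.abs(_as_1d(x))))


def feature_rms(x) -> float:
    """Root mean square."""
    return float(np.sqrt(np.mean(np.square(_as_1d(x)))))


def feature_wl(x) -> float:
    """Waveform length: sum of absolute successive differences."""
    x = _as_1d(x)
    if x.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def feature_zc(x, threshold: float = 0.0) -> int:
    """Zero crossings: sign changes whose step clears ``threshold``."""
    x = _as_1d(x)
    if x.size < 2:
        raise ValueError("zero-crossing count needs at least 2 samples")
    sign_change = x[:-1] * x[1:] < 0
    big_step = np.abs(np.diff(x)) >= threshold
    return int(np.count_nonzero(sign_change & big_step))


def feature_ssc(x, threshold: float = 0.0) -> int:
    """Slope sign changes with both adjacent steps clearing ``threshold``."""
    x = _as_1d(x)
    if x.size < 3:
        raise ValueError("slope-sign-change count needs at least 3 samples")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    turning = left * right > 0
    big = (np.abs(left) >= threshold) & (np.abs(right) >= threshold)
    return int(np.count_nonzero(turning & big))


def feature_wamp(x, threshold: float = 0.0) -> int:
    """Willison amplitude: steps with magnitude >= ``threshold``."""
    x = _as_1d(x)
    if x.size < 2:
        raise ValueError("Willison amplitude needs at least 2 samples")
    return int(np.count_nonzero(np.abs(np.diff(x)) >= threshold))


def feature_sampen(x, m: int = 2, r: float = 0.2, cap: float = 10.0) -> float:
    """Sample entropy -ln(A/B) with Chebyshev tolerance ``r * sd(x)``.

    Template pairs of length m (count B) and m+1 (count A) are taken over
    the n - m templates starting at 0..n-m-1, self-matches excluded,
    distance <= tolerance counting as a match (population sd, ddof=0).
    Returns ``cap`` when A = 0 and 0.0 for the degenerate B = 0 case.
    """
    x = _as_1d(x)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"sample entropy needs more than m+1={m + 1} samples, got {n}")
    if r <= 0:
        raise ValueError("tolerance multiplier r must be > 0")
    tol = r * float(np.std(x))
    # Chebyshev distances between all templates, built incrementally.
    n_templates = n - m
    starts = np.arange(n_templates)
    dist = np.zeros((n_templates, n_templates))
    for k in range(m):
        dist = np.maximum(dist, np.abs(x[starts + k, None] - x[None, starts + k]))
    iu = np.triu_indices(n_templates, k=1)
    B = int(np.count_nonzero(dist[iu] <= tol))
    dist_m1 = np.maximum(dist, np.abs(x[starts + m, None] - x[None, starts + m]))
    A = int(np.count_nonzero(dist_m1[iu] <= tol))
    if B == 0:
        return 0.0
    if A == 0:
        return float(cap)
    return float(-np.log(A / B))


def feature_ar(x, p: int = 4, on_singular: str = "raise") -> np.ndarray:
    """Yule-Walker AR(p) prediction coefficients.

    Solves ``R a = r`` where R is the Toeplitz autocorrelation matrix of
    lags 0..p-1 and r the lag 1..p autocorrelations (biased estimates),
    for the model ``x_t ~ sum_k a_k x_{t-k}``.
    """
    x = _as_1d(x)
    n = x.size
    if p >= n:
        raise ValueError(f"AR order {p} requires more than {p} samples, got {n}")
    x = x - x.mean()
    acov = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(p + 1)])
    if acov[0] <= 0:
        if on_singular == "zeros":
            return np.zeros(p)
        raise ValueError("singular autocorrelation (constant input)")
    try:
        a = scipy.linalg.solve_toeplitz(acov[:p], acov[1 : p + 1])
    except np.linalg.LinAlgError:
        if on_singular == "zeros":
            return np.zeros(p)
        raise
    return np.asarray(a, dtype=float)


def feature_cc(x, p: int = 4, on_singular: str = "raise") -> np.ndarray:
    """Cepstral coefficients from the AR(p) fit (see module docstring)."""
    a = feature_ar(x, p, on_singular=on_singular)
    c = np.zeros(p)
    c[0] = -a[0]
    for n_ in range(2, p + 1):
        ls = np.arange(1, n_)
        c[n_ - 1] = -a[n_ - 1] - np.sum((1 - ls / n_) * a[ls - 1] * c[n_ - 1 - ls])
    return c


def _channel_features(x: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    parts: list[np.ndarray] = []
    for name in cfg.feature_names:
        if name == "MAV":
            parts.append(np.array([feature_mav(x)]))
        elif name == "RMS":
            parts.append(np.array([feature_rms(x)]))
        elif name == "WL":
            parts.append(np.array([feature_wl(x)]))
        elif name == "ZC":
            parts.append(np.array([float(feature_zc(x, cfg.zc_threshold))]))
        elif name == "SSC":
            parts.append(np.array([float(feature_ssc(x, cfg.ssc_threshold))]))
        elif name == "WAMP":
            parts.append(np.array([float(feature_wamp(x, cfg.wamp_threshold))]))
        elif name == "SampEn":
            parts.append(
                np.array([feature_sampen(x, cfg.sampen_m, cfg.sampen_r, cfg.sampen_cap)])
            )
        elif name == "AR":
            parts.append(feature_ar(x, cfg.ar_order, cfg.ar_on_singular))
        elif name == "CC":
            parts.append(feature_cc(x, cfg.cc_order, cfg.ar_on_singular))
    return np.concatenate(parts)


def extract_features(
    seg: Window | Subsegment | np.ndarray, cfg: FeatureConfig | None = None
) -> ChannelFeatureMatrix:
    """Per-channel feature matrix of a window or subsegment.

    Row c holds channel c's feature values concatenated in configured
    order; the matrix is C x D with D = ``cfg.total_dimension``.
    """
    if cfg is None:
        cfg = FeatureConfig()
    data = seg if isinstance(seg, np.ndarray) else seg.data
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("segment data must be frames x channels")
    values = np.stack([_channel_features(data[:, c], cfg) for c in range(data.shape[1])])
    return ChannelFeatureMatrix(values=values, feature_names=cfg.feature_names)
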
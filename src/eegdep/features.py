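"""Nonlinear complexity features for short EEG windows.

Six estimators, implemented from their definitions and vectorized with NumPy:

- ``perm_entropy``     Shannon entropy (base 2) of ordinal-pattern frequencies.
- ``sample_entropy``   -ln(A/B) of Chebyshev template matches, self-matches
  excluded (Richman & Moorman counting convention).
- ``spectral_entropy`` Shannon entropy of the Welch power spectral density
  normalized to a probability distribution.
- ``svd_entropy``      entropy of normalized singular values of the
  time-delay embedding matrix.
- ``dfa_exponent``     detrended fluctuation analysis slope: ~0.5 for white
  noise, ~1.5 for Brownian motion, ~(beta+1)/2 for 1/f^beta noise.
- ``higuchi_fd``       Higuchi's curve-length fractal dimension: ~1 for
  smooth curves, ~2 for white noise.

Normalized entropies lie in [0, 1]. Defaults (embedding order 3, delay 1 for
ordinal/SVD entropies; m=2, r=0.2*SD, Chebyshev for sample entropy; kmax=10
for Higuchi; Welch PSD) follow common practice for resting EEG. At the
pipeline's 200-sample windows, sample entropy and DFA are high-variance
estimates; they stay well-defined (DFA box sizes are capped at n/4) but
per-window values should be interpreted as noisy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import WindowVector

__all__ = [
    "FeatureParams",
    "FeatureVector",
    "FEATURE_ORDER",
    "DegenerateSignalError",
    "UndefinedEntropyError",
    "perm_entropy",
    "sample_entropy",
    "spectral_entropy",
    "svd_entropy",
    "dfa_exponent",
    "higuchi_fd",
    "compute_feature",
    "extract_features",
    "channel_feature_table",
    "feature_table",
    "ComplexityFeatures",
]

#: canonical feature order (the full six-feature combination)
FEATURE_ORDER: tuple[str, ...] = (
    "PermEnt",
    "SampEnt",
    "SVDEnt",
    "DFA",
    "SpectEnt",
    "Higuchi",
)


class DegenerateSignalError(ValueError):
    """Raised for inputs on which an estimator is undefined (e.g. constant)."""


class UndefinedEntropyError(ValueError):
    """Raised when sample entropy has no template matches (A or B is zero)."""


@dataclass
class FeatureParams:
    """Hyperparameters of the six estimators."""

    perm_order: int = 3
    perm_delay: int = 1
    samp_order: int = 2
    samp_r_factor: float = 0.2  # r = factor * SD(window)
    svd_order: int = 3
    svd_delay: int = 1
    higuchi_kmax: int = 10
    welch_nperseg: int | None = None  # default min(n, 256)
    normalized: bool = True

    def __post_init__(self):
        if self.perm_order < 2 or self.svd_order < 2:
            raise ValueError("embedding orders must be >= 2")
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")
        if self.samp_r_factor <= 0:
            raise ValueError("samp_r_factor must be positive")


@dataclass
class FeatureVector:
    """The six features averaged over selected electrodes, plus the label."""

    values: dict[str, float]
    y: int
    subject_id: str = "sub-000"
    window_index: int = 0

    def as_array(self, order: Iterable[str] = FEATURE_ORDER) -> np.ndarray:
        return np.array([self.values[name] for name in order])


def _check_signal(x, min_len: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < min_len:
        raise ValueError(f"{what}: signal too short ({x.size} < {min_len})")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what}: signal contains non-finite values")
    return x


def perm_entropy(
    x, order: int = 3, delay: int = 1, normalized: bool = True
) -> float:
    """Permutation entropy: entropy of ordinal patterns of ``order`` values.

    Patterns are ranked with a stable argsort, so ties break by order of
    appearance. Base-2 entropy, divided by log2(order!) when normalized.
    """
    x = _check_signal(x, order * delay + 1, "perm_entropy")
    emb = sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    patterns = np.argsort(emb, axis=1, kind="stable")
    # encode each pattern as an integer in factorial-free base `order`
    codes = (patterns * order ** np.arange(order)).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log2(p)).sum()
    if normalized:
        h /= np.log2(float(math.factorial(order)))
    return float(h) + 0.0  # normalize -0.0


def sample_entropy(x, order: int = 2, r: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with Chebyshev distance, self-matches excluded.

    ``B`` counts pairs of length-``order`` templates within ``r``; ``A`` the
    same for length ``order + 1``; both over the first ``n - order`` start
    positions. ``r`` defaults to 0.2 times the signal SD. A constant signal
    (r = 0) raises ``DegenerateSignalError``; zero matches at either length
    raise ``UndefinedEntropyError`` rather than returning a silent 0.
    """
    x = _check_signal(x, order + 2, "sample_entropy")
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise DegenerateSignalError("sample_entropy: zero tolerance (constant signal)")
    n = x.size
    m_templates = n - order  # template count shared by both lengths
    dist = np.abs(x[:, None] - x[None, :])
    cheb = dist[:m_templates, :m_templates].copy()
    for k in range(1, order):
        np.maximum(cheb, dist[k : k + m_templates, k : k + m_templates], out=cheb)
    b = int((np.count_nonzero(cheb <= r) - m_templates) // 2)  # no self-matches
    np.maximum(cheb, dist[order : order + m_templates, order : order + m_templates], out=cheb)
    a = int((np.count_nonzero(cheb <= r) - m_templates) // 2)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"sample_entropy undefined: A={a}, B={b} template matches"
        )
    return float(-np.log(a / b))


def spectral_entropy(
    x, fs: float, normalized: bool = True, nperseg: int | None = None
) -> float:
    """Shannon entropy (base 2) of the Welch PSD as a probability distribution.

    Divided by log2 of the number of frequency bins when normalized: ~0 for a
    pure tone, ~1 for white noise.
    """
    x = _check_signal(x, 4, "spectral_entropy")
    if not np.any(x):
        raise DegenerateSignalError("spectral_entropy: all-zero signal")
    if nperseg is None:
        nperseg = min(x.size, 256)
    _, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    total = psd.sum()
    if total <= 0:
        raise DegenerateSignalError("spectral_entropy: empty spectrum")
    p = psd / total
    p = p[p > 0]
    h = -(p * np.log2(p)).sum()
    if normalized:
        h /= np.log2(psd.size)
    return float(h)


def svd_entropy(
    x, order: int = 3, delay: int = 1, normalized: bool = True
) -> float:
    """Entropy of the normalized singular values of the delay-embedding matrix."""
    x = _check_signal(x, order * delay, "svd_entropy")
    emb = sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    s = np.linalg.svd(emb, compute_uv=False)
    s = s / s.sum()
    s = s[s > 1e-300]
    h = -(s * np.log2(s)).sum()
    if normalized:
        h /= np.log2(order)
    return float(h)


def _dfa_box_sizes(n: int) -> np.ndarray:
    sizes = np.unique(
        np.floor(np.logspace(np.log10(4), np.log10(n // 4), 12)).astype(int)
    )
    return sizes[sizes >= 4]


def dfa_exponent(x, box_sizes: np.ndarray | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Integrates the mean-removed signal, splits it into non-overlapping boxes
    of size ``n`` (log-spaced, 4 .. N/4 by default), removes a linear trend
    per box, and returns the slope of log RMS fluctuation vs log box size.
    """
    x = _check_signal(x, 64, "dfa_exponent")
    if x.std() == 0:
        raise DegenerateSignalError("dfa_exponent: constant signal")
    profile = np.cumsum(x - x.mean())
    n = profile.size
    sizes = _dfa_box_sizes(n) if box_sizes is None else np.asarray(box_sizes, int)
    flucts = np.empty(sizes.size)
    for i, size in enumerate(sizes):
        n_boxes = n // size
        segs = profile[: n_boxes * size].reshape(n_boxes, size)
        t = np.arange(size)
        # per-box linear detrend via least squares on a shared design
        design = np.vstack([t, np.ones(size)]).T
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        flucts[i] = np.sqrt((resid**2).mean())
    slope, _ = np.polyfit(np.log(sizes), np.log(flucts), 1)
    return float(slope)


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension from reconstructed curve lengths.

    For each lag k and offset m, L_m(k) = (sum of |x[m+ik] - x[m+(i-1)k]|)
    * (N-1) / (floor((N-m-1)/k) * k) / k; the FD is the slope of
    log(mean_m L_m(k)) vs log(1/k) over k = 1..kmax.
    """
    x = _check_signal(x, 2 * kmax, "higuchi_fd")
    n = x.size
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            n_int = idx.size - 1
            if n_int < 1:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            lk += dist * (n - 1) / (n_int * k) / k
        lengths[k - 1] = lk / k  # mean over the k offsets
    logs = np.log(lengths)
    ks = np.arange(1, kmax + 1)
    slope, _ = np.polyfit(np.log(1.0 / ks), logs, 1)
    return float(slope)


_DISPATCH = {
    "PermEnt": lambda x, fs, p: perm_entropy(
        x, p.perm_order, p.perm_delay, p.normalized
    ),
    "SampEnt": lambda x, fs, p: sample_entropy(
        x, p.samp_order, p.samp_r_factor * np.std(x)
    ),
    "SVDEnt": lambda x, fs, p: svd_entropy(x, p.svd_order, p.svd_delay, p.normalized),
    "DFA": lambda x, fs, p: dfa_exponent(x),
    "SpectEnt": lambda x, fs, p: spectral_entropy(
        x, fs, p.normalized, p.welch_nperseg
    ),
    "Higuchi": lambda x, fs, p: higuchi_fd(x, p.higuchi_kmax),
}


def compute_feature(name: str, x, fs: float, params: FeatureParams | None = None) -> float:
    """Compute one named feature on a 1-D signal."""
    if name not in _DISPATCH:
        raise KeyError(f"unknown feature {name!r}; known: {list(_DISPATCH)}")
    return _DISPATCH[name](np.asarray(x, float), fs, params or FeatureParams())


def extract_features(
    window: WindowVector,
    electrodes: list[str] | None = None,
    params: FeatureParams | None = None,
    features: Iterable[str] = FEATURE_ORDER,
    fs: float = 200.0,
) -> FeatureVector:
    """Per-electrode features arithmetically averaged over ``electrodes``.

    Errors from any single channel propagate with the channel name attached.
    """
    params = params or FeatureParams()
    if electrodes is None:
        electrodes = window.channel_names
    lower = {c.lower(): i for i, c in enumerate(window.channel_names)}
    idx = []
    for e in electrodes:
        if e.lower() not in lower:
            raise KeyError(f"electrode {e!r} not present in window")
        idx.append(lower[e.lower()])
    values: dict[str, float] = {}
    for name in features:
        per_channel = []
        for i in idx:
            try:
                per_channel.append(compute_feature(name, window.x[i], fs, params))
            except Exception as err:
                raise type(err)(
                    f"{name} on channel {window.channel_names[i]!r} "
                    f"(subject {window.subject_id}, window {window.window_index}): {err}"
                ) from err
        values[name] = float(np.mean(per_channel))
    return FeatureVector(
        values=values,
        y=window.y,
        subject_id=window.subject_id,
        window_index=window.window_index,
    )


def channel_feature_table(
    windows: list[WindowVector],
    features: Iterable[str] = FEATURE_ORDER,
    params: FeatureParams | None = None,
    fs: float = 200.0,
) -> pd.DataFrame:
    """Long-format per-channel feature table.

    Columns: subject_id, window_index, channel, feature, value, y. This is
    the caching layer for the selection sweeps: channel subsets and window
    prefixes reduce to row filters plus group means.
    """
    params = params or FeatureParams()
    rows = []
    for w in windows:
        for i, ch in enumerate(w.channel_names):
            sig = w.x[i]
            for name in features:
                rows.append(
                    (
                        w.subject_id,
                        w.window_index,
                        ch,
                        name,
                        compute_feature(name, sig, fs, params),
                        w.y,
                    )
                )
    return pd.DataFrame(
        rows, columns=["subject_id", "window_index", "channel", "feature", "value", "y"]
    )


def feature_table(
    windows: list[WindowVector],
    electrodes: list[str] | None = None,
    params: FeatureParams | None = None,
    features: Iterable[str] = FEATURE_ORDER,
) -> pd.DataFrame:
    """Wide table of electrode-averaged features, one row per window."""
    feats = list(features)
    recs = []
    for w in windows:
        fv = extract_features(w, electrodes, params, feats)
        recs.append(
            {
                "subject_id": fv.subject_id,
                "window_index": fv.window_index,
                **fv.values,
                "y": fv.y,
            }
        )
    return pd.DataFrame(recs)


class ComplexityFeatures(BaseEstimator, TransformerMixin):
    """Transformer mapping window arrays to electrode-averaged feature vectors.

    Input ``X`` is an array of shape ``(n_windows, n_channels, 200)``; output
    has shape ``(n_windows, n_features)`` with columns in ``features`` order.
    Stateless (``fit`` only validates), so it composes with scikit-learn
    pipelines and cross-validation without leakage concerns.
    """

    def __init__(
        self,
        features: tuple[str, ...] = FEATURE_ORDER,
        params: FeatureParams | None = None,
        fs: float = 200.0,
    ):
        self.features = features
        self.params = params
        self.fs = fs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_windows, n_channels, n_samples)")
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_windows, n_channels, n_samples)")
        params = self.params or FeatureParams()
        out = np.empty((X.shape[0], len(self.features)))
        for i, win in enumerate(X):
            for j, name in enumerate(self.features):
                out[i, j] = np.mean(
                    [compute_feature(name, ch, self.fs, params) for ch in win]
                )
        return out
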
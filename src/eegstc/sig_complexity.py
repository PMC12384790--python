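"""Complexity metrics of continuous single-channel (or region) signals.

Six metrics, each probing a different facet of a real-valued series:

* LZC  - Lempel-Ziv complexity of the median-binarised signal,
  normalised as C(N) log2(N) / N (~1 for white noise).
* SampEn - sample entropy: -ln of the conditional probability that
  subsequences matching for m points (Chebyshev distance, tolerance
  r x SD) still match for m+1 points.  Defaults m=2, r=0.15.
* PeEn - permutation entropy of ordinal patterns of order m=5, delay 1,
  normalised by log2(m!) into [0, 1].
* FD   - Higuchi fractal dimension (k_max=10 by default, with a
  stability rule for choosing k_max), in [1, 2].
* WE   - Wiener entropy / spectral flatness: geometric over arithmetic
  mean of the power spectral density, in [0, 1] (1 = white spectrum).
* SSV  - variance of WE over short subwindows: stability of the
  spectral structure through time.

All six are invariant under positive linear rescaling of the input.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import signal as sps

from ._lz import lz76_phrase_count
from .io_preprocess import Epoch, WindowSpec, sliding_windows

__all__ = [
    "lzc",
    "sampen",
    "peen",
    "higuchi_fd",
    "select_kmax",
    "wiener_entropy",
    "ssv",
    "windowed_complexity",
    "signal_metrics",
    "ComplexityResult",
]

_POWER_FLOOR = 1e-300


def _series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).squeeze()
    if arr.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains NaN or Inf")
    return arr


def lzc(x) -> float:
    """Normalised Lempel-Ziv complexity of the median-binarised signal."""
    x = _series(x)
    n = x.size
    if n < 2:
        raise ValueError("signal too short")
    if np.ptp(x) == 0:
        warnings.warn("constant signal: binarisation is degenerate")
    bits = x > np.median(x)
    c = lz76_phrase_count(bits)
    return float(c * np.log2(n) / n)


def sampen(x, m: int = 2, r: float = 0.15, r_mode: str = "sd") -> float:
    """Sample entropy in nats; NaN when no matches exist (undefined).

    ``r_mode='sd'`` (default) scales the tolerance as r x SD(x); a
    constant signal gets a tiny tolerance floor so that it scores 0
    rather than erroring.  ``r_mode='absolute'`` uses r as given.
    """
    x = _series(x)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples")
    if r <= 0:
        raise ValueError("r must be positive")
    if r_mode == "sd":
        sd = x.std(ddof=0)
        tol = r * sd if sd > 0 else 1e-12
    elif r_mode == "absolute":
        tol = r
    else:
        raise ValueError("r_mode must be 'sd' or 'absolute'")
    n_t = n - m  # number of (m+1)-length templates; m-templates truncated to match
    # Chebyshev distances accumulated component-wise over the embedding
    d = np.abs(x[:n_t, None] - x[None, :n_t])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n_t, None] - x[None, k : k + n_t]), out=d)
    b_mask = d <= tol
    np.maximum(d, np.abs(x[m : m + n_t, None] - x[None, m : m + n_t]), out=d)
    a_mask = d <= tol
    # exclude self-matches; each unordered pair counted once
    b = (b_mask.sum() - n_t) / 2
    a = (a_mask.sum() - n_t) / 2
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no matches); returning NaN")
        return float("nan")
    return float(-math.log(a / b))


def peen(x, m: int = 5, tau: int = 1) -> float:
    """Permutation entropy normalised by log2(m!) into [0, 1].

    Ordinal patterns use a stable ranking, so tied values are ordered by
    temporal occurrence.
    """
    x = _series(x)
    if m < 2 or tau < 1:
        raise ValueError("need m >= 2 and tau >= 1")
    span = (m - 1) * tau
    n_pat = x.size - span
    if n_pat < 1:
        raise ValueError(f"need at least m*tau+1 samples for m={m}, tau={tau}")
    emb = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, ::tau]
    patterns = np.argsort(emb, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / n_pat
    H = -(p * np.log2(p)).sum()
    return float(H / np.log2(math.factorial(m)))


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension: slope of ln L(k) against ln(1/k).

    L(k) averages the normalised curve length over the k possible
    starting offsets.  The result is clipped into [1, 2] with a warning
    when the regression strays outside.
    """
    x = _series(x)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if kmax >= n / 2:
        raise ValueError(f"kmax={kmax} too large for length {n}")
    Lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        Lk[k - 1] = np.mean(lengths)
    ks = np.arange(1, kmax + 1)
    valid = Lk > 0
    if valid.sum() < 2:
        warnings.warn("degenerate curve lengths; returning dimension 1")
        return 1.0
    slope, _ = np.polyfit(np.log(1.0 / ks[valid]), np.log(Lk[valid]), 1)
    if not 1.0 <= slope <= 2.0:
        warnings.warn(f"Higuchi slope {slope:.3f} outside [1, 2]; clipping")
    return float(np.clip(slope, 1.0, 2.0))


def select_kmax(x, candidates=(6, 8, 10, 12, 14, 16), tol: float = 0.02) -> int:
    """Smallest candidate k whose dimension estimate has stabilised.

    Returns the first k with |D(k+2) - D(k)| < tol, scanning candidate
    pairs in order; falls back to 10 with a warning when none stabilises.
    """
    x = _series(x)
    candidates = sorted(candidates)
    D = {k: higuchi_fd(x, kmax=k) for k in candidates}
    for k in candidates:
        if k + 2 in D and abs(D[k + 2] - D[k]) < tol:
            return k
    warnings.warn("fractal dimension never stabilised; defaulting to kmax=10")
    return 10


def wiener_entropy(x, fs: float = 1.0) -> float:
    """Spectral flatness (Wiener entropy) in [0, 1].

    The PSD is estimated by Welch's method (Hann window, 50% overlap,
    segments of ~1/8 the signal when the signal is long enough) and the
    flatness is the geometric over the arithmetic mean of the positive-
    frequency bins (DC excluded).  Averaged segments keep the estimator's
    own variance from dragging the flatness of genuinely white signals
    well below 1.
    """
    x = _series(x)
    if x.size < 8:
        raise ValueError("signal too short for a spectral estimate")
    if np.ptp(x) == 0:
        raise ValueError("spectral flatness undefined for an all-constant signal")
    nperseg = min(x.size, max(256, x.size // 8))
    _, p = sps.welch(x, fs=fs, nperseg=nperseg, window="hann")
    p = p[1:]  # drop DC
    p = np.maximum(p, _POWER_FLOOR)
    sfm = math.exp(np.mean(np.log(p))) / np.mean(p)
    return float(min(sfm, 1.0))


def ssv(x, fs: float, subwindow_s: float = 0.5, overlap: float = 0.5) -> float:
    """Variance of spectral flatness across short subwindows.

    Indexes the stability of the spectral structure: 0 for a signal whose
    subwindow spectra are identical, larger when the spectrum drifts.
    """
    x = _series(x)
    n_sub = int(round(subwindow_s * fs))
    if n_sub < 8:
        raise ValueError("subwindow too short for a spectral estimate")
    step = max(1, int(round(n_sub * (1 - overlap))))
    starts = range(0, x.size - n_sub + 1, step)
    values = [wiener_entropy(x[s : s + n_sub], fs=fs) for s in starts]
    if len(values) < 2:
        raise ValueError("signal spans fewer than 2 subwindows")
    return float(np.var(values))  # population variance


class ComplexityResult:
    """A metric value plus an optional per-window profile."""

    def __init__(self, metric: str, value: float, windows=None):
        self.metric = metric
        self.value = value
        self.windows = windows  # list of (start_s, end_s, value) or None

    def __repr__(self) -> str:
        nw = len(self.windows) if self.windows else 0
        return f"ComplexityResult({self.metric}={self.value:.4g}, windows={nw})"


_METRIC_MIN_SAMPLES = {
    "lzc": 2,
    "sampen": 4,
    "peen": 6,
    "fd": 21,
    "we": 8,
    "ssv": 16,
}


def _evaluate(metric: str, x: np.ndarray, fs: float, **kwargs) -> float:
    if metric == "lzc":
        return lzc(x)
    if metric == "sampen":
        return sampen(x, **kwargs)
    if metric == "peen":
        return peen(x, **kwargs)
    if metric == "fd":
        return higuchi_fd(x, **kwargs)
    if metric == "we":
        return wiener_entropy(x, fs=fs)
    if metric == "ssv":
        return ssv(x, fs=fs, **kwargs)
    raise ValueError(f"unknown metric {metric!r}")


def signal_metrics(x, fs: float) -> dict[str, float]:
    """All six signal metrics at their default parameters."""
    return {m: _evaluate(m, _series(x), fs) for m in _METRIC_MIN_SAMPLES}


def windowed_complexity(
    signal, fs: float, metric: str, spec: WindowSpec | None = None, **kwargs
) -> ComplexityResult:
    """A metric's whole-signal value plus its sliding-window profile.

    ``signal`` is a 1-D series (one channel or one region).  Windows
    follow :func:`eegstc.io_preprocess.sliding_windows` (default 1 s
    length, 0.2 s step).
    """
    x = _series(signal)
    spec = spec or WindowSpec()
    need = _METRIC_MIN_SAMPLES.get(metric)
    if need is None:
        raise ValueError(f"unknown metric {metric!r}")
    if round(spec.length * fs) < need:
        raise ValueError(
            f"window of {spec.length} s at {fs} Hz is too short for metric {metric!r}"
        )
    ep = Epoch(data=x[None, :], fs=fs)
    wins = []
    for start_s, end_s, sub in sliding_windows(ep, spec):
        wins.append((start_s, end_s, _evaluate(metric, sub.data[0], fs, **kwargs)))
    return ComplexityResult(metric, _evaluate(metric, x, fs, **kwargs), wins)
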
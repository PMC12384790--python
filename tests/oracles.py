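"""Naive direct-from-definition reference implementations.

Each function here recomputes a complexity metric with explicit loops
and dictionary counting, staying deliberately independent of the
vectorised library code so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# LZ76
# ---------------------------------------------------------------------------

def lz76_naive(symbols) -> int:
    """Phrase count of the LZ76 exhaustive history, by explicit scanning."""
    s = [int(v) for v in np.asarray(symbols).ravel()]
    n = len(s)
    c = 0
    i = 0
    while i < n:
        ln = 1
        while i + ln <= n and _occurs_before(s, i, ln):
            ln += 1
        c += 1
        i += ln
    return c


def _occurs_before(s, i, ln) -> bool:
    """Does s[i:i+ln] occur starting at any j < i (overlap allowed)?"""
    pat = s[i : i + ln]
    for j in range(i):
        if s[j : j + ln] == pat and j + ln <= i + ln - 1:
            return True
    return False


# ---------------------------------------------------------------------------
# symbolic metrics
# ---------------------------------------------------------------------------

def marginal_naive(labels) -> dict:
    labels = list(map(int, labels))
    n = len(labels)
    return {k: v / n for k, v in Counter(labels).items()}


def joint_naive(labels) -> dict:
    labels = list(map(int, labels))
    pairs = list(zip(labels[:-1], labels[1:]))
    n = len(pairs)
    return {k: v / n for k, v in Counter(pairs).items()}


def mig_naive(labels) -> float:
    pj = joint_naive(labels)
    origin = Counter()
    for (i, _), v in pj.items():
        origin[i] += v
    total = 0.0
    for (i, j), pij in pj.items():
        total -= pij * math.log2(pij / origin[i])
    return total + 0.0


def fc_naive(labels) -> float:
    p = marginal_naive(labels)
    pj = joint_naive(labels)
    return sum(pij * math.log2(p[i] / p[j]) ** 2 for (i, j), pij in pj.items())


def se_naive(labels) -> float:
    return -sum(p * math.log2(p) for p in marginal_naive(labels).values()) + 0.0


def block_entropy_naive(labels, k) -> float:
    labels = list(map(int, labels))
    blocks = [tuple(labels[i : i + k]) for i in range(len(labels) - k + 1)]
    n = len(blocks)
    return -sum(
        (v / n) * math.log2(v / n) for v in Counter(blocks).values()
    ) + 0.0


def er_ee_naive(labels, k_max) -> tuple[float, float]:
    """Closed-form least-squares line through (k, H_k), k = 1..k_max."""
    ks = list(range(1, k_max + 1))
    H = [block_entropy_naive(labels, k) for k in ks]
    n = len(ks)
    kbar = sum(ks) / n
    hbar = sum(H) / n
    num = sum((k - kbar) * (h - hbar) for k, h in zip(ks, H))
    den = sum((k - kbar) ** 2 for k in ks)
    slope = num / den
    intercept = hbar - slope * kbar
    if slope < 0:
        slope, intercept = 0.0, hbar
    return slope, intercept


# ---------------------------------------------------------------------------
# signal metrics
# ---------------------------------------------------------------------------

def lzc_signal_naive(x) -> float:
    x = list(map(float, x))
    med = float(np.median(x))
    bits = [1 if v > med else 0 for v in x]
    n = len(bits)
    return lz76_naive(bits) * math.log2(n) / n


def sampen_naive(x, m=2, r=0.15) -> float:
    x = list(map(float, x))
    n = len(x)
    sd = float(np.std(x))
    tol = r * sd if sd > 0 else 1e-12
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def peen_naive(x, m=5, tau=1) -> float:
    x = list(map(float, x))
    pats = Counter()
    n_pat = len(x) - (m - 1) * tau
    for i in range(n_pat):
        window = x[i : i + (m - 1) * tau + 1 : tau]
        order = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        pats[order] += 1
    H = -sum((v / n_pat) * math.log2(v / n_pat) for v in pats.values())
    return H / math.log2(math.factorial(m))


def higuchi_naive(x, kmax=10) -> float:
    x = list(map(float, x))
    n = len(x)
    logL, loginvk = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = list(range(m0, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(x[idx[q]] - x[idx[q - 1]]) for q in range(1, len(idx)))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        L = sum(lengths) / len(lengths)
        if L > 0:
            logL.append(math.log(L))
            loginvk.append(math.log(1.0 / k))
    nn = len(logL)
    xbar = sum(loginvk) / nn
    ybar = sum(logL) / nn
    slope = sum((a - xbar) * (b - ybar) for a, b in zip(loginvk, logL)) / sum(
        (a - xbar) ** 2 for a in loginvk
    )
    return min(2.0, max(1.0, slope))


def _welch_psd_naive(x, nperseg):
    """One-sided Welch PSD by hand: Hann (periodic), 50% overlap, mean detrend."""
    x = list(map(float, x))
    n = len(x)
    nperseg = min(n, nperseg)
    step = nperseg // 2
    w = [0.5 - 0.5 * math.cos(2 * math.pi * k / nperseg) for k in range(nperseg)]
    wss = sum(v * v for v in w)
    psds = []
    start = 0
    while start + nperseg <= n:
        seg = x[start : start + nperseg]
        mu = sum(seg) / nperseg
        seg = [(v - mu) * wv for v, wv in zip(seg, w)]
        spec = np.fft.rfft(seg)
        p = (np.abs(spec) ** 2 / wss).tolist()
        # one-sided doubling (not DC; not Nyquist when nperseg even)
        for i in range(1, len(p) - (1 if nperseg % 2 == 0 else 0)):
            p[i] *= 2
        psds.append(p)
        start += step
    nb = len(psds[0])
    return [sum(p[i] for p in psds) / len(psds) for i in range(nb)]


def wiener_naive(x) -> float:
    x = list(map(float, x))
    nperseg = min(len(x), max(256, len(x) // 8))
    p = _welch_psd_naive(x, nperseg)[1:]  # drop DC
    p = [max(v, 1e-300) for v in p]
    geo = math.exp(sum(math.log(v) for v in p) / len(p))
    ari = sum(p) / len(p)
    return min(geo / ari, 1.0)


def ssv_naive(x, fs, subwindow_s=0.5, overlap=0.5) -> float:
    x = list(map(float, x))
    n_sub = round(subwindow_s * fs)
    step = max(1, round(n_sub * (1 - overlap)))
    vals = []
    start = 0
    while start + n_sub <= len(x):
        vals.append(wiener_naive(x[start : start + n_sub]))
        start += step
    mu = sum(vals) / len(vals)
    return sum((v - mu) ** 2 for v in vals) / len(vals)
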
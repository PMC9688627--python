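"""Literal-definition brute-force oracles for the complexity estimators.

Deliberately slow and loop-based: each function transcribes the textbook
definition with explicit Python loops so it shares no code path with the
vectorized implementations it cross-checks.
"""

from __future__ import annotations

import math

import numpy as np


def perm_entropy_naive(x, order=3, delay=1, normalized=True):
    x = np.asarray(x, float)
    counts: dict[tuple, int] = {}
    last = len(x) - (order - 1) * delay
    for i in range(last):
        vals = [x[i + k * delay] for k in range(order)]
        # stable ranking: ties broken by order of appearance
        pattern = tuple(sorted(range(order), key=lambda k: (vals[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    if normalized:
        h /= math.log2(math.factorial(order))
    return h


def sample_entropy_naive(x, order=2, r=None):
    """Returns None when A or B is zero (undefined)."""
    x = np.asarray(x, float)
    if r is None:
        r = 0.2 * x.std()
    n = len(x)

    def count(m):
        c = 0
        for i in range(n - order):
            for j in range(i + 1, n - order):
                if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                    c += 1
        return c

    b = count(order)
    a = count(order + 1)
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def svd_entropy_naive(x, order=3, delay=1, normalized=True):
    x = np.asarray(x, float)
    rows = []
    for i in range(len(x) - (order - 1) * delay):
        rows.append([x[i + k * delay] for k in range(order)])
    s = np.linalg.svd(np.array(rows), compute_uv=False)
    s = s / s.sum()
    h = -sum(v * math.log2(v) for v in s if v > 0)
    if normalized:
        h /= math.log2(order)
    return h


def higuchi_naive(x, kmax=10):
    x = np.asarray(x, float)
    n = len(x)
    logs, loginv = [], []
    for k in range(1, kmax + 1):
        lmk = []
        for m in range(k):
            n_int = (n - 1 - m) // k
            if n_int < 1:
                continue
            dist = 0.0
            for i in range(1, n_int + 1):
                dist += abs(x[m + i * k] - x[m + (i - 1) * k])
            lmk.append(dist * (n - 1) / (n_int * k) / k)
        logs.append(math.log(sum(lmk) / len(lmk)))
        loginv.append(math.log(1.0 / k))
    slope, _ = np.polyfit(loginv, logs, 1)
    return float(slope)


def dfa_naive(x, box_sizes):
    x = np.asarray(x, float)
    profile = np.cumsum(x - x.mean())
    n = len(profile)
    log_n, log_f = [], []
    for size in box_sizes:
        residuals = []
        for start in range(0, (n // size) * size, size):
            seg = profile[start : start + size]
            t = np.arange(size)
            slope, intercept = np.polyfit(t, seg, 1)
            residuals.extend((seg - (slope * t + intercept)) ** 2)
        log_n.append(math.log(size))
        log_f.append(math.log(math.sqrt(sum(residuals) / len(residuals))))
    slope, _ = np.polyfit(log_n, log_f, 1)
    return float(slope)


def spectral_entropy_naive(psd, normalized=True):
    """Entropy of an already-computed PSD by the explicit formula."""
    total = sum(psd)
    h = 0.0
    for v in psd:
        p = v / total
        if p > 0:
            h -= p * math.log2(p)
    if normalized:
        h /= math.log2(len(psd))
    return h


def auc_pairs_naive(scores, labels, positive=1):
    """AUC as concordant-pair fraction (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
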
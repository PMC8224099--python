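"""Naive brute-force reference implementations of every entropy estimator.

Pure-Python double loops, deliberately independent of the package's compiled
kernels.  Only usable at small N; the test suite compares the package
implementations against these on exhaustive short-input suites.
"""

import math

import numpy as np


def chebyshev(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def _templates(x, m, tau=1):
    T = len(x) - m * tau
    return [[x[i + k * tau] for k in range(m)] for i in range(T)]


def sampen_oracle(x, m, r):
    tm = _templates(x, m)
    tm1 = _templates(list(x) + [0.0], m + 1)[:len(tm)]  # same count; rebuild:
    tm1 = [[x[i + k] for k in range(m + 1)] for i in range(len(x) - m)]
    cm = cm1 = 0
    T = len(tm)
    for i in range(T):
        for j in range(i + 1, T):
            if chebyshev(tm[i], tm[j]) < r:
                cm += 1
                if chebyshev(tm1[i], tm1[j]) < r:
                    cm1 += 1
    if cm == 0:
        return float("nan")
    if cm1 == 0:
        return math.log(T * (T - 1) / 2)
    return -math.log(cm1 / cm)


def fuzzyen_oracle(x, m, r, expo=2.0):
    T = len(x) - m

    def detrended(length):
        out = []
        for i in range(T):
            t = [x[i + k] for k in range(length)]
            mu = sum(t) / length
            out.append([v - mu for v in t])
        return out

    tm, tm1 = detrended(m), detrended(m + 1)
    sm = sm1 = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            sm += math.exp(-chebyshev(tm[i], tm[j]) ** expo / r)
            sm1 += math.exp(-chebyshev(tm1[i], tm1[j]) ** expo / r)
    return -math.log(sm1 / sm)


def _hist_entropy(dists, B):
    dmax = max(dists)
    hist = [0] * B
    if dmax == 0:
        hist[0] = len(dists)
    else:
        for d in dists:
            hist[min(int(d / dmax * B), B - 1)] += 1
    total = sum(hist)
    h = 0.0
    for c in hist:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h / math.log2(B)


def disten_oracle(x, m, B):
    tm = _templates(x, m)
    dists = [chebyshev(tm[i], tm[j])
             for i in range(len(tm)) for j in range(i + 1, len(tm))]
    return _hist_entropy(dists, B)


def xsampen_oracle(x, y, m, tau, r):
    tx = _templates(x, m, tau)
    ty = _templates(y, m, tau)
    tx1 = [[x[i + k * tau] for k in range(m + 1)] for i in range(len(tx))]
    ty1 = [[y[i + k * tau] for k in range(m + 1)] for i in range(len(ty))]
    cm = cm1 = 0
    T = len(tx)
    for i in range(T):
        for j in range(T):
            if chebyshev(tx[i], ty[j]) < r:
                cm += 1
                if chebyshev(tx1[i], ty1[j]) < r:
                    cm1 += 1
    if cm == 0:
        return float("nan")
    if cm1 == 0:
        return math.log(T * T)
    return -math.log(cm1 / cm)


def xfuzzyen_oracle(x, y, m, tau, r):
    T = len(x) - m * tau
    tx = _templates(x, m, tau)
    ty = _templates(y, m, tau)
    tx1 = [[x[i + k * tau] for k in range(m + 1)] for i in range(T)]
    ty1 = [[y[i + k * tau] for k in range(m + 1)] for i in range(T)]
    ln2 = math.log(2.0)
    sm = sm1 = 0.0
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            sm += math.exp(-ln2 * (chebyshev(tx[i], ty[j]) / r) ** 2)
            sm1 += math.exp(-ln2 * (chebyshev(tx1[i], ty1[j]) / r) ** 2)
    return -math.log(sm1 / sm)


def jdisten_oracle(x, y, m, tau, B):
    tx = _templates(x, m, tau)
    ty = _templates(y, m, tau)
    T = len(tx)
    dists = [math.sqrt(chebyshev(tx[i], tx[j]) * chebyshev(ty[i], ty[j]))
             for i in range(T) for j in range(i + 1, T)]
    return _hist_entropy(dists, B)


def bandpower_oracle(x, fs, lo, hi):
    """Periodogram band power via the raw DFT (Parseval)."""
    spec = np.abs(np.fft.rfft(np.asarray(x, float))) ** 2
    f = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(spec[(f >= lo) & (f <= hi)].sum())
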
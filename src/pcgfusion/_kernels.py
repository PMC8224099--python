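"""Numba kernels for pairwise-template computations.

All entropy estimators in this package reduce to scans over pairs of
delay-embedded templates under the Chebyshev (max-norm) distance.  At 2 kHz a
10-s segment has 20 000 samples, so the O(N^2) pair scans are the hot path;
they are implemented here as compiled loops that never materialize an
N x N distance matrix (peak memory is O(N)).

Conventions shared by every kernel (and by the brute-force oracles in the
test suite):

* templates are delay embeddings ``X_i = (x[i], x[i+tau], ..., x[i+(m-1)tau])``
  with ``i = 0 .. N - m*tau - 1``, so the same number of templates exists at
  length ``m`` and ``m+1``;
* a "match" is strict: ``d < r``;
* single-series estimators scan unordered pairs ``i < j`` (self-pairs
  excluded); the cross estimators scan the full ``(i, j)`` grid except where
  noted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "sampen_counts",
    "fuzzyen_sums",
    "disten_histogram",
    "xsampen_counts",
    "xfuzzyen_sums",
    "jdisten_histogram",
]


@njit(cache=True)
def sampen_counts(x, m, r):
    """Matched-pair counts (B_m, B_m1) for sample entropy, pairs i < j."""
    T = x.shape[0] - m
    cm = 0
    cm1 = 0
    for i in range(T):
        for j in range(i + 1, T):
            d = 0.0
            for k in range(m):
                a = abs(x[i + k] - x[j + k])
                if a > d:
                    d = a
            if d < r:
                cm += 1
                a = abs(x[i + m] - x[j + m])
                if a > d:
                    d = a
                if d < r:
                    cm1 += 1
    return cm, cm1


@njit(cache=True)
def fuzzyen_sums(x, m, r, expo):
    """Fuzzy membership sums (S_m, S_m1), pairs i < j.

    Templates are baseline-removed (each template minus its own mean); the
    membership of a pair at Chebyshev distance d is exp(-d**expo / r).
    """
    n = x.shape[0]
    T = n - m
    # rolling template means at lengths m and m+1
    mu_m = np.empty(T)
    mu_m1 = np.empty(T)
    for i in range(T):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        mu_m[i] = s / m
        mu_m1[i] = (s + x[i + m]) / (m + 1)
    sm = 0.0
    sm1 = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            d = 0.0
            for k in range(m):
                a = abs((x[i + k] - mu_m[i]) - (x[j + k] - mu_m[j]))
                if a > d:
                    d = a
            sm += np.exp(-(d ** expo) / r)
            d1 = 0.0
            for k in range(m + 1):
                a = abs((x[i + k] - mu_m1[i]) - (x[j + k] - mu_m1[j]))
                if a > d1:
                    d1 = a
            sm1 += np.exp(-(d1 ** expo) / r)
    return sm, sm1


@njit(cache=True)
def disten_histogram(x, m, B):
    """Equal-width histogram over [0, dmax] of all i < j template distances."""
    T = x.shape[0] - m
    dmax = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            d = 0.0
            for k in range(m):
                a = abs(x[i + k] - x[j + k])
                if a > d:
                    d = a
            if d > dmax:
                dmax = d
    hist = np.zeros(B, dtype=np.int64)
    if dmax == 0.0:
        hist[0] = T * (T - 1) // 2
        return hist
    for i in range(T):
        for j in range(i + 1, T):
            d = 0.0
            for k in range(m):
                a = abs(x[i + k] - x[j + k])
                if a > d:
                    d = a
            b = int(d / dmax * B)
            if b >= B:
                b = B - 1
            hist[b] += 1
    return hist


@njit(cache=True)
def xsampen_counts(x, y, m, tau, r):
    """Cross matched-pair counts over the full (i, j) grid, x vs y templates."""
    T = x.shape[0] - m * tau
    cm = 0
    cm1 = 0
    for i in range(T):
        for j in range(T):
            d = 0.0
            for k in range(m):
                a = abs(x[i + k * tau] - y[j + k * tau])
                if a > d:
                    d = a
            if d < r:
                cm += 1
                a = abs(x[i + m * tau] - y[j + m * tau])
                if a > d:
                    d = a
                if d < r:
                    cm1 += 1
    return cm, cm1


@njit(cache=True)
def xfuzzyen_sums(x, y, m, tau, r):
    """Cross fuzzy sums with membership exp(-ln(2) (d/r)^2), grid i != j."""
    T = x.shape[0] - m * tau
    ln2 = np.log(2.0)
    sm = 0.0
    sm1 = 0.0
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            d = 0.0
            for k in range(m):
                a = abs(x[i + k * tau] - y[j + k * tau])
                if a > d:
                    d = a
            sm += np.exp(-ln2 * (d / r) ** 2)
            a = abs(x[i + m * tau] - y[j + m * tau])
            if a > d:
                d = a
            sm1 += np.exp(-ln2 * (d / r) ** 2)
    return sm, sm1


@njit(cache=True)
def jdisten_histogram(x, y, m, tau, B):
    """Histogram of joint distances sqrt(d_x(i,j) * d_y(i,j)), pairs i < j.

    d_x is the Chebyshev distance between the i-th and j-th templates of x
    (and likewise d_y within y), so the joint distance reduces to the
    single-series template distance when x and y coincide.
    """
    T = x.shape[0] - m * tau
    dmax = 0.0
    for i in range(T):
        for j in range(i + 1, T):
            dx = 0.0
            dy = 0.0
            for k in range(m):
                a = abs(x[i + k * tau] - x[j + k * tau])
                if a > dx:
                    dx = a
                a = abs(y[i + k * tau] - y[j + k * tau])
                if a > dy:
                    dy = a
            d = np.sqrt(dx * dy)
            if d > dmax:
                dmax = d
    hist = np.zeros(B, dtype=np.int64)
    if dmax == 0.0:
        hist[0] = T * (T - 1) // 2
        return hist
    for i in range(T):
        for j in range(i + 1, T):
            dx = 0.0
            dy = 0.0
            for k in range(m):
                a = abs(x[i + k * tau] - x[j + k * tau])
                if a > dx:
                    dx = a
                a = abs(y[i + k * tau] - y[j + k * tau])
                if a > dy:
                    dy = a
            d = np.sqrt(dx * dy)
            b = int(d / dmax * B)
            if b >= B:
                b = B - 1
            hist[b] += 1
    return hist
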
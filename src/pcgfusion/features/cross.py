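"""Two-channel cross-entropy estimators: XSampEn, XFuzzyEn, JDistEn.

These measure pattern synchrony between two simultaneously recorded
channels; larger values mean *less* coupling.  In CAD, dyssynchronous
myocardial motion reduces inter-channel coupling, so cross entropies rise.

* **XSampEn** -- sample entropy with the template pool split across the two
  series: every delay template of ``x`` is compared against every template
  of ``y`` (strict Chebyshev match ``d < r``).
* **XFuzzyEn** -- the same scan with the Gaussian membership
  ``exp(-ln(2) * (d/r)**2)``, which equals 1/2 exactly at ``d = r``.
* **JDistEn** -- distribution entropy of the *joint* template distance
  ``sqrt(d_x(i,j) * d_y(i,j))`` (geometric mean of the within-series
  distances), which reduces exactly to single-channel DistEn when the two
  series coincide.

Both inputs must be normalized (zero mean, unit SD) so that the relative
tolerance ``r`` is comparable across channel pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .. import _kernels
from ..preprocess import Segment, normalize
from .entropy import histogram_entropy

DEFAULT_DECIMATION = 4  # 2 kHz -> 500 Hz before the O(N^2) template scans

CHANNEL_PAIRS = tuple(f"{i}{j}" for i, j in
                      itertools.combinations(range(1, 6), 2))
CROSS_MEASURES = ("XSampEn", "XFuzzyEn", "JDistEn")


@dataclass(frozen=True)
class CrossEntropyParams:
    """Embedding dimension, time delay, tolerance and JDistEn bin count."""

    m: int = 2
    tau: int = 1
    r: float = 0.2
    B: int = 256

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.B < 2:
            raise ValueError("B must be >= 2")


def _check_pair(x, y, p: CrossEntropyParams):
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < p.m * p.tau + 10:
        raise ValueError(f"series of length {len(x)} too short for "
                         f"m={p.m}, tau={p.tau}")
    return x, y


def xsampen(x: np.ndarray, y: np.ndarray,
            p: CrossEntropyParams = CrossEntropyParams()) -> float:
    """Cross sample entropy; symmetric in (x, y).

    NaN (with a warning) when no cross-template pair matches at length m;
    the +infinity limit (no matches at m + 1) is capped at ``log(T**2)``
    with T the template count.
    """
    x, y = _check_pair(x, y, p)
    cm, cm1 = _kernels.xsampen_counts(x, y, p.m, p.tau, p.r)
    if cm == 0:
        warnings.warn("xsampen undefined: no cross-template matches at length m")
        return float("nan")
    if cm1 == 0:
        t = len(x) - p.m * p.tau
        return float(np.log(t * t))
    return float(-np.log(cm1 / cm))


def xfuzzyen(x: np.ndarray, y: np.ndarray,
             p: CrossEntropyParams = CrossEntropyParams()) -> float:
    """Cross fuzzy entropy; symmetric, always finite and nonnegative."""
    x, y = _check_pair(x, y, p)
    sm, sm1 = _kernels.xfuzzyen_sums(x, y, p.m, p.tau, p.r)
    return float(-np.log(sm1 / sm))


def jdisten(x: np.ndarray, y: np.ndarray,
            p: CrossEntropyParams = CrossEntropyParams()) -> float:
    """Joint distribution entropy in [0, 1]; symmetric."""
    x, y = _check_pair(x, y, p)
    hist = _kernels.jdisten_histogram(x, y, p.m, p.tau, p.B)
    return histogram_entropy(hist, p.B)


def decimate_for_cross(x: np.ndarray, fs_hz: float,
                       factor: int = DEFAULT_DECIMATION) -> np.ndarray:
    """Anti-aliased decimation before the quadratic-cost template scans."""
    if factor <= 1:
        return np.asarray(x, dtype=np.float64)
    return sp_signal.decimate(np.asarray(x, dtype=np.float64), factor,
                              ftype="fir", zero_phase=True)


def cross_block(seg: Segment,
                p: CrossEntropyParams = CrossEntropyParams(),
                decimation: int = DEFAULT_DECIMATION,
                annotation=None, state: str | None = None) -> dict:
    """The 30 cross-entropy features of one segment.

    Each of the 10 unordered channel pairs contributes XSampEn, XFuzzyEn and
    JDistEn, computed on the full (decimated, re-normalized) 10-s segment.
    Keys follow the ``<Measure>_<ij>`` convention, e.g. ``XSampEn_12``.

    Passing ``annotation`` (a CycleAnnotation) with ``state`` in
    {"S1", "Sys", "S2", "Dia"} restricts the computation to that cardiac
    state (the state windows are concatenated across cycles before
    decimation) instead of the whole segment.
    """
    if seg.samples.shape[0] != 5:
        raise ValueError("cross_block requires all 5 channels")
    if state is not None:
        if annotation is None:
            raise ValueError("per-state computation needs an annotation")
        raw = [np.concatenate([sl[state] for sl in
                               annotation.state_slices(seg.samples[c])])
               for c in range(5)]
    else:
        raw = [seg.samples[c] for c in range(5)]
    chans = [normalize(decimate_for_cross(x, seg.fs_hz, decimation))
             for x in raw]
    out = {}
    for i, j in itertools.combinations(range(1, 6), 2):
        x, y = chans[i - 1], chans[j - 1]
        out[f"XSampEn_{i}{j}"] = xsampen(x, y, p)
        out[f"XFuzzyEn_{i}{j}"] = xfuzzyen(x, y, p)
        out[f"JDistEn_{i}{j}"] = jdisten(x, y, p)
    return out


def r_sweep(x: np.ndarray, y: np.ndarray,
            r_values=(0.1, 0.15, 0.2, 0.25, 0.3),
            m: int = 2, tau: int = 1):
    """XSampEn/XFuzzyEn and raw match counts across a tolerance sweep.

    Returns a list of dicts (one per r).  Template match counts are
    monotone nondecreasing in r by construction.
    """
    rows = []
    for r in r_values:
        p = CrossEntropyParams(m=m, tau=tau, r=r)
        xa, ya = _check_pair(x, y, p)
        cm, cm1 = _kernels.xsampen_counts(xa, ya, m, tau, r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append({"r": r, "matches_m": int(cm), "matches_m1": int(cm1),
                         "XSampEn": xsampen(x, y, p),
                         "XFuzzyEn": xfuzzyen(x, y, p)})
    return rows
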
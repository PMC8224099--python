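"""Single-channel entropy estimators: SampEn, FuzzyEn, DistEn.

All three operate on length-``m`` delay templates compared under the
Chebyshev (max-norm) distance, the convention of the sample-entropy
literature:

* **SampEn** -- negative log of the conditional probability that templates
  matching at length ``m`` (distance strictly below ``r``) still match at
  length ``m + 1``; self-matches are excluded.
* **FuzzyEn** -- the hard threshold is replaced by the fuzzy membership
  ``exp(-d**n / r)`` (default exponent ``n = 2``) computed on
  baseline-removed templates (each template minus its own mean).
* **DistEn** -- the normalized Shannon entropy of the empirical distribution
  of *all* pairwise template distances, histogrammed into ``B`` equal-width
  bins spanning [0, max distance]; bounded in [0, 1] and free of the
  tolerance parameter.

The per-segment feature block evaluates each estimator on the systolic and
diastolic window of every cardiac cycle (tolerance ``r`` scaled by the SD of
each window) and emits mean and SD across cycles: 12 features per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .. import _kernels
from ..segmentation import CycleAnnotation

MIN_SLICE_MARGIN = 10  # systole/diastole slices must have >= m + 10 samples


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension, relative tolerance and DistEn bin count."""

    m: int = 2
    r: float = 0.2     # in units of the input's SD
    B: int = 256
    fuzzy_exponent: float = 2.0  # n in the membership exp(-d**n / r)

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.B < 2:
            raise ValueError("B must be >= 2")


def _check_length(x: np.ndarray, m: int) -> np.ndarray:
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample array")
    if len(x) < m + 2:
        raise ValueError(f"input of length {len(x)} too short (need >= {m + 2})")
    return x


def sampen(x: np.ndarray, m: int = 2, r_abs: float = 0.2) -> float:
    """Sample entropy with an absolute tolerance ``r_abs``.

    Returns NaN (with a warning) when no template pair matches at length
    ``m``; when matches exist at ``m`` but none survive at ``m + 1``, the
    +infinity limit is replaced by the cap ``-log(1 / n_pairs)``, the
    largest value resolvable from ``n_pairs`` template pairs.
    """
    x = _check_length(x, m)
    if r_abs <= 0:
        raise ValueError("r_abs must be positive")
    cm, cm1 = _kernels.sampen_counts(x, m, r_abs)
    if cm == 0:
        warnings.warn("sampen undefined: no template matches at length m")
        return float("nan")
    if cm1 == 0:
        t = len(x) - m
        return float(np.log(t * (t - 1) / 2))
    return float(-np.log(cm1 / cm))


def fuzzyen(x: np.ndarray, m: int = 2, r: float = 0.2,
            exponent: float = 2.0) -> float:
    """Fuzzy entropy with membership ``exp(-d**exponent / r)``.

    ``r`` is used as an absolute tolerance here (callers scale it by the
    signal SD).  Always finite: fuzzy memberships are strictly positive.
    """
    x = _check_length(x, m)
    if r <= 0:
        raise ValueError("r must be positive")
    sm, sm1 = _kernels.fuzzyen_sums(x, m, r, exponent)
    return float(-np.log(sm1 / sm))


def disten(x: np.ndarray, m: int = 2, B: int = 256) -> float:
    """Distribution entropy in [0, 1] (normalized by log2 B)."""
    x = _check_length(x, m)
    if B < 2:
        raise ValueError("B must be >= 2")
    hist = _kernels.disten_histogram(x, m, B)
    return histogram_entropy(hist, B)


def histogram_entropy(hist: np.ndarray, B: int) -> float:
    """Shannon entropy of a histogram, normalized by log2(B); 0 log 0 = 0."""
    total = hist.sum()
    if total == 0:
        return 0.0
    p = hist[hist > 0] / total
    return float(-(p * np.log2(p)).sum() / np.log2(B))


ENTROPY_NAMES = ("SampEn_Sys", "SampEn_Dia", "FuzzyEn_Sys", "FuzzyEn_Dia",
                 "DistEn_Sys", "DistEn_Dia")


def entropy_block(seg_channel: np.ndarray, ann: CycleAnnotation,
                  params: EntropyParams = EntropyParams(),
                  channel: int = 1) -> dict:
    """The 12 entropy features of one channel (mean and SD across cycles).

    SampEn/FuzzyEn tolerances are ``params.r`` times the SD of each state
    window.  A feature whose per-cycle value is undefined (NaN) in more than
    half the cycles is emitted as NaN; otherwise undefined cycles are
    dropped from the mean/SD.
    """
    if ann.n_cycles < 3:
        raise ValueError("need at least 3 cycles for per-cycle statistics")
    per_cycle = {name: [] for name in ENTROPY_NAMES}
    for sl in ann.state_slices(seg_channel):
        for state_key, state_name in (("Sys", "Sys"), ("Dia", "Dia")):
            w = np.asarray(sl[state_key], dtype=np.float64)
            if len(w) < params.m + MIN_SLICE_MARGIN:
                raise ValueError("state window too short for entropy analysis")
            sd = w.std()
            if sd == 0:
                se = fe = float("nan")
            else:
                r_abs = params.r * sd
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    se = sampen(w, params.m, r_abs)
                fe = fuzzyen(w, params.m, r_abs, params.fuzzy_exponent)
            per_cycle[f"SampEn_{state_name}"].append(se)
            per_cycle[f"FuzzyEn_{state_name}"].append(fe)
            per_cycle[f"DistEn_{state_name}"].append(disten(w, params.m, params.B))
    out = {}
    for name, values in per_cycle.items():
        arr = np.asarray(values, dtype=np.float64)
        good = arr[np.isfinite(arr)]
        if len(good) < 0.5 * len(arr):
            warnings.warn(f"{name}: undefined in more than half the cycles")
            mean = sd = float("nan")
        else:
            mean, sd = float(good.mean()), float(good.std())
        out[f"m_{name}_{channel}"] = mean
        out[f"sd_{name}_{channel}"] = sd
    return out
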
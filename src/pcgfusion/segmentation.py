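"""Cardiac-state segmentation: delimit S1 / systole / S2 / diastole per cycle.

Two sources of annotation are supported:

* **ground-truth pass-through** -- for synthetic recordings the generator's
  exact state boundaries are cropped to the segment window.  This is the
  default for synthetic cohorts.
* **envelope segmentation** -- a simplified detector for recordings without
  ground truth: peaks of the Shannon-energy envelope are picked and assigned
  alternately to S1 and S2 using the physiological rule that diastole
  (S2 -> next S1) is longer than systole (S1 -> S2); fixed-width state
  windows are placed around the peaks.  This deliberately replaces trained
  hidden-semi-Markov segmenters, which require labelled training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .preprocess import Segment, normalize
from .synthetic import GroundTruthStates

ENVELOPE_FS_HZ = 50.0
S1_HALF_WIDTH_S = 0.045
S2_HALF_WIDTH_S = 0.035
MIN_CYCLES = 3


@dataclass
class CycleAnnotation:
    """Ordered per-cycle state boundaries within one segment.

    Rows are (s1_start, s1_end, sys_end, s2_end, dia_end), 0-based half-open
    sample indices; ``source`` records whether they came from generator
    ground truth or from the envelope detector.
    """

    cycles: np.ndarray  # (n_cycles, 5) int
    source: str = "ground_truth"

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=np.int64).reshape(-1, 5)
        for row in self.cycles:
            if np.any(np.diff(row) <= 0):
                raise ValueError("state indices must strictly increase")
        for k in range(len(self.cycles) - 1):
            if self.cycles[k, 4] > self.cycles[k + 1, 0]:
                raise ValueError("cycles overlap")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def usable(self) -> bool:
        """Downstream statistics need at least 3 complete cycles."""
        return self.n_cycles >= MIN_CYCLES

    def state_slices(self, x: np.ndarray):
        """Per-cycle state windows of a channel: dicts with keys
        S1/Sys/S2/Dia plus the boundary indices."""
        out = []
        for s1s, s1e, syse, s2e, diae in self.cycles:
            out.append({"S1": x[s1s:s1e], "Sys": x[s1e:syse],
                        "S2": x[syse:s2e], "Dia": x[s2e:diae],
                        "bounds": (s1s, s1e, syse, s2e, diae)})
        return out

    @classmethod
    def from_ground_truth(cls, states: GroundTruthStates) -> "CycleAnnotation":
        return cls(cycles=states.cycles.copy(), source="ground_truth")

    def to_csv(self, path) -> None:
        """Same schema as the generator's ground-truth CSV (round-trips)."""
        GroundTruthStates(self.cycles.copy()).to_csv(path)

    @classmethod
    def from_csv(cls, path, source: str = "ground_truth") -> "CycleAnnotation":
        return cls(GroundTruthStates.from_csv(path).cycles, source=source)


def shannon_energy_envelope(x: np.ndarray, fs_hz: float):
    """Shannon energy envelope at 50 Hz.

    The signal is scaled to unit peak, per-sample Shannon energy
    ``-u^2 * log(u^2)`` is computed, smoothed with a 20 ms moving average and
    downsampled to 50 Hz.  Returns ``(envelope, decimation_factor)``; sample
    ``k`` of the envelope corresponds to input index ``k * decimation_factor``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    peak = np.abs(x).max()
    # scale so u^2 <= 1/e: -p log p is monotone on [0, 1/e], which keeps the
    # envelope maximal at the burst center instead of splitting into side
    # lobes where u^2 crosses 1/e
    if peak > 0:
        u2 = (x / peak) ** 2 / np.e
    else:
        u2 = np.zeros_like(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(u2 > 0, -u2 * np.log(u2), 0.0)
    win = max(1, int(round(0.02 * fs_hz)))
    padded = np.pad(e, win, mode="reflect")
    e = np.convolve(padded, np.ones(win) / win, mode="same")[win:-win]
    dec = max(1, int(round(fs_hz / ENVELOPE_FS_HZ)))
    return e[::dec], dec


def _pick_peaks(env: np.ndarray, fs_env: float) -> np.ndarray:
    # S1-S2 gaps are >= ~0.15 s even at high heart rate
    distance = max(1, int(round(0.15 * fs_env)))
    height = 0.2 * env.max() if env.max() > 0 else None
    peaks, _ = sp_signal.find_peaks(env, distance=distance, height=height,
                                    prominence=0.1 * env.max())
    return peaks


def _assign_s1(peaks: np.ndarray):
    """Choose which alternating peak subset is S1.

    Diastole (S2 -> next S1) is longer than systole (S1 -> S2); when the two
    interval families are nearly equal, the assignment minimizing the
    variance of systolic intervals wins.
    """
    gaps = np.diff(peaks)
    even_sys = gaps[0::2]   # hypothesis A: peaks 0, 2, ... are S1
    odd_sys = gaps[1::2]    # hypothesis B: peaks 1, 3, ... are S1
    even_dia = odd_sys
    odd_dia = gaps[2::2]
    mean = lambda a: float(np.mean(a)) if len(a) else np.inf
    a_ok = mean(even_sys) < mean(even_dia)
    b_ok = mean(odd_sys) < mean(odd_dia)
    if a_ok and not b_ok:
        return 0
    if b_ok and not a_ok:
        return 1
    var = lambda a: float(np.var(a)) if len(a) else np.inf
    return 0 if var(even_sys) <= var(odd_sys) else 1


def envelope_segment(x: np.ndarray, fs_hz: float) -> CycleAnnotation:
    """Detect cycles on one channel via envelope peak-picking."""
    env, dec = shannon_energy_envelope(normalize(x), fs_hz)
    fs_env = fs_hz / dec
    peaks = _pick_peaks(env, fs_env)
    if len(peaks) < 4:
        return CycleAnnotation(np.empty((0, 5), dtype=np.int64),
                               source="envelope")
    first_s1 = _assign_s1(peaks)
    s1_peaks = peaks[first_s1::2] * dec
    s2_peaks = peaks[first_s1 + 1::2] * dec
    w1 = int(round(S1_HALF_WIDTH_S * fs_hz))
    w2 = int(round(S2_HALF_WIDTH_S * fs_hz))
    n = len(x)
    cycles = []
    for k in range(min(len(s1_peaks), len(s2_peaks))):
        if k + 1 >= len(s1_peaks):
            break  # incomplete last cycle: no following S1
        s1s = int(s1_peaks[k]) - w1
        s1e = int(s1_peaks[k]) + w1
        syse = int(s2_peaks[k]) - w2
        s2e = int(s2_peaks[k]) + w2
        diae = int(s1_peaks[k + 1]) - w1
        # clamp sub-envelope-sample overhang at the segment edges; anything
        # larger is an incomplete first/last cycle and is discarded
        if -dec <= s1s < 0:
            s1s = 0
        if n < diae <= n + dec:
            diae = n
        if s1s < 0 or diae > n:
            continue
        if not (s1s < s1e < syse < s2e < diae):
            continue  # malformed detection
        cycles.append((s1s, s1e, syse, s2e, diae))
    return CycleAnnotation(np.array(cycles, dtype=np.int64).reshape(-1, 5),
                           source="envelope")


def segment_states(seg: Segment, channel: int = 0,
                   truth: GroundTruthStates | None = None) -> CycleAnnotation:
    """Annotate one segment's cardiac states.

    With ``truth`` (recording-level ground truth), the states are cropped to
    the segment window and re-indexed -- the exact annotation.  Without it,
    the envelope detector runs on the requested channel.  Check ``usable``
    on the result: fewer than 3 detected cycles makes a segment unusable
    for the per-cycle mean/SD features.
    """
    if truth is not None:
        start = seg.segment_index * seg.n_samples
        cropped = truth.crop(start, start + seg.n_samples)
        return CycleAnnotation.from_ground_truth(cropped)
    return envelope_segment(seg.samples[channel], seg.fs_hz)
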
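"""Time-domain and frequency-domain features per channel per segment.

Ten per-cycle time-domain quantities (interval durations, duration ratios,
average-amplitude ratios) and eight per-cycle spectral proportions (high-
and low-frequency power fraction of each of the four states) are computed
cycle by cycle; their mean and population SD across the cycles of a segment
are the emitted features (20 time + 16 frequency per channel).

"High frequency" is power above 200 Hz, "low frequency" below 50 Hz --
murmurs from turbulent flow through stenosed arteries raise the 200-800 Hz
band, while normal heart sounds live below 200 Hz.
"""

from __future__ import annotations

import numpy as np

from ..segmentation import CycleAnnotation

HF_THRESHOLD_HZ = 200.0
LF_THRESHOLD_HZ = 50.0

TIME_FEATURE_NAMES = (
    "CC", "IntS1", "IntS2", "IntSys", "IntDia",
    "Ratio_SysCC", "Ratio_DiaCC", "Ratio_SysDia",
    "Ratio_Amp_SysS1", "Ratio_Amp_DiaS2",
)
FREQ_FEATURE_NAMES = (
    "HFAll_S1", "LFAll_S1", "HFAll_S2", "LFAll_S2",
    "HFAll_Sys", "LFAll_Sys", "HFAll_Dia", "LFAll_Dia",
)
MIN_SPECTRUM_SAMPLES = 16


def mean_sd_block(per_cycle: dict, suffix: str) -> dict:
    """Mean and population SD across cycles, named m_<name>_<ch> / sd_<name>_<ch>."""
    out = {}
    for name, values in per_cycle.items():
        arr = np.asarray(values, dtype=np.float64)
        out[f"m_{name}_{suffix}"] = float(arr.mean())
        out[f"sd_{name}_{suffix}"] = float(arr.std())
    return out


def time_domain_features(seg_channel: np.ndarray, ann: CycleAnnotation,
                         fs_hz: float, channel: int) -> dict:
    """The 20 time-domain features of one channel (Table-style naming)."""
    if ann.n_cycles < 3:
        raise ValueError("need at least 3 cycles for per-cycle statistics")
    per_cycle = {name: [] for name in TIME_FEATURE_NAMES}
    for sl in ann.state_slices(seg_channel):
        s1s, s1e, syse, s2e, diae = sl["bounds"]
        cc = (diae - s1s) / fs_hz
        int_s1 = (s1e - s1s) / fs_hz
        int_s2 = (s2e - syse) / fs_hz
        int_sys = (syse - s1e) / fs_hz
        int_dia = (diae - s2e) / fs_hz
        amp = {k: float(np.mean(np.abs(sl[k]))) for k in ("S1", "Sys", "S2", "Dia")}
        per_cycle["CC"].append(cc)
        per_cycle["IntS1"].append(int_s1)
        per_cycle["IntS2"].append(int_s2)
        per_cycle["IntSys"].append(int_sys)
        per_cycle["IntDia"].append(int_dia)
        per_cycle["Ratio_SysCC"].append(int_sys / cc)
        per_cycle["Ratio_DiaCC"].append(int_dia / cc)
        per_cycle["Ratio_SysDia"].append(int_sys / int_dia)
        per_cycle["Ratio_Amp_SysS1"].append(amp["Sys"] / amp["S1"])
        per_cycle["Ratio_Amp_DiaS2"].append(amp["Dia"] / amp["S2"])
    return mean_sd_block(per_cycle, str(channel))


def state_spectrum_proportions(state_slice: np.ndarray, fs_hz: float,
                               taper: str | None = None):
    """(hf_prop, lf_prop): power fractions above 200 Hz / below 50 Hz.

    Power spectrum via the discrete Fourier transform of the raw slice;
    proportions are Parseval-consistent fractions of total power from 0 to
    Nyquist.  State slices are short, so no taper is applied by default;
    ``taper="hann"`` enables one.
    """
    x = np.asarray(state_slice, dtype=np.float64)
    if len(x) < MIN_SPECTRUM_SAMPLES:
        raise ValueError(
            f"state slice of {len(x)} samples is too short for a spectrum "
            f"(need >= {MIN_SPECTRUM_SAMPLES})")
    if taper == "hann":
        x = x * np.hanning(len(x))
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs_hz)
    total = spec.sum()
    if total == 0:
        return 0.0, 0.0
    hf = spec[freqs > HF_THRESHOLD_HZ].sum() / total
    lf = spec[freqs < LF_THRESHOLD_HZ].sum() / total
    return float(hf), float(lf)


def frequency_domain_features(seg_channel: np.ndarray, ann: CycleAnnotation,
                              fs_hz: float, channel: int) -> dict:
    """The 16 frequency-domain features of one channel."""
    if ann.n_cycles < 3:
        raise ValueError("need at least 3 cycles for per-cycle statistics")
    per_cycle = {name: [] for name in FREQ_FEATURE_NAMES}
    for sl in ann.state_slices(seg_channel):
        for state in ("S1", "S2", "Sys", "Dia"):
            hf, lf = state_spectrum_proportions(sl[state], fs_hz)
            per_cycle[f"HFAll_{state}"].append(hf)
            per_cycle[f"LFAll_{state}"].append(lf)
    return mean_sd_block(per_cycle, str(channel))
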
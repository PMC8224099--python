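"""Synthetic five-channel phonocardiogram (PCG) generator.

Real multi-site heart-sound recordings with angiography-confirmed labels are
not publicly available, so this module synthesizes cohorts with the
statistical structure the downstream analysis assumes:

* quasi-periodic cardiac cycles tiled by four states -- S1, systole, S2,
  diastole -- with exactly known boundaries (the ground truth that the
  segmentation module can pass through);
* five synchronously recorded channels: gain-scaled, time-aligned copies of
  the cardiac source with channel-specific morphology perturbations, plus
  independent sensor noise, respiration drift and mains interference;
* a controllable coronary-artery-disease (CAD) signature: band-limited
  200-800 Hz murmur noise during systole and diastole (turbulence through a
  stenosed artery) and reduced inter-channel synchrony (per-channel timing
  jitter plus independent noise, modelling dyssynchronous myocardial motion).

Every recording is fully determined by the profile's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

N_CHANNELS = 5
DEFAULT_FS_HZ = 2000.0
DEFAULT_DURATION_S = 300.0

# cardiac morphology constants (fractions of a cycle / absolute durations)
S1_DURATION_S = 0.09
S2_DURATION_S = 0.07
SYSTOLE_FRACTION = 0.35  # systole state duration as a fraction of the cycle

# S1 is dominated by 30-100 Hz energy, S2 by 50-150 Hz
S1_CARRIER_HZ = 55.0
S2_CARRIER_HZ = 95.0
S1_AMPLITUDE = 1.0
S2_AMPLITUDE = 0.75

# background: sensor noise with a soft high-frequency roll-off (knee ~100 Hz),
# a small white floor, respiration drift and mains interference
SHAPED_NOISE_RMS = 0.03
WHITE_NOISE_RMS = 0.006
RESPIRATION_HZ = 0.2
RESPIRATION_AMP = 0.05
MAINS_HZ = 50.0
MAINS_AMP = 0.02

# CAD signature scales
MURMUR_BAND_HZ = (200.0, 800.0)
MURMUR_COMMON_FRACTION = 0.5   # variance fraction of the shared murmur source
MURMUR_COUPLING_LOG_SD = 1.2   # site-to-site spread of murmur audibility
DESYNC_MAX_DELAY_S = 0.015     # timing jitter amplitude at desync_level = 1
DESYNC_NOISE_RMS_FRACTION = 0.25  # independent-noise RMS at desync_level = 1

LABEL_CAD = "CAD"
LABEL_NONCAD = "non-CAD"

STATE_COLUMNS = ("s1_start", "s1_end", "sys_end", "s2_end", "dia_end")


@dataclass(frozen=True)
class SubjectProfile:
    """Generator parameters for one synthetic subject."""

    subject_id: str
    label: str
    heart_rate_bpm: float = 70.0
    hr_jitter: float = 0.03
    murmur_snr_db: float = -np.inf
    desync_level: float = 0.0
    channel_gains: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.label not in (LABEL_CAD, LABEL_NONCAD):
            raise ValueError(f"label must be {LABEL_CAD!r} or {LABEL_NONCAD!r}")
        if not 40.0 <= self.heart_rate_bpm <= 140.0:
            raise ValueError("heart_rate_bpm must lie in [40, 140]")
        if self.hr_jitter < 0:
            raise ValueError("hr_jitter must be nonnegative")
        if not 0.0 <= self.desync_level <= 1.0:
            raise ValueError("desync_level must lie in [0, 1]")
        if len(self.channel_gains) != N_CHANNELS:
            raise ValueError(f"channel_gains must have {N_CHANNELS} entries")
        if any(g <= 0 for g in self.channel_gains):
            raise ValueError("channel gains must be positive")


@dataclass
class MultiChannelRecording:
    """Synchronized five-channel PCG samples with subject metadata."""

    samples: np.ndarray  # (5, N)
    fs_hz: float
    subject_id: str
    label: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValueError(f"samples must be ({N_CHANNELS}, N)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def to_wav(self, path) -> None:
        wavfile.write(path, int(self.fs_hz), self.samples.T.astype(np.float32))

    @classmethod
    def from_wav(cls, path, subject_id="", label=LABEL_NONCAD):
        fs, data = wavfile.read(path)
        if data.ndim == 1:
            raise ValueError("expected a multi-channel WAV")
        return cls(samples=data.T.astype(np.float64), fs_hz=float(fs),
                   subject_id=subject_id, label=label)


@dataclass
class GroundTruthStates:
    """Per-cycle state boundaries: 0-based, half-open sample indices.

    Each row is (s1_start, s1_end, sys_end, s2_end, dia_end); the four state
    windows [s1_start, s1_end), [s1_end, sys_end), [sys_end, s2_end),
    [s2_end, dia_end) tile the cycle contiguously.
    """

    cycles: np.ndarray  # (n_cycles, 5) int

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=np.int64).reshape(-1, 5)
        flat = self.cycles.ravel()
        if len(flat) and np.any(np.diff(flat) <= 0):
            # cross-cycle: dia_end == next s1_start is allowed (contiguous)
            for k in range(len(self.cycles) - 1):
                if self.cycles[k, 4] > self.cycles[k + 1, 0]:
                    raise ValueError("cycles overlap")
            for row in self.cycles:
                if np.any(np.diff(row) <= 0):
                    raise ValueError("state indices must strictly increase")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def crop(self, start: int, stop: int) -> "GroundTruthStates":
        """Cycles fully contained in [start, stop), re-indexed to the window."""
        keep = (self.cycles[:, 0] >= start) & (self.cycles[:, 4] <= stop)
        return GroundTruthStates(self.cycles[keep] - start)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.cycles, columns=list(STATE_COLUMNS))
        df.insert(0, "cycle", np.arange(len(df)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruthStates":
        df = pd.read_csv(path)
        return cls(df[list(STATE_COLUMNS)].to_numpy())


def _shaped_noise(rng: np.random.Generator, n: int, fs_hz: float,
                  knee_hz: float = 100.0) -> np.ndarray:
    """Unit-RMS noise with power roll-off 1 / (1 + (f/knee)^4)."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    h = 1.0 / np.sqrt(1.0 + (f / knee_hz) ** 4)
    shaped = np.fft.irfft(np.fft.rfft(white) * h, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _gaussian_burst(t_axis: np.ndarray, center_s: float, duration_s: float,
                    carrier_hz: float, amplitude: float) -> np.ndarray:
    """Gaussian-enveloped cosine burst; envelope sigma = duration / 6."""
    sigma = duration_s / 6.0
    env = np.exp(-0.5 * ((t_axis - center_s) / sigma) ** 2)
    return amplitude * env * np.cos(2.0 * np.pi * carrier_hz * (t_axis - center_s))


def _draw_cycle_lengths(rng, heart_rate_bpm, hr_jitter, duration_s):
    t_nominal = 60.0 / heart_rate_bpm
    lengths = []
    total = 0.0
    while total + t_nominal <= duration_s + t_nominal:  # generous overshoot
        eps = rng.standard_normal() * hr_jitter
        eps = float(np.clip(eps, -3.0 * hr_jitter, 3.0 * hr_jitter))
        t_k = t_nominal * (1.0 + eps)
        lengths.append(t_k)
        total += t_k
        if total > duration_s:
            break
    return np.array(lengths)


def generate_recording(profile: SubjectProfile,
                       duration_s: float = DEFAULT_DURATION_S,
                       fs_hz: float = DEFAULT_FS_HZ):
    """Synthesize the baseline (murmur-free) recording for one subject.

    Returns ``(MultiChannelRecording, GroundTruthStates)``.  The recording
    contains only complete cardiac cycles' worth of states; samples after the
    last complete cycle are background only.  For a CAD profile, apply
    :func:`inject_cad_signature` to the result.
    """
    min_duration = 3 * 60.0 / profile.heart_rate_bpm
    if duration_s < min_duration:
        raise ValueError(
            f"duration_s={duration_s:g} too short: need at least 3 cardiac "
            f"cycles = {min_duration:g} s at {profile.heart_rate_bpm:g} bpm")
    rng = np.random.default_rng(profile.seed)
    n = int(round(duration_s * fs_hz))
    t_axis = np.arange(n) / fs_hz

    # channel-specific morphology: carrier detune and S2/S1 amplitude ratio
    carrier_detune = 1.0 + 0.06 * rng.standard_normal(N_CHANNELS)
    s2_ratio_perturb = 1.0 + 0.15 * rng.standard_normal(N_CHANNELS)

    lengths = _draw_cycle_lengths(rng, profile.heart_rate_bpm,
                                  profile.hr_jitter, duration_s)
    # per-cycle common amplitude modulation (shared by all channels)
    cycle_amp = 1.0 + 0.05 * rng.standard_normal(len(lengths))

    samples = np.zeros((N_CHANNELS, n))
    cycles = []
    t0 = 0.0
    for k, t_k in enumerate(lengths):
        s1_start = int(round(t0 * fs_hz))
        dia_end = int(round((t0 + t_k) * fs_hz))
        if dia_end > n:
            break
        s1_end = s1_start + int(round(S1_DURATION_S * fs_hz))
        # the systole state window (S1 end -> S2 start) is 0.35 x cycle
        sys_end = s1_end + int(round(SYSTOLE_FRACTION * t_k * fs_hz))
        s2_end = sys_end + int(round(S2_DURATION_S * fs_hz))
        if not (s1_start < s1_end < sys_end < s2_end < dia_end):
            raise ValueError("cycle too short for the fixed state durations")
        cycles.append((s1_start, s1_end, sys_end, s2_end, dia_end))

        s1_center = (t0 + 0.5 * S1_DURATION_S)
        s2_center = (t0 + S1_DURATION_S + SYSTOLE_FRACTION * t_k
                     + 0.5 * S2_DURATION_S)
        lo = max(0, s1_start - int(0.1 * fs_hz))
        hi = min(n, dia_end + int(0.1 * fs_hz))
        tt = t_axis[lo:hi]
        for ch in range(N_CHANNELS):
            burst = _gaussian_burst(tt, s1_center, S1_DURATION_S,
                                    S1_CARRIER_HZ * carrier_detune[ch],
                                    S1_AMPLITUDE * cycle_amp[k])
            burst += _gaussian_burst(tt, s2_center, S2_DURATION_S,
                                     S2_CARRIER_HZ * carrier_detune[ch],
                                     S2_AMPLITUDE * s2_ratio_perturb[ch]
                                     * cycle_amp[k])
            samples[ch, lo:hi] += burst
        t0 += t_k

    # background: independent per-channel sensor noise + common drift/mains
    respiration = RESPIRATION_AMP * np.sin(2 * np.pi * RESPIRATION_HZ * t_axis)
    mains = MAINS_AMP * np.sin(2 * np.pi * MAINS_HZ * t_axis)
    for ch in range(N_CHANNELS):
        samples[ch] += SHAPED_NOISE_RMS * _shaped_noise(rng, n, fs_hz)
        samples[ch] += WHITE_NOISE_RMS * rng.standard_normal(n)
        samples[ch] += respiration + mains
        samples[ch] *= profile.channel_gains[ch]

    rec = MultiChannelRecording(samples=samples, fs_hz=fs_hz,
                                subject_id=profile.subject_id,
                                label=profile.label)
    return rec, GroundTruthStates(np.array(cycles, dtype=np.int64))


def _murmur_window(states: GroundTruthStates, n: int, fs_hz: float) -> np.ndarray:
    """Smooth 0/1 mask over systole and diastole windows (20 ms Hann ramps)."""
    mask = np.zeros(n)
    for s1_start, s1_end, sys_end, s2_end, dia_end in states.cycles:
        mask[s1_end:sys_end] = 1.0
        mask[s2_end:dia_end] = 1.0
    w = signal.windows.hann(max(3, int(0.02 * fs_hz)))
    return np.convolve(mask, w / w.sum(), mode="same")


def _bandlimited_noise(rng, n, fs_hz, band=MURMUR_BAND_HZ):
    white = rng.standard_normal(n)
    nyq = fs_hz / 2.0
    hi = min(band[1], 0.98 * nyq)
    sos = signal.butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    out = signal.sosfiltfilt(sos, white)
    sd = out.std()
    return out / sd if sd > 0 else out


def _smooth_delay_field(rng, n, fs_hz, max_delay_s):
    """Slowly varying random delay (samples), bounded by +/- max_delay_s."""
    slow = _shaped_noise(rng, n, fs_hz, knee_hz=1.0)
    slow = slow / max(np.abs(slow).max(), 1e-12)
    return slow * max_delay_s * fs_hz


def inject_cad_signature(rec: MultiChannelRecording,
                         states: GroundTruthStates,
                         profile: SubjectProfile) -> MultiChannelRecording:
    """Add the CAD signature: systolic/diastolic murmur + channel dyssynchrony.

    The murmur is 200-800 Hz band-limited noise gated to the systole and
    diastole windows, with per-channel RMS set ``murmur_snr_db`` decibels
    relative to that channel's signal RMS.  Channels share a common murmur
    source only partially and pick it up with heterogeneous coupling gains
    (sound radiated from a single stenosis reaches the five auscultation
    sites very differently).  Dyssynchrony applies a per-channel smooth
    timing jitter and mixes in independent low-frequency noise, both scaled
    by ``desync_level``, which raises every pairwise cross entropy.
    """
    if profile.label != LABEL_CAD:
        raise ValueError("inject_cad_signature requires a CAD profile")
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0x5CAD]))
    n = rec.n_samples
    fs = rec.fs_hz
    out = rec.samples.copy()

    if np.isfinite(profile.murmur_snr_db):
        mask = _murmur_window(states, n, fs)
        common = _bandlimited_noise(rng, n, fs)
        # sound radiated from a localized stenosis reaches the five
        # auscultation sites very unevenly: per-channel coupling spans
        # roughly two orders of magnitude, so no single site reliably
        # captures every subject's murmur
        coupling = np.exp(MURMUR_COUPLING_LOG_SD * rng.standard_normal(N_CHANNELS))
        amp_scale = 10.0 ** (profile.murmur_snr_db / 20.0)
        for ch in range(N_CHANNELS):
            local = _bandlimited_noise(rng, n, fs)
            source = (np.sqrt(MURMUR_COMMON_FRACTION) * common
                      + np.sqrt(1 - MURMUR_COMMON_FRACTION) * local)
            target_rms = amp_scale * np.sqrt(np.mean(out[ch] ** 2))
            out[ch] += coupling[ch] * target_rms * source * mask

    if profile.desync_level > 0:
        idx = np.arange(n, dtype=np.float64)
        for ch in range(N_CHANNELS):
            delay = _smooth_delay_field(rng, n, fs,
                                        profile.desync_level * DESYNC_MAX_DELAY_S)
            out[ch] = np.interp(idx + delay, idx, out[ch])
            noise = _shaped_noise(rng, n, fs)
            rms = np.sqrt(np.mean(out[ch] ** 2))
            out[ch] += (profile.desync_level * DESYNC_NOISE_RMS_FRACTION
                        * rms * noise)

    return MultiChannelRecording(samples=out, fs_hz=fs,
                                 subject_id=rec.subject_id, label=rec.label)


@dataclass(frozen=True)
class CohortConfig:
    """Distributions the per-subject generator parameters are drawn from."""

    heart_rate_range: tuple = (60.0, 100.0)
    hr_jitter_range: tuple = (0.02, 0.05)
    gain_log_sd: float = 0.2
    murmur_snr_db_range: tuple = (-30.0, -12.0)
    desync_range: tuple = (0.1, 0.7)


def make_profile(subject_id: str, label: str, seed: int,
                 config: CohortConfig = CohortConfig()) -> SubjectProfile:
    """Draw one subject's generator parameters from the cohort distributions."""
    rng = np.random.default_rng(seed)
    hr = rng.uniform(*config.heart_rate_range)
    jitter = rng.uniform(*config.hr_jitter_range)
    gains = tuple(np.exp(config.gain_log_sd * rng.standard_normal(N_CHANNELS)))
    if label == LABEL_CAD:
        snr = rng.uniform(*config.murmur_snr_db_range)
        desync = rng.uniform(*config.desync_range)
    else:
        snr, desync = -np.inf, 0.0
    return SubjectProfile(subject_id=subject_id, label=label,
                          heart_rate_bpm=hr, hr_jitter=jitter,
                          murmur_snr_db=snr, desync_level=desync,
                          channel_gains=gains, seed=seed)


def generate_subject(profile: SubjectProfile,
                     duration_s: float = DEFAULT_DURATION_S,
                     fs_hz: float = DEFAULT_FS_HZ):
    """Generate one subject end to end (baseline + CAD signature if CAD)."""
    rec, states = generate_recording(profile, duration_s, fs_hz)
    if profile.label == LABEL_CAD:
        rec = inject_cad_signature(rec, states, profile)
    return rec, states


def generate_cohort(n_cad: int, n_noncad: int, seed: int,
                    duration_s: float = DEFAULT_DURATION_S,
                    fs_hz: float = DEFAULT_FS_HZ,
                    config: CohortConfig = CohortConfig(),
                    return_profiles: bool = False):
    """Generate a labelled cohort of synthetic recordings.

    Per-subject seeds are spawned deterministically from the master seed, so
    the same (n_cad, n_noncad, seed) always yields a bit-identical cohort.
    """
    if n_cad < 0 or n_noncad < 0:
        raise ValueError("subject counts must be nonnegative")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_cad + n_noncad)
    out, profiles = [], []
    for k in range(n_cad + n_noncad):
        if k < n_cad:
            sid, label = f"cad{k + 1:02d}", LABEL_CAD
        else:
            sid, label = f"non{k - n_cad + 1:02d}", LABEL_NONCAD
        profile = make_profile(sid, label, int(child_seeds[k]), config)
        out.append(generate_subject(profile, duration_s, fs_hz))
        profiles.append(profile)
    if return_profiles:
        return out, profiles
    return out


def write_cohort(out_dir, cohort, profiles) -> None:
    """Export a cohort: per-subject WAV + states CSV, and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (rec, states), profile in zip(cohort, profiles):
        rec.to_wav(out_dir / f"{rec.subject_id}.wav")
        states.to_csv(out_dir / f"{rec.subject_id}_states.csv")
        rows.append({
            "subject_id": profile.subject_id,
            "label": profile.label,
            "heart_rate_bpm": profile.heart_rate_bpm,
            "hr_jitter": profile.hr_jitter,
            "murmur_snr_db": profile.murmur_snr_db,
            "desync_level": profile.desync_level,
            **{f"gain_{c + 1}": g for c, g in enumerate(profile.channel_gains)},
            "seed": profile.seed,
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
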
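"""Assembly of the 270-column feature table and the five feature sets.

Per 10-s segment: 20 time-domain + 16 frequency-domain + 12 entropy features
for each of the five channels (240 single-channel features) plus 30
cross-entropy features over the 10 channel pairs -- 270 columns in total,
in a canonical order (channel blocks 1-5, then the cross block).

Five feature sets are derived from the full table:

=====  =======================================================  =======
id     contents                                                 columns
=====  =======================================================  =======
Sin1   one channel, time + frequency                            36
Sin2   one channel, time + frequency + entropy                  48
Mul1   five channels, time + frequency                          180
Mul2   five channels, time + frequency + entropy                240
Mul3   Mul2 + cross entropy                                     270
=====  =======================================================  =======
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..preprocess import (DEFAULT_SEGMENT_S, QualityConfig, Segment,
                          filter_recording, crop_segments, assess_quality)
from ..segmentation import CycleAnnotation, segment_states
from .cross import (CHANNEL_PAIRS, CROSS_MEASURES, CrossEntropyParams,
                    DEFAULT_DECIMATION, cross_block)
from .entropy import ENTROPY_NAMES, EntropyParams, entropy_block
from .timefreq import (FREQ_FEATURE_NAMES, TIME_FEATURE_NAMES,
                       frequency_domain_features, time_domain_features)

META_COLUMNS = ("subject_id", "label", "segment_index")


def _mean_sd_names(base_names, channel) -> list:
    out = []
    for name in base_names:
        out.append(f"m_{name}_{channel}")
        out.append(f"sd_{name}_{channel}")
    return out


def channel_feature_names(channel: int) -> list:
    """The 48 single-channel feature names of one channel, canonical order."""
    return (_mean_sd_names(TIME_FEATURE_NAMES, channel)
            + _mean_sd_names(FREQ_FEATURE_NAMES, channel)
            + _mean_sd_names(ENTROPY_NAMES, channel))


def cross_feature_names() -> list:
    """The 30 cross-entropy feature names, measure-major."""
    return [f"{meas}_{pair}" for meas in CROSS_MEASURES
            for pair in CHANNEL_PAIRS]


def canonical_feature_names() -> list:
    """All 270 feature column names in canonical order."""
    names = []
    for ch in range(1, 6):
        names.extend(channel_feature_names(ch))
    names.extend(cross_feature_names())
    return names


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the per-segment feature extraction."""

    entropy: EntropyParams = field(default_factory=EntropyParams)
    cross: CrossEntropyParams = field(default_factory=CrossEntropyParams)
    cross_decimation: int = DEFAULT_DECIMATION


def extract_features(seg: Segment, annotations,
                     cfg: FeatureConfig = FeatureConfig()) -> dict:
    """One segment -> one 270-column feature row (plus metadata).

    ``annotations`` is either a single :class:`CycleAnnotation` shared by
    all channels (the ground-truth case) or a dict mapping channel number
    (1-5) to its annotation.  A failing feature block leaves its columns as
    NaN (with a warning) rather than dropping the row.
    """
    if isinstance(annotations, CycleAnnotation):
        anns = {ch: annotations for ch in range(1, 6)}
    else:
        anns = dict(annotations)
    row = {name: np.nan for name in canonical_feature_names()}
    row["subject_id"] = seg.subject_id
    row["label"] = seg.label
    row["segment_index"] = seg.segment_index
    for ch in range(1, 6):
        x = seg.samples[ch - 1]
        ann = anns[ch]
        try:
            row.update(time_domain_features(x, ann, seg.fs_hz, ch))
            row.update(frequency_domain_features(x, ann, seg.fs_hz, ch))
            row.update(entropy_block(x, ann, cfg.entropy, ch))
        except ValueError as exc:
            warnings.warn(f"channel {ch} features failed: {exc}")
    try:
        row.update(cross_block(seg, cfg.cross, cfg.cross_decimation))
    except ValueError as exc:
        warnings.warn(f"cross-entropy block failed: {exc}")
    return row


def extract_cohort_features(cohort, cfg: FeatureConfig = FeatureConfig(),
                            seg_len_s: float = DEFAULT_SEGMENT_S,
                            quality: QualityConfig = QualityConfig(),
                            drop_failed_quality: bool = True,
                            annotation_source: str = "ground_truth",
                            shared_channel: int = 2) -> pd.DataFrame:
    """Full pipeline for a list of ``(recording, ground_truth)`` pairs.

    Each recording is filtered, cropped into segments, quality-gated and
    annotated; unusable segments (quality fail or fewer than 3 complete
    cycles on any channel) are skipped.  ``annotation_source`` selects
    ground-truth pass-through (default for synthetic cohorts), per-channel
    envelope segmentation ("envelope"), or envelope segmentation of one
    channel shared by all ("envelope_shared", using ``shared_channel``).
    """
    if annotation_source not in ("ground_truth", "envelope",
                                 "envelope_shared"):
        raise ValueError(f"unknown annotation source {annotation_source!r}")
    rows = []
    for rec, truth in cohort:
        filtered = filter_recording(rec)
        for seg in crop_segments(filtered, seg_len_s):
            passed, _ = assess_quality(seg, quality)
            seg.quality_pass = passed
            if drop_failed_quality and not passed:
                continue
            if annotation_source == "ground_truth":
                anns = segment_states(seg, truth=truth)
                usable = anns.usable
            elif annotation_source == "envelope_shared":
                anns = segment_states(seg, channel=shared_channel - 1)
                usable = anns.usable
            else:
                anns = {ch: segment_states(seg, channel=ch - 1)
                        for ch in range(1, 6)}
                usable = all(a.usable for a in anns.values())
            if not usable:
                continue
            rows.append(extract_features(seg, anns, cfg))
    columns = list(META_COLUMNS) + canonical_feature_names()
    return pd.DataFrame(rows, columns=columns)


VALID_SET_IDS = ("Sin1", "Sin2", "Mul1", "Mul2", "Mul3")
EXPECTED_SET_SIZES = {"Sin1": 36, "Sin2": 48, "Mul1": 180,
                      "Mul2": 240, "Mul3": 270}


@dataclass(frozen=True)
class FeatureSetSpec:
    """One of the five feature-set definitions (column-selection rule)."""

    id: str
    channel: int | None = None

    def __post_init__(self):
        if self.id not in VALID_SET_IDS:
            raise ValueError(f"unknown feature set {self.id!r}")
        if self.id.startswith("Sin"):
            if self.channel is None:
                raise ValueError(f"{self.id} requires a channel (1-5)")
            if not 1 <= self.channel <= 5:
                raise ValueError("channel must be in 1..5")

    def columns(self) -> list:
        if self.id == "Sin1":
            return (_mean_sd_names(TIME_FEATURE_NAMES, self.channel)
                    + _mean_sd_names(FREQ_FEATURE_NAMES, self.channel))
        if self.id == "Sin2":
            return channel_feature_names(self.channel)
        if self.id == "Mul1":
            return [c for ch in range(1, 6)
                    for c in (_mean_sd_names(TIME_FEATURE_NAMES, ch)
                              + _mean_sd_names(FREQ_FEATURE_NAMES, ch))]
        if self.id == "Mul2":
            return [c for ch in range(1, 6) for c in channel_feature_names(ch)]
        return canonical_feature_names()


def build_feature_set(table: pd.DataFrame, spec: FeatureSetSpec) -> pd.DataFrame:
    """Select the metadata plus the spec's feature columns from the table."""
    cols = spec.columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns, e.g. {missing[:3]}")
    meta = [c for c in META_COLUMNS if c in table.columns]
    return table[meta + cols]


def drop_incomplete_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with any missing feature are excluded from modelling."""
    feat = [c for c in table.columns if c not in META_COLUMNS]
    n_bad = int(table[feat].isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} rows with missing features")
    return table.dropna(subset=feat).reset_index(drop=True)
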
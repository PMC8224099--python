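import numpy as np
import pytest
from hypothesis import settings

import pcgfusion as pf

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def metronome_profile():
    """Jitter-free 60 bpm non-CAD subject: exactly one cycle per second."""
    return pf.SubjectProfile("metro", "non-CAD", heart_rate_bpm=60.0,
                             hr_jitter=0.0, seed=7)


@pytest.fixture(scope="session")
def metronome_segment(metronome_profile):
    """One preprocessed 10-s segment with ground-truth annotation."""
    rec, states = pf.generate_recording(metronome_profile, duration_s=10.0)
    seg = pf.preprocess_recording(rec)[0]
    ann = pf.segment_states(seg, truth=states)
    return seg, ann


@pytest.fixture(scope="session")
def cad_pair():
    """A matched (non-CAD, CAD) pair: same base recording, the CAD copy has
    an audible murmur (0 dB) and strong dyssynchrony injected."""
    base = pf.SubjectProfile("pair", "CAD", heart_rate_bpm=72.0,
                             hr_jitter=0.02, murmur_snr_db=0.0,
                             desync_level=0.8, seed=41)
    rec, states = pf.generate_recording(base, duration_s=10.0)
    cad_rec = pf.inject_cad_signature(rec, states, base)
    seg_clean = pf.preprocess_recording(rec)[0]
    seg_cad = pf.preprocess_recording(cad_rec)[0]
    ann = pf.segment_states(seg_clean, truth=states)
    return seg_clean, seg_cad, ann


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
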
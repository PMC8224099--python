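"""Cross-entropy estimators (XSampEn, XFuzzyEn, JDistEn) vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcgfusion as pf
from pcgfusion.features.cross import (CHANNEL_PAIRS, CrossEntropyParams,
                                      cross_block, r_sweep)

from oracles import (disten_oracle, jdisten_oracle, xfuzzyen_oracle,
                     xsampen_oracle)

pair_series = st.tuples(
    st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False, width=32),
             min_size=15, max_size=60),
    st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False, width=32),
             min_size=15, max_size=60),
).map(lambda t: (np.asarray(t[0][:min(len(t[0]), len(t[1]))], float),
                 np.asarray(t[1][:min(len(t[0]), len(t[1]))], float)))


class TestXSampen:
    def test_self_comparison_includes_self_matches(self, rng):
        # xsampen(x, x) equals a SampEn variant that keeps self-matches
        x = rng.standard_normal(80)
        p = CrossEntropyParams(r=0.3)
        assert pf.xsampen(x, x, p) == pytest.approx(
            xsampen_oracle(x, x, 2, 1, 0.3), rel=1e-12)

    @given(xy=pair_series, r=st.floats(min_value=0.1, max_value=1.5))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce(self, xy, r):
        x, y = xy
        p = CrossEntropyParams(r=r)
        got = pf.xsampen(x, y, p)
        want = xsampen_oracle(x, y, 2, 1, r)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-12)

    def test_symmetry_exact(self, rng):
        p = CrossEntropyParams()
        for _ in range(50):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60)
            assert pf.xsampen(x, y, p) == pf.xsampen(y, x, p)

    def test_independent_noise_raises_value(self, rng):
        base = np.tile([1.0, 2.0, 3.0, 2.0], 30)
        clean = pf.xsampen(base, base.copy(), CrossEntropyParams(r=0.5))
        noisy = base + rng.standard_normal(base.size)
        assert pf.xsampen(base, noisy, CrossEntropyParams(r=0.5)) > clean

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pf.xsampen(np.zeros(30), np.zeros(31))


class TestXFuzzyen:
    def test_membership_at_r_is_half(self):
        # exp(-ln 2 * (d/r)^2) = 1/2 exactly at d = r
        assert np.exp(-np.log(2.0) * 1.0 ** 2) == 0.5

    @given(xy=pair_series, r=st.floats(min_value=0.1, max_value=1.5))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce(self, xy, r):
        x, y = xy
        assert pf.xfuzzyen(x, y, CrossEntropyParams(r=r)) == pytest.approx(
            xfuzzyen_oracle(x, y, 2, 1, r), rel=1e-10)

    def test_symmetric_and_nonnegative(self, rng):
        p = CrossEntropyParams()
        for _ in range(20):
            x, y = rng.standard_normal((2, 80))
            a, b = pf.xfuzzyen(x, y, p), pf.xfuzzyen(y, x, p)
            assert a == pytest.approx(b, rel=1e-12)
            assert a >= 0.0


class TestJDisten:
    def test_reduces_to_disten_on_identical_input(self, rng):
        x = rng.standard_normal(100)
        p = CrossEntropyParams(B=64)
        assert pf.jdisten(x, x, p) == pytest.approx(
            disten_oracle(x, 2, 64), rel=1e-12)

    @given(xy=pair_series, B=st.sampled_from([8, 64, 256]))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce(self, xy, B):
        x, y = xy
        assert pf.jdisten(x, y, CrossEntropyParams(B=B)) == pytest.approx(
            jdisten_oracle(x, y, 2, 1, B), rel=1e-12)

    def test_dyssynchrony_raises_jdisten_on_heart_sounds(self, cad_pair):
        # on matched PCG segments, per-channel timing jitter plus
        # independent noise (reduced synchrony) raises the joint
        # distribution entropy across channel pairs
        from pcgfusion.features.cross import cross_block
        seg_clean, seg_cad, _ = cad_pair
        clean = cross_block(seg_clean, decimation=8)
        cad = cross_block(seg_cad, decimation=8)
        pairs = [f"JDistEn_{pq}" for pq in CHANNEL_PAIRS]
        mean_clean = np.mean([clean[k] for k in pairs])
        mean_cad = np.mean([cad[k] for k in pairs])
        assert mean_cad > mean_clean

    def test_bounded_on_random_pairs(self, rng):
        p = CrossEntropyParams()
        for _ in range(50):
            n = int(rng.integers(30, 300))
            x, y = rng.standard_normal((2, n))
            assert 0.0 <= pf.jdisten(x, y, p) <= 1.0


class TestCrossBlock:
    def test_thirty_named_features(self, metronome_segment):
        seg, _ = metronome_segment
        block = cross_block(seg)
        assert len(block) == 30
        expected = {f"{m}_{pq}" for m in ("XSampEn", "XFuzzyEn", "JDistEn")
                    for pq in CHANNEL_PAIRS}
        assert set(block) == expected
        assert all(np.isfinite(v) for v in block.values())

    def test_identical_channels_equal_values(self, metronome_segment):
        seg, _ = metronome_segment
        clone = type(seg)(samples=np.tile(seg.samples[:1], (5, 1)),
                          fs_hz=seg.fs_hz, subject_id=seg.subject_id,
                          label=seg.label, segment_index=0)
        block = cross_block(clone)
        xs_values = [block[f"XSampEn_{pq}"] for pq in CHANNEL_PAIRS]
        assert np.ptp(xs_values) == 0.0

    def test_desync_raises_cross_entropies(self, cad_pair):
        seg_clean, seg_cad, _ = cad_pair
        clean = cross_block(seg_clean, decimation=8)
        cad = cross_block(seg_cad, decimation=8)
        larger = sum(cad[f"XSampEn_{pq}"] > clean[f"XSampEn_{pq}"]
                     for pq in CHANNEL_PAIRS)
        assert larger >= 8


class TestPerStateCrossBlock:
    def test_diastolic_restriction_returns_thirty_finite_values(
            self, metronome_segment):
        seg, ann = metronome_segment
        block = cross_block(seg, decimation=8, annotation=ann, state="Dia")
        assert len(block) == 30
        assert all(np.isfinite(v) for v in block.values())

    def test_state_without_annotation_rejected(self, metronome_segment):
        seg, _ = metronome_segment
        with pytest.raises(ValueError, match="annotation"):
            cross_block(seg, state="Dia")


class TestRSweep:
    def test_match_counts_monotone_in_r(self, rng):
        x, y = rng.standard_normal((2, 300))
        rows = r_sweep(x, y)
        assert [row["r"] for row in rows] == [0.1, 0.15, 0.2, 0.25, 0.3]
        counts = [row["matches_m"] for row in rows]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
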
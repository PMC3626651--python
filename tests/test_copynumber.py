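import numpy as np
import pandas as pd
import pytest

from derivchrom.copynumber import (
    DepthProfile,
    ProbeTableError,
    bin_depth,
    call_segments,
    detrend_waves,
    normalize_spline,
    probe_log2,
    subtract_matched,
)
from derivchrom.mapping import MateAlignment, PairCategory, ReadPairRecord


def probe_table(positions, test, reference, quality=1.0):
    n = len(positions)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "seq_name": "chr21",
            "position": np.asarray(positions),
            "test": np.asarray(test, float),
            "reference": np.asarray(reference, float),
            "quality": np.full(n, quality, float),
        }
    )


def correct_pair(pos, seq="g", pid="x:0", cat=PairCategory.SHORT_CORRECT):
    return ReadPairRecord(
        pair_id=pid, library="a",
        mate1=MateAlignment(seq, pos, "+", 60),
        mate2=MateAlignment(seq, pos + 300, "-", 60),
        read_length=75, category=cat,
    )


class TestBinDepth:
    def test_leftmost_coordinates_share_first_bin(self):
        pairs = [correct_pair(p, pid=f"x:{p}") for p in (1, 500, 999)]
        profile = bin_depth(pairs, "g", 5000)
        assert profile.counts[0] == 3
        assert profile.counts.sum() == 3

    def test_discordant_pairs_do_not_contribute(self):
        base = [correct_pair(p, pid=f"x:{p}") for p in (10, 20)]
        extra = [correct_pair(30, pid="d:0", cat=PairCategory.DISCORDANT)]
        assert bin_depth(base, "g", 5000).counts.sum() == \
            bin_depth(base + extra, "g", 5000).counts.sum()

    def test_duplicated_span_doubles_depth(self, small_sim):
        """The demo plan repeats graft segment (150 kb, 170 kb]; mapped to
        the (single-copy) reference its bins carry ~2x the graft baseline."""
        glen = len(small_sim.reference.graft_seq)
        profile = bin_depth(small_sim.records, "graft21", glen)
        dup = profile.counts[152:168].mean()
        flank = profile.counts[20:48].mean()
        assert 1.8 <= dup / flank <= 2.2

    def test_graft_depth_half_of_host(self, small_sim):
        gname = small_sim.reference.graft_name
        g = bin_depth(small_sim.records, gname, len(small_sim.reference.graft_seq))
        h = bin_depth(small_sim.records, "hostA", len(small_sim.reference.host["hostA"]))
        # compare away from rearranged spans: graft bins 20-48 kb are intact
        ratio = g.counts[20:48].mean() / h.counts[5:45].mean()
        assert 0.4 <= ratio <= 0.6


class TestNormalizeSpline:
    def test_equal_channels_unchanged(self):
        rng = np.random.default_rng(0)
        inten = 2.0 ** rng.normal(10, 1, 500)
        table = probe_table(np.arange(500) * 1000 + 1, inten, inten)
        out = normalize_spline(table)
        assert np.allclose(out["log2"], 0.0, atol=1e-9)

    def test_monotone_dye_bias_removed_including_extremes(self):
        rng = np.random.default_rng(1)
        n = 4000
        base = 2.0 ** rng.normal(10, 1.2, n)
        bias = 0.5 * np.tanh(np.log2(base) - 10)
        table = probe_table(np.arange(n) * 500 + 1, base * 2.0**bias, base)
        out = normalize_spline(table)
        log2 = out["log2"].to_numpy()
        assert np.median(np.abs(log2)) < 0.05
        # extreme intensity deciles rely on extrapolation
        g = np.log2(base)
        for sel in (g < np.quantile(g, 0.1), g > np.quantile(g, 0.9)):
            assert np.median(np.abs(log2[sel])) < 0.05

    def test_non_positive_probes_dropped(self):
        inten = np.full(200, 1000.0)
        table = probe_table(np.arange(200) * 100 + 1, inten, inten)
        table.loc[3, "test"] = 0.0
        out = normalize_spline(table)
        assert len(out) == 199
        assert out.attrs["n_dropped"] == 1

    def test_too_few_probes_rejected(self):
        t = probe_table([1, 2], [1, 1], [1, 1])
        with pytest.raises(ProbeTableError):
            normalize_spline(t)


class TestDetrendWaves:
    def mk(self, sig, spacing=500):
        n = len(sig)
        return probe_table(np.arange(n) * spacing + 1, 1000 * 2.0**sig, np.full(n, 1000.0))

    def test_flat_signal_unchanged(self):
        out = detrend_waves(self.mk(np.zeros(30_000)))
        assert np.abs(out["log2"]).max() < 1e-6

    def test_long_wave_removed(self):
        n = 30_000
        pos = np.arange(n) * 500 + 1
        wave = 0.3 * np.sin(2 * np.pi * pos / 10e6)
        out = detrend_waves(self.mk(wave))
        assert np.abs(out["log2"]).max() < 0.05

    def test_short_segment_preserved(self):
        sig = np.zeros(30_000)
        sig[5000:5010] = 0.9
        out = detrend_waves(self.mk(sig))
        seg = out["log2"].to_numpy()[5000:5010]
        assert abs(seg.mean() - 0.9) < 0.1

    def test_short_span_is_noop_with_warning(self):
        with pytest.warns(UserWarning, match="cutoff"):
            out = detrend_waves(self.mk(np.zeros(100)))
        assert np.allclose(out["log2"], 0.0)


class TestSubtractMatched:
    def test_identical_profiles_cancel(self):
        rng = np.random.default_rng(2)
        inten = 2.0 ** rng.normal(10, 1, 300)
        t = probe_table(np.arange(300) * 100 + 1, inten * 1.3, inten)
        out = subtract_matched(t, t.copy())
        assert np.allclose(out["log2"], 0.0)

    def test_shared_artifact_cancels_graft_event_survives(self):
        n = 2000
        base = np.full(n, 1000.0)
        artifact = np.zeros(n)
        artifact[100:200] = 0.8  # shared hybridization artifact
        event = np.zeros(n)
        event[1000:1100] = -1.0  # graft-only deletion
        pos = np.arange(n) * 100 + 1
        test = probe_table(pos, base * 2.0 ** (artifact + event), base)
        neg = probe_table(pos, base * 2.0**artifact, base)
        out = subtract_matched(test, neg)
        log2 = out["log2"].to_numpy()
        assert np.abs(log2[100:200]).max() < 0.1
        assert abs(log2[1000:1100].mean() + 1.0) < 0.05

    def test_probe_set_mismatch_rejected(self):
        a = probe_table([1, 2, 3], [1, 1, 1], [1, 1, 1])
        b = a.copy()
        b.loc[1, "probe_id"] = "other"
        with pytest.raises(ProbeTableError, match="mismatched"):
            subtract_matched(a, b)


class TestCallSegments:
    def test_flat_zero_signal_no_calls(self):
        t = probe_table(np.arange(500) * 100 + 1, np.full(500, 1000.0), np.full(500, 1000.0))
        segs = call_segments(t)
        assert all(s.state == "neutral" for s in segs)

    @pytest.mark.parametrize("run,expected_states", [(9, set()), (10, {"loss"})])
    def test_ten_probe_criterion(self, run, expected_states):
        n = 400
        sig = np.zeros(n)
        sig[200 : 200 + run] = -1.0
        t = probe_table(np.arange(n) * 100 + 1, 1000 * 2.0**sig, np.full(n, 1000.0))
        segs = call_segments(t)
        assert {s.state for s in segs if s.state != "neutral"} == expected_states

    def test_amplitude_criterion(self):
        n = 400
        sig = np.zeros(n)
        sig[100:150] = 0.4  # 50 probes but below |0.5|
        t = probe_table(np.arange(n) * 100 + 1, 1000 * 2.0**sig, np.full(n, 1000.0))
        assert all(s.state == "neutral" for s in call_segments(t))

    def test_planted_gain_boundaries_within_two_probes(self):
        rng = np.random.default_rng(3)
        n = 5000
        sig = np.zeros(n)
        sig[2000:2300] = 0.58
        noise = rng.normal(0, 0.1, n)
        pos = np.arange(n) * 500 + 1
        t = probe_table(pos, 1000 * 2.0 ** (sig + noise), np.full(n, 1000.0))
        gains = [s for s in call_segments(t) if s.state == "gain"]
        assert len(gains) == 1
        i0 = np.searchsorted(pos, gains[0].interval.start)
        i1 = np.searchsorted(pos, gains[0].interval.stop)
        assert abs(i0 - 2000) <= 2 and abs(i1 - 2299) <= 2

    def test_low_quality_probes_removed_first(self):
        n = 400
        sig = np.zeros(n)
        sig[200:212] = -1.0
        t = probe_table(np.arange(n) * 100 + 1, 1000 * 2.0**sig, np.full(n, 1000.0))
        t.loc[200:211, "quality"] = 0.2  # the event rests on unreliable probes
        assert all(s.state == "neutral" for s in call_segments(t))

    def test_segments_partition_span_without_overlap(self):
        rng = np.random.default_rng(4)
        n = 3000
        sig = np.zeros(n)
        sig[500:700] = 0.7
        sig[2000:2015] = -1.2
        pos = np.arange(n) * 200 + 1
        t = probe_table(pos, 1000 * 2.0 ** (sig + rng.normal(0, 0.1, n)), np.full(n, 1000.0))
        segs = call_segments(t)
        assert segs[0].interval.start == pos[0]
        assert segs[-1].interval.stop == pos[-1]
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.interval.stop < b.interval.start

    def test_depth_profile_input(self):
        counts = np.full(400, 40, dtype=np.int64)
        counts[100:140] = 80
        profile = DepthProfile("g", 1000, counts)
        gains = [s for s in call_segments(profile) if s.state == "gain"]
        assert len(gains) == 1
        assert gains[0].interval.start == 100_001
        assert gains[0].interval.stop == 140_000

    def test_empty_signal(self):
        t = probe_table([], [], [])
        assert call_segments(t) == []


def test_probe_log2_prefers_precomputed_column():
    t = probe_table([1], [8.0], [2.0])
    assert probe_log2(t)[0] == 2.0
    t["log2"] = [0.25]
    assert probe_log2(t)[0] == 0.25
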
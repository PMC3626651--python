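import random

import pytest

from derivchrom.insert_size import InsertProfile, estimate_insert_profile
from derivchrom.intervals import GenomeInterval
from derivchrom.mapping import MateAlignment, ReadPairRecord, dedupe, map_pairs
from derivchrom.notation import junction_key
from derivchrom.pipeline import _reads_near_clusters
from derivchrom.simulate import (
    JunctionPlan,
    LibrarySpec,
    RearrangementPlan,
    build_derivative,
    make_composite_reference,
    simulate_pairs,
)
from derivchrom.svcalls import (
    OrientationSignature,
    assemble_junction,
    classify_orientation,
    cluster_events,
    screen_discordant,
)


def profile(lib="a", threshold=550, mode=450):
    return InsertProfile(
        library=lib, histogram={mode: 100}, mode_bin=mode,
        upper_threshold=threshold, n_used=100,
    )


PROFILES = {"a": profile("a"), "b": profile("b"), "c": profile("c"),
            "l": profile("l", threshold=3600, mode=3000)}


def pair(p1, p2, s1="+", s2="-", q=60, seq1="g", seq2="g", pid="a:0", lib="a"):
    return ReadPairRecord(
        pair_id=pid, library=lib,
        mate1=MateAlignment(seq1, p1, s1, q),
        mate2=MateAlignment(seq2, p2, s2, q),
        read_length=75,
    )


class TestScreen:
    def test_concordant_pair_excluded(self):
        assert screen_discordant([pair(100, 425)], PROFILES) == []

    def test_over_distance_pair_included(self):
        (rec,) = screen_discordant([pair(100, 12_000)], PROFILES)
        assert rec.insert_size > 550

    def test_quality_threshold_is_strict(self):
        at_threshold = pair(100, 12_000, q=35)
        above = pair(100, 12_000, q=36, pid="a:1")
        out = screen_discordant([at_threshold, above], PROFILES)
        assert [r.pair_id for r in out] == ["a:1"]

    def test_cross_sequence_always_discordant(self):
        (rec,) = screen_discordant([pair(100, 400, seq2="h")], PROFILES)
        assert classify_orientation(rec) == OrientationSignature.CROSS_SEQUENCE

    def test_missing_profile_rejected(self):
        with pytest.raises(KeyError):
            screen_discordant([pair(100, 400, lib="zz")], PROFILES)


class TestClassify:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("+", "-", OrientationSignature.FR_DELETION),
        ("+", "+", OrientationSignature.FF_INVERSION),
        ("-", "+", OrientationSignature.RF_TANDEM_DUP),
        ("-", "-", OrientationSignature.RR_INVERSION),
    ])
    def test_signatures_by_leftmost_order(self, s1, s2, expected):
        assert classify_orientation(pair(100, 5000, s1, s2)) == expected
        # swapping mate labels must not change the signature
        assert classify_orientation(pair(5000, 100, s2, s1)) == expected

    def test_exhaustive_over_screened_pairs(self, small_sim):
        for rec in small_sim.discordant:
            assert classify_orientation(rec) in OrientationSignature

    def test_tandem_duplication_majority_signature(self, small_sim):
        """Pairs spanning the planted tandem-duplication junction carry the
        reverse-forward signature."""
        sigs = [
            classify_orientation(r)
            for r in small_sim.discordant
            if r.mate1.seq_name == "graft21"
            and 149_000 < min(r.mate1.pos, r.mate2.pos) < 153_500
            and 166_000 < max(r.mate1.pos, r.mate2.pos) < 170_001
        ]
        assert sigs
        rf = sum(s == OrientationSignature.RF_TANDEM_DUP for s in sigs)
        assert rf / len(sigs) > 0.9


class TestCluster:
    def test_single_pair_cluster_unconfirmed(self):
        (cluster,) = cluster_events([pair(100, 12_000)], PROFILES)
        assert cluster.n_pairs == 1 and not cluster.confirmed

    def test_three_pairs_three_libraries_confirmed(self):
        pairs = [
            pair(100, 12_000, pid="a:0", lib="a"),
            pair(140, 12_050, pid="b:0", lib="b"),
            pair(180, 12_100, pid="c:0", lib="c"),
        ]
        (cluster,) = cluster_events(pairs, PROFILES)
        assert cluster.confirmed
        assert cluster.libraries == {"a", "b", "c"}

    def test_two_pairs_one_library_not_confirmed(self):
        pairs = [pair(100, 12_000, pid="a:0"), pair(140, 12_050, pid="a:1")]
        (cluster,) = cluster_events(pairs, PROFILES)
        assert cluster.n_pairs == 2 and not cluster.confirmed

    def test_distant_events_never_merge(self):
        pairs = [
            pair(100, 12_000, pid="a:0"),
            pair(1_100_000, 1_112_000, pid="a:1"),
        ]
        clusters = cluster_events(pairs, PROFILES)
        assert len(clusters) == 2

    def test_order_independence(self, small_sim):
        shuffled = list(small_sim.discordant)
        random.Random(9).shuffle(shuffled)
        a = cluster_events(small_sim.discordant, small_sim.profiles)
        b = cluster_events(shuffled, small_sim.profiles)
        assert [(c.signature, c.interval_a, c.interval_b, c.pair_ids) for c in a] == \
            [(c.signature, c.interval_a, c.interval_b, c.pair_ids) for c in b]

    def test_large_insert_override(self):
        pairs = [pair(100, 12_000, pid="l:0", lib="l"), pair(150, 12_040, pid="l:1", lib="l")]
        (cluster,) = cluster_events(pairs, PROFILES)
        assert not cluster.confirmed
        assert cluster.confirmed_with(large_insert_override=frozenset({"l"}))


class TestAssembly:
    def test_confirmed_clusters_assemble_to_truth(self, small_sim):
        truth_keys = {junction_key(t) for t in small_sim.deriv.truth_junctions}
        assembled = []
        for cluster in small_sim.clusters:
            if not cluster.confirmed:
                continue
            informative, everything = small_sim.zone_reads[cluster.cluster_id]
            call = assemble_junction(
                cluster, informative, small_sim.reference.sequences,
                small_sim.read_length, fallback_reads=everything,
            )
            assert call.resolution == "assembled"
            assembled.append(junction_key(call.junction))
        assert set(assembled) <= truth_keys
        assert len(assembled) == 4  # every detectable planted junction

    def test_no_crossing_reads_falls_back_to_read_pair(self, small_sim):
        cluster = next(c for c in small_sim.clusters if c.confirmed)
        call = assemble_junction(
            cluster, [], small_sim.reference.sequences, small_sim.read_length
        )
        assert call.resolution == "read_pair"
        assert call.uncertainty_bp == cluster.window


class TestLargeInsertSensitivity:
    def test_repeat_flanked_junction_needs_large_insert_libraries(self):
        """A junction whose proximal flank is an ambiguous repeat longer
        than the small-insert span is detected only by large-insert pairs."""
        ref = make_composite_reference(120_000, {"hostA": 40_000}, seed=21)
        graft = ref.graft_seq
        # copy the 900 bp immediately left of the breakpoint elsewhere:
        # reads there become multi-mapping (quality 0)
        block = graft[49_100:50_000]
        graft = graft[:10_000] + block + graft[10_900:]
        ref = type(ref)(host=ref.host, graft_name=ref.graft_name, graft_seq=graft)
        plan = RearrangementPlan(
            segments=(
                (GenomeInterval("graft21", 1, 50_000), "F"),
                (GenomeInterval("graft21", 80_001, 120_000), "F"),
            ),
            junctions=(JunctionPlan(),),
        )
        deriv = build_derivative(ref, plan)
        libs = [
            LibrarySpec("s1", 450, 12, 75, 4000),
            LibrarySpec("s2", 500, 14, 75, 4000),
            LibrarySpec("s3", 550, 16, 75, 4000),
            LibrarySpec("l1", 3000, 15, 75, 2500),
            LibrarySpec("l2", 3500, 16, 75, 2500),
        ]
        genome = {**deriv.reference.host, "derivative": deriv.derivative}
        copies = {n: 2 for n in deriv.reference.host}
        copies["derivative"] = 1
        reads = simulate_pairs(genome, copies, libs, seed=22)
        records = dedupe(map_pairs(reads.pairs, deriv.reference))
        profiles = {l.name: estimate_insert_profile(records, l.name) for l in libs}
        clusters = cluster_events(
            screen_discordant(records, profiles), profiles
        )
        supporting = [
            c for c in clusters
            if c.signature == OrientationSignature.FR_DELETION
            and c.interval_a[1] < 50_001 <= c.interval_b[0] + 1000
            and c.n_pairs >= 2
        ]
        assert supporting
        libraries = set().union(*(c.libraries for c in supporting))
        assert libraries <= {"l1", "l2"}
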
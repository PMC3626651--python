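import pytest

from derivchrom.fixture import load_fixture
from derivchrom.intervals import GenomeInterval
from derivchrom.notation import JunctionSide, JunctionSpec
from derivchrom.pipeline import demo_plan, fixture_regions
from derivchrom.reconstruct import (
    ConstraintError,
    CopyNumberEvidence,
    GeneModel,
    SegmentationError,
    assemble_structure,
    build_region_graph,
    dosage_summary,
    expected_mutation_count,
    fixture_cn_evidence,
    gene_status,
    parse_bed12,
    segment_regions,
)
from derivchrom.sequtil import ASCENDING, DESCENDING
from derivchrom.simulate import RearrangementPlan, build_derivative, make_composite_reference


def iv(a, b, name="chr21"):
    return GenomeInterval(name, a, b)


def junction(lpos, rpos, ldir=ASCENDING, rdir=ASCENDING, name="chr21", **kw):
    return JunctionSpec(
        left=JunctionSide(name, lpos, ldir),
        right=JunctionSide(name, rpos, rdir),
        **kw,
    )


DEMO_CN = CopyNumberEvidence(
    losses=(iv(50_001, 70_000, "graft21"), iv(99_989, 120_000, "graft21"),
            iv(140_001, 150_000, "graft21")),
    gains=(iv(150_001, 170_000, "graft21"),),
)


class TestSegmentRegions:
    def test_no_evidence_single_region(self):
        (region,) = segment_regions([], None, 1_000_000)
        assert region.interval == iv(1, 1_000_000)
        assert region.copy_number == 1

    def test_regions_tile_chromosome(self, corpus):
        regions = fixture_regions()
        assert regions[0].interval.start == 1
        assert regions[-1].interval.stop == corpus.chrom_length
        assert sum(r.span for r in regions) == corpus.chrom_length
        for a, b in zip(regions[:-1], regions[1:]):
            assert b.interval.start == a.interval.stop + 1

    def test_fixture_corpus_yields_41_regions(self, corpus):
        regions = fixture_regions()
        assert len(regions) == 41

    def test_fixture_deleted_regions_match_reported_ids(self):
        regions = fixture_regions()
        deleted = [r.region_id for r in regions if r.copy_number == 0]
        assert deleted == [14, 16, 34, 39]

    def test_fixture_region_27_coordinates(self):
        """The only region whose coordinates the study prints explicitly."""
        r27 = fixture_regions()[26]
        assert r27.interval.start == 24_725_876
        assert abs(r27.interval.stop - 24_880_958) <= 1

    def test_hand_enumerated_boundary_oracle(self):
        """3 distant junctions + 1 deletion: region count equals the
        hand-enumerated distinct boundary count + 1."""
        junctions = [
            junction(100_000, 200_000),
            junction(300_000, 400_000, DESCENDING, DESCENDING),
            junction(500_000, 600_000),
        ]
        cn = CopyNumberEvidence(losses=(iv(700_000, 800_000),), gains=())
        regions = segment_regions(junctions, cn, 1_000_000)
        # cuts: 100000,199999 | 299999,400000 | 500000,599999 | 699999,800000
        assert len(regions) == 9
        deleted = [r for r in regions if r.copy_number == 0]
        assert len(deleted) == 1
        assert deleted[0].interval == iv(700_000, 800_000)

    def test_nearby_cuts_merge_to_junction_position(self):
        """An array change point within the merge radius collapses onto the
        base-pair-resolved junction boundary."""
        j = junction(100_000, 500_000, evidence_flags=frozenset({"pcr_verified"}))
        cn = CopyNumberEvidence(losses=(), gains=(iv(101_500, 300_000),))
        regions = segment_regions([j], cn, 1_000_000)
        starts = [r.interval.start for r in regions]
        assert 100_001 in starts
        assert 101_500 not in starts and 101_501 not in starts

    def test_boundary_outside_chromosome_rejected(self):
        with pytest.raises(SegmentationError):
            segment_regions([junction(100, 2_000_000)], None, 1_000_000)

    def test_analyzed_span_terminal_edge_is_not_a_change_point(self):
        cn = CopyNumberEvidence(losses=(), gains=(iv(900_000, 1_000_000),))
        with_span = segment_regions([], cn, 1_100_000, analyzed_span=(1, 1_000_000))
        without = segment_regions([], cn, 1_100_000)
        assert len(with_span) == len(without) - 1


@pytest.fixture(scope="module")
def demo():
    ref = make_composite_reference(200_000, {"hostA": 50_000}, seed=3)
    deriv = build_derivative(ref, demo_plan(200_000))
    regions = segment_regions(
        deriv.truth_junctions, DEMO_CN, 200_000, seq_name="graft21"
    )
    graph = build_region_graph(regions, deriv.truth_junctions)
    return deriv, regions, graph


class TestStructureAssembly:
    def test_unrearranged_simulation_single_path(self):
        ref = make_composite_reference(50_000, {"hostA": 10_000}, seed=4)
        plan = RearrangementPlan(segments=((iv(1, 50_000, "graft21"), "F"),))
        deriv = build_derivative(ref, plan)
        regions = segment_regions(deriv.truth_junctions, None, 50_000, seq_name="graft21")
        st = assemble_structure(build_region_graph(regions, []), regions)
        assert st.placed == [(1, "F")]
        assert st.unplaced == [] and st.confidence == []

    def test_demo_plan_round_trip(self, demo):
        """With every junction known and the duplicated copy linked by a
        junction, the walk reproduces the plan exactly."""
        deriv, regions, graph = demo
        st = assemble_structure(graph, regions)
        assert st.placed == [(1, "F"), (3, "F"), (5, "R"), (7, "F"), (7, "F"), (8, "F")]
        assert all(c == "certain" for c in st.confidence)
        assert st.unplaced == []

    def test_fixture_constraints_preserve_observed_order(self, corpus):
        regions = fixture_regions()
        graph = build_region_graph(regions, list(corpus.junctions))
        fish_order = [11, 20, 22, 24, 19, 18, 25, 17, 13, 28, 26, 6, 15, 35, 32,
                      5, 9, 10, 33, 38, 40, 36, 37, 31, 29, 23, 22, 21, 20, 11]
        st = assemble_structure(graph, regions, constraints=[fish_order])
        placed_ids = [rid for rid, _ in st.placed]
        target = iter(placed_ids)
        assert all(x in target for x in [11, 20, 22, 24, 19, 18, 25, 17, 13])
        assert "suggested" in st.confidence

    def test_contradictory_constraints_rejected(self, demo):
        _, regions, graph = demo
        with pytest.raises(ConstraintError, match="conflicting"):
            assemble_structure(graph, regions, constraints=[[1, 3], [1, 5]])


class TestDosage:
    def test_no_events(self):
        regions = segment_regions([], None, 1_000_000)
        d = dosage_summary(regions, 1_000_000)
        assert d.fraction_deleted == 0.0 and d.fraction_duplicated == 0.0

    def test_fixture_duplicated_fraction_rounds_to_reported_percent(self, corpus):
        d = dosage_summary(fixture_regions(), corpus.chrom_length)
        assert round(100 * d.fraction_duplicated, 1) == 10.0

    def test_fixture_deleted_fraction_in_expected_band(self, corpus):
        d = dosage_summary(fixture_regions(), corpus.chrom_length)
        assert 0.085 <= d.fraction_deleted <= 0.088

    def test_deleted_and_duplicated_unions_disjoint(self, corpus):
        d = dosage_summary(fixture_regions(), corpus.chrom_length)
        for a in d.deleted_intervals:
            assert not any(a.overlaps(b) for b in d.duplicated_intervals)

    def test_non_tiling_regions_rejected(self):
        (region,) = segment_regions([], None, 1000)
        with pytest.raises(SegmentationError):
            dosage_summary([region], 2000)


def gene(name, start, stop, exons, strand="+", chrom="chr21"):
    return GeneModel(
        gene_id=name, seq_name=chrom, start=start, stop=stop, strand=strand,
        exons=tuple(iv(a, b, chrom) for a, b in exons),
    )


class TestGeneStatus:
    REGIONS = segment_regions(
        [],
        CopyNumberEvidence(
            losses=(iv(100_000, 200_000),), gains=(iv(500_000, 600_000),)
        ),
        1_000_000,
    )

    def classify(self, g, junctions=()):
        statuses, _ = gene_status([g], self.REGIONS, list(junctions))
        return statuses[0].status

    def test_single_copy_gene(self):
        assert self.classify(
            gene("plain", 300_000, 310_000, [(300_000, 310_000)])
        ) == "one_copy"

    def test_fully_deleted_and_partially_deleted(self):
        assert self.classify(
            gene("gone", 120_000, 130_000, [(120_000, 130_000)])
        ) == "deleted"
        assert self.classify(
            gene("edge", 190_000, 210_000, [(190_000, 210_000)])
        ) == "partially_deleted"

    def test_duplicated_and_partially_duplicated(self):
        assert self.classify(
            gene("dup", 510_000, 520_000, [(510_000, 520_000)])
        ) == "duplicated"
        assert self.classify(
            gene("halfdup", 590_000, 620_000, [(590_000, 620_000)])
        ) == "partially_duplicated"

    def test_junction_inside_gene_body_disrupts_even_in_intron(self):
        g = gene("split", 300_000, 320_000,
                 [(300_000, 302_000), (318_000, 320_000)])
        j = junction(310_000, 700_000)  # lands in the intron
        statuses, _ = gene_status([g], self.REGIONS, [j])
        assert statuses[0].status == "disrupted"
        assert statuses[0].disrupting_junctions == (0,)

    def test_inconsistent_exon_bounds_rejected(self):
        with pytest.raises(ValueError, match="exon"):
            gene("bad", 100, 200, [(150, 300)])

    def test_in_frame_fusion_and_insertion_frame_shift(self):
        """First exon of gene A joined to the final exons of gene B: in
        frame when the retained upstream coding length is a multiple of 3
        relative to B's phase; one inserted base shifts it out of frame."""
        a = gene("upstream", 300_000, 306_000,
                 [(300_000, 300_500), (305_000, 306_000)])
        b = gene("downstream", 700_000, 710_000,
                 [(700_000, 700_400), (705_000, 706_000), (709_000, 710_000)])
        # junction keeps 501 coding bases of A (intron landing, mod 3 == 0)
        # and discards the first 3 coding bases of B (phase 0)
        j_in_frame = junction(304_999, 700_003)
        _, fusions = gene_status([a, b], self.REGIONS, [j_in_frame])
        assert len(fusions) == 1
        assert fusions[0].upstream_gene == "upstream"
        assert fusions[0].in_frame

        j_shifted = junction(304_999, 700_003, inserted="A")
        _, fusions2 = gene_status([a, b], self.REGIONS, [j_shifted])
        assert not fusions2[0].in_frame

    def test_bed12_parsing(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text(
            "chr21\t299999\t306000\tupstream\t0\t+\t299999\t306000\t0\t2\t"
            "501,1000\t0,5001\n"
        )
        (g,) = parse_bed12(str(bed))
        assert g.gene_id == "upstream"
        assert g.start == 300_000 and g.stop == 306_000
        assert g.exons[0] == iv(300_000, 300_500)
        assert g.coding_length == 1501


class TestMutationBurden:
    def test_reported_assumptions_give_order_ten(self):
        expected = expected_mutation_count(48_129_895, 1000, 1e-6, 200)
        assert abs(expected - 9.626) < 0.01

    def test_zero_dose(self):
        assert expected_mutation_count(48_129_895, 1000, 1e-6, 0) == 0.0

    def test_linear_in_dose(self):
        one = expected_mutation_count(1_000_000, 1000, 1e-6, 100)
        assert expected_mutation_count(1_000_000, 1000, 1e-6, 200) == 2 * one

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            expected_mutation_count(0, 1000, 1e-6, 1)
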
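"""Config-driven end-to-end runs: simulate -> map -> thresholds -> CN -> SV
-> junction anatomy -> reconstruction -> summary report."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from .copynumber import bin_depth, call_segments
from .fixture import load_fixture
from .insert_size import estimate_insert_profile, thresholds_for_categorization
from .intervals import GenomeInterval
from .mapping import categorize_pair, dedupe, map_pairs, write_sam
from .reconstruct import (
    CopyNumberEvidence,
    assemble_structure,
    build_region_graph,
    dosage_summary,
    fixture_cn_evidence,
    segment_regions,
)
from .simulate import (
    CompositeReference,
    DerivativeResult,
    JunctionPlan,
    LibrarySpec,
    RearrangementPlan,
    build_derivative,
    make_composite_reference,
    simulate_pairs,
    write_fasta,
)
from .svcalls import assemble_junction, cluster_events, screen_discordant

log = logging.getLogger("derivchrom")


@dataclass
class PipelineConfig:
    """Defaults equal the published analysis parameters."""

    seed: int = 1
    out_dir: str = "run"
    k: int = 31
    min_quality: int = 35
    min_pairs: int = 2
    min_libraries: int = 3
    depth_bin: int = 1000
    probe_quality_min: float = 0.6
    call_min_count: int = 10
    call_min_abs_log2: float = 0.5
    assembly_window: int = 4000
    insert_bin: int = 10
    insert_ratio: float = 1.1
    insert_margin: int = 50
    merge_radius: int = 3000
    graft_length: int = 400_000
    host_lengths: dict[str, int] = field(
        default_factory=lambda: {"hostA": 150_000, "hostB": 150_000}
    )
    libraries: list[LibrarySpec] = field(default_factory=list)
    pair_density: float = 10.0  # pairs x read bases per genome base (approx)
    stages: tuple[str, ...] = ("simulate", "map", "insertstats", "depth", "sv",
                               "junctions", "reconstruct", "report")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["libraries"] = [dataclasses.asdict(l) for l in self.libraries]
        return d


def default_libraries(n_pairs_small: int, n_pairs_large: int) -> list[LibrarySpec]:
    """Three small- and two large-insert libraries, emulating a mixed design.

    Insert distributions are tight (sd ~ 1-5% of the mean, as for
    size-selected libraries); the 10 bp ratio-scan threshold estimator
    presumes a histogram that falls steeply from its mode, which very
    broad libraries would not satisfy.
    """
    return [
        LibrarySpec("s1", 450, 12, 75, n_pairs_small),
        LibrarySpec("s2", 500, 14, 75, n_pairs_small),
        LibrarySpec("s3", 550, 16, 75, n_pairs_small),
        LibrarySpec("l1", 3000, 15, 75, n_pairs_large),
        LibrarySpec("l2", 3500, 16, 75, n_pairs_large),
    ]


def demo_plan(graft_length: int, seq_name: str = "graft21") -> RearrangementPlan:
    """A small plan exercising the event classes the pipeline must resolve:
    a deletion, an inversion and a tandem duplication, with NHEJ-style
    junctions carrying 0-3 bp micro-homology and one short insertion."""
    L = graft_length
    u = L // 20
    segs = [
        (GenomeInterval(seq_name, 1, 5 * u), "F"),
        (GenomeInterval(seq_name, 7 * u + 1, 10 * u), "F"),      # deletion of (5u,7u]
        (GenomeInterval(seq_name, 12 * u + 1, 14 * u), "R"),     # inversion
        (GenomeInterval(seq_name, 15 * u + 1, 17 * u), "F"),
        (GenomeInterval(seq_name, 15 * u + 1, 17 * u), "F"),     # tandem duplication
        (GenomeInterval(seq_name, 17 * u + 1, L), "F"),
    ]
    juncs = [
        JunctionPlan(microhomology_len=3),
        JunctionPlan(microhomology_len=2, deleted_left=12),
        JunctionPlan(inserted="TTAACCGGTT"),
        JunctionPlan(microhomology_len=1),
        JunctionPlan(),
    ]
    return RearrangementPlan(segments=tuple(segs), junctions=tuple(juncs))


@dataclass
class PipelineResult:
    reference: CompositeReference
    derivative: DerivativeResult
    records: list
    profiles: dict
    clusters: list
    calls: list
    regions: list
    structure: object
    summary: dict


def run_pipeline(config: PipelineConfig, plan: RearrangementPlan | None = None
                 ) -> PipelineResult:
    """Run the configured stages end to end over a simulated genome.

    Every run writes a resolved-config record and a machine-readable
    summary into ``config.out_dir``; identical config + seed gives an
    identical summary.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "config.json"), "w") as fh:
        json.dump(config.resolved(), fh, indent=2, default=str)
    stages = set(config.stages)
    summary: dict = {"stages": sorted(stages)}
    ref = deriv = None
    records: list = []
    profiles: dict = {}
    clusters: list = []
    calls: list = []
    regions: list = []
    structure = None

    if "simulate" in stages:
        ref = make_composite_reference(
            config.graft_length, config.host_lengths, seed=config.seed
        )
        plan = plan or demo_plan(config.graft_length)
        deriv = build_derivative(ref, plan)
        libraries = config.libraries or _scaled_libraries(config, ref, deriv)
        genome = {**deriv.reference.host, "derivative": deriv.derivative}
        copies = {name: 2 for name in deriv.reference.host}
        copies["derivative"] = 1
        reads = simulate_pairs(genome, copies, libraries, seed=config.seed + 1)
        write_fasta(deriv.reference.sequences, os.path.join(config.out_dir, "reference.fa"))
        write_fasta({"derivative": deriv.derivative},
                    os.path.join(config.out_dir, "derivative.fa"))
        summary["n_truth_junctions"] = len(deriv.truth_junctions)
        summary["n_pairs_simulated"] = len(reads.pairs)
        log.info("simulated %d pairs over %d-junction plan",
                 len(reads.pairs), len(deriv.truth_junctions))
    else:
        reads = None

    if "map" in stages and reads is not None:
        records = map_pairs(reads.pairs, deriv.reference, k=config.k)
        records = dedupe(records)
        summary["n_pairs_mapped"] = len(records)

    if "insertstats" in stages and records:
        libs = sorted({r.library for r in records})
        profiles = {
            lib: estimate_insert_profile(
                records, lib, bin_width=config.insert_bin,
                ratio=config.insert_ratio, margin=config.insert_margin,
            )
            for lib in libs
        }
        thresholds = thresholds_for_categorization(profiles)
        records = [categorize_pair(r, thresholds) for r in records]
        summary["insert_thresholds"] = {
            lib: p.upper_threshold for lib, p in profiles.items()
        }
        write_sam(records, {**deriv.reference.lengths()},
                  os.path.join(config.out_dir, "mapped.sam"))

    if "depth" in stages and records:
        gname = deriv.reference.graft_name
        profile = bin_depth(records, gname, len(deriv.reference.graft_seq),
                            bin_width=config.depth_bin)
        summary["graft_mean_depth"] = float(profile.counts.mean())
        depth_segments = call_segments(
            profile, min_count=config.call_min_count,
            min_abs_log2=config.call_min_abs_log2,
        )
        summary["n_depth_segments"] = len(depth_segments)

    if "sv" in stages and records and profiles:
        disc = screen_discordant(records, profiles, min_quality=config.min_quality)
        clusters = cluster_events(disc, profiles, min_quality=config.min_quality)
        summary["n_discordant_pairs"] = len(disc)
        summary["n_clusters"] = len(clusters)
        summary["n_confirmed_clusters"] = sum(c.confirmed for c in clusters)

    if "junctions" in stages and clusters:
        read_length = records[0].read_length
        refseqs = deriv.reference.sequences
        by_seq_reads = _reads_near_clusters(reads, records, clusters,
                                            config.assembly_window)
        for cluster in clusters:
            if not cluster.confirmed:
                continue
            informative, everything = by_seq_reads.get(cluster.cluster_id, ([], []))
            calls.append(
                assemble_junction(
                    cluster, informative, refseqs, read_length,
                    fallback_reads=everything,
                )
            )
        summary["n_assembled_calls"] = sum(
            1 for c in calls if c.resolution == "assembled"
        )

    if "reconstruct" in stages and deriv is not None:
        gname = deriv.reference.graft_name
        regions = segment_regions(
            calls or deriv.truth_junctions, None,
            chrom_length=len(deriv.reference.graft_seq), seq_name=gname,
            merge_radius=config.merge_radius,
        )
        graph = build_region_graph(regions, calls or deriv.truth_junctions,
                                   merge_radius=config.merge_radius)
        structure = assemble_structure(graph, regions)
        summary["n_regions"] = len(regions)
        summary["n_placed"] = len(structure.placed)

    if "report" in stages:
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    return PipelineResult(
        reference=ref, derivative=deriv, records=records, profiles=profiles,
        clusters=clusters, calls=calls, regions=regions, structure=structure,
        summary=summary,
    )


def _scaled_libraries(config, ref, deriv) -> list[LibrarySpec]:
    genome_bp = sum(
        len(s) * 2 for s in deriv.reference.host.values()
    ) + len(deriv.derivative)
    total_pairs = int(config.pair_density * genome_bp / 150)
    small = int(total_pairs * 0.26)
    large = (total_pairs - 3 * small) // 2
    return default_libraries(small, max(large, 1))


def _reads_near_clusters(reads, records, clusters, window) -> dict[int, list[str]]:
    """Read sequences mapping within ``window`` of each cluster's breakpoints."""
    seq_by_pid = {pid: (r1, r2) for pid, r1, r2 in reads.pairs}
    rec_by_pid = {r.pair_id: r for r in records}
    out: dict[int, list[str]] = {}
    for cluster in clusters:
        if not cluster.confirmed:
            continue
        lo_a, hi_a = cluster.interval_a
        lo_b, hi_b = cluster.interval_b
        zones = [
            (cluster.seq_a, lo_a - window, hi_a + window),
            (cluster.seq_b, lo_b - window, hi_b + window),
        ]
        informative_reads: list[str] = []
        all_reads: list[str] = []
        members = set(cluster.pair_ids)
        for rec in records:
            hit = any(
                mate.seq_name == name and lo <= mate.pos <= hi
                for mate in (rec.mate1, rec.mate2)
                if mate.seq_name is not None
                for name, lo, hi in zones
            )
            if not hit:
                continue
            pair_seqs = seq_by_pid.get(rec.pair_id)
            if not pair_seqs:
                continue
            all_reads.extend(pair_seqs)
            # rearrangement-informative: cluster members and pairs whose
            # unmapped partner (a junction-crossing read) hangs off a mate
            # mapped in the zone
            if rec.pair_id in members or (
                (rec.mate1.seq_name is None) != (rec.mate2.seq_name is None)
            ):
                informative_reads.extend(pair_seqs)
        out[cluster.cluster_id] = (informative_reads, all_reads)
    return out


def fixture_regions(merge_radius: int = 3000):
    """Regions of the packaged corpus (junctions + printed aCGH intervals)."""
    corpus = load_fixture()
    return segment_regions(
        list(corpus.junctions),
        fixture_cn_evidence(corpus),
        chrom_length=corpus.chrom_length,
        seq_name=corpus.seq_name,
        merge_radius=merge_radius,
        analyzed_span=corpus.analyzed_span,
    )


def fixture_summary(merge_radius: int = 3000) -> dict:
    corpus = load_fixture()
    regions = fixture_regions(merge_radius)
    dosage = dosage_summary(regions, corpus.chrom_length)
    return {
        "n_regions": len(regions),
        "fraction_deleted": dosage.fraction_deleted,
        "fraction_duplicated": dosage.fraction_duplicated,
        "deleted_region_ids": [r.region_id for r in regions if r.copy_number == 0],
        "duplicated_region_ids": [r.region_id for r in regions if r.copy_number >= 2],
    }
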
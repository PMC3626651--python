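"""Derivative-chromosome reconstruction from breakpoints + copy-number calls.

The chromosome is partitioned into *regions* — maximal intervals
uninterrupted by any rearrangement breakpoint or copy-number change
point. Boundary evidence comes at very different resolutions: junction
sides sequenced to the base pair, junction flanking-deletion edges, and
array change points localized only to a few kb. Boundaries closer
together than a merge radius (default 3 kb, the array's change-point
localization uncertainty) describe the same physical breakpoint and are
collapsed, with the most precise member (sequence beats array) as the
representative. A copy-number interval edge coinciding with the end of
the probed span is a span edge, not a change point, and contributes no
boundary.

Regions are then assembled into the derivative structure: junctions are
edges between oriented region ends, maximal unambiguous paths form
sections, and external ordering constraints (e.g. FISH observations)
merge sections with "suggested" confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .intervals import GenomeInterval, merge_intervals, subtract_interval, union_spans
from .notation import JunctionSpec
from .sequtil import ASCENDING
from .svcalls import BreakpointCall

# cut-source priorities: lower wins when choosing a boundary representative
_PRIO_JUNCTION_EXACT = 0
_PRIO_FLANK_EDGE = 1
_PRIO_JUNCTION_APPROX = 2
_PRIO_ARRAY = 3


@dataclass(frozen=True)
class Region:
    region_id: int
    interval: GenomeInterval
    copy_number: int
    note: str  # deleted | duplicated | triplicated | normal

    @property
    def span(self) -> int:
        return self.interval.span


@dataclass
class DerivativeStructure:
    placed: list[tuple[int, str]]  # (region id, "F"/"R")
    unplaced: list[int]
    confidence: list[str]  # per adjacency in ``placed``: "certain"/"suggested"


@dataclass(frozen=True)
class GeneStatus:
    gene_id: str
    status: str
    disrupting_junctions: tuple[int, ...] = ()


@dataclass(frozen=True)
class FusionCandidate:
    upstream_gene: str
    downstream_gene: str
    junction_index: int
    in_frame: bool


class SegmentationError(ValueError):
    pass


def _junction_cuts(spec: JunctionSpec) -> list[tuple[int, int]]:
    """(cut position, priority) pairs for one junction.

    A cut after position p separates p from p+1. A side whose retained
    flank lies at coordinates <= pos (left-ascending, right-descending)
    cuts after pos; a side whose flank lies at coordinates >= pos cuts
    after pos - 1. Flanking-deletion intervals contribute their own edge
    cuts (the deleted bases bound retained sequence on both sides).
    """
    prio = (
        _PRIO_JUNCTION_EXACT if spec.pcr_verified else _PRIO_JUNCTION_APPROX
    )
    cuts = []
    left_cut = spec.left.pos if spec.left.direction == ASCENDING else spec.left.pos - 1
    right_cut = (
        spec.right.pos - 1 if spec.right.direction == ASCENDING else spec.right.pos
    )
    cuts.append((left_cut, prio))
    cuts.append((right_cut, prio))
    for iv in (spec.deleted_proximal, spec.deleted_distal):
        if iv is not None:
            cuts.append((iv.start - 1, _PRIO_FLANK_EDGE))
            cuts.append((iv.stop, _PRIO_FLANK_EDGE))
    return cuts


def _cn_interval_cuts(
    intervals: list[GenomeInterval], analyzed_span: tuple[int, int]
) -> list[tuple[int, int]]:
    lo, hi = analyzed_span
    cuts = []
    for iv in intervals:
        for cut in (iv.start - 1, iv.stop):
            if cut in (lo - 1, hi):  # span edge, not a change point
                continue
            cuts.append((cut, _PRIO_ARRAY))
    return cuts


@dataclass(frozen=True)
class CopyNumberEvidence:
    """Loss/gain intervals driving region copy-number annotation."""

    losses: tuple[GenomeInterval, ...]
    gains: tuple[GenomeInterval, ...]


def fixture_cn_evidence(corpus) -> CopyNumberEvidence:
    """Loss/gain intervals from a fixture corpus (deletions minus retained
    blocks, plus duplications)."""
    losses = []
    for iv, retained in corpus.acgh_deletions:
        losses.extend(subtract_interval(iv, [retained] if retained else []))
    return CopyNumberEvidence(
        losses=tuple(losses), gains=tuple(corpus.acgh_duplications)
    )


def segment_regions(
    junctions: list[JunctionSpec | BreakpointCall],
    cn_evidence: CopyNumberEvidence | None,
    chrom_length: int,
    seq_name: str = "chr21",
    merge_radius: int = 3000,
    analyzed_span: tuple[int, int] | None = None,
) -> list[Region]:
    """Partition [1, chrom_length] at junction and copy-number boundaries.

    Boundaries within ``merge_radius`` of each other (single linkage) are
    one physical breakpoint; the representative is the highest-precision
    cut. Regions are annotated with copy number 0/1/2 by majority overlap
    with the loss/gain evidence.
    """
    specs = [j.junction if isinstance(j, BreakpointCall) else j for j in junctions]
    cuts: list[tuple[int, int]] = []
    for spec in specs:
        cuts.extend(_junction_cuts(spec))
    if cn_evidence is not None:
        span = analyzed_span or (1, chrom_length)
        cuts.extend(
            _cn_interval_cuts(list(cn_evidence.losses) + list(cn_evidence.gains), span)
        )
    for cut, _ in cuts:
        if not 0 <= cut <= chrom_length:
            raise SegmentationError(f"boundary {cut} outside [1, {chrom_length}]")
    cuts = sorted({c for c in cuts if 0 < c[0] < chrom_length})
    # single-linkage clusters along the line
    boundaries: list[int] = []
    cluster: list[tuple[int, int]] = []
    for cut in cuts:
        if cluster and cut[0] - cluster[-1][0] > merge_radius:
            boundaries.append(_representative(cluster))
            cluster = []
        cluster.append(cut)
    if cluster:
        boundaries.append(_representative(cluster))

    losses = merge_intervals(cn_evidence.losses) if cn_evidence else []
    gains = merge_intervals(cn_evidence.gains) if cn_evidence else []
    regions = []
    prev = 0
    for i, b in enumerate(boundaries + [chrom_length]):
        iv = GenomeInterval(seq_name, prev + 1, b)
        copy, note = _annotate(iv, losses, gains)
        regions.append(Region(region_id=i + 1, interval=iv, copy_number=copy, note=note))
        prev = b
    return regions


def _representative(cluster: list[tuple[int, int]]) -> int:
    best_prio = min(p for _, p in cluster)
    return min(c for c, p in cluster if p == best_prio)


def _overlap_bp(iv: GenomeInterval, others: list[GenomeInterval]) -> int:
    return sum(
        min(iv.stop, o.stop) - max(iv.start, o.start) + 1
        for o in others
        if o.overlaps(iv)
    )


def _annotate(iv, losses, gains) -> tuple[int, str]:
    if _overlap_bp(iv, losses) > iv.span / 2:
        return 0, "deleted"
    if _overlap_bp(iv, gains) > iv.span / 2:
        return 2, "duplicated"
    return 1, "normal"


# --- derivative structure assembly --------------------------------------


def _region_port_of_cut(cut: int, boundaries: list[int], merge_radius: int):
    """Map a cut position to (region index of the boundary, side).

    Returns the index i of the nearest boundary (regions i and i+1 meet
    there); raises if the cut is not near any boundary.
    """
    best = min(range(len(boundaries)), key=lambda i: abs(boundaries[i] - cut))
    if abs(boundaries[best] - cut) > merge_radius:
        raise SegmentationError(f"junction cut {cut} not at any region boundary")
    return best


def build_region_graph(
    regions: list[Region],
    junctions: list[JunctionSpec | BreakpointCall],
    merge_radius: int = 3000,
) -> nx.MultiGraph:
    """Graph of region ports joined by junction edges.

    Each region has an ``L`` (low-coordinate) and ``R`` (high-coordinate)
    port. A junction side leaving ascending occupies the R port of the
    region ending at its boundary; a descending side occupies the L port
    of the region starting there. Reference adjacency is retained at
    boundaries where neither flanking port is consumed by a junction and
    no copy-number drop to zero intervenes.
    """
    specs = [j.junction if isinstance(j, BreakpointCall) else j for j in junctions]
    boundaries = [r.interval.stop for r in regions[:-1]]
    g = nx.MultiGraph()
    for r in regions:
        g.add_node((r.region_id, "L"), region=r.region_id)
        g.add_node((r.region_id, "R"), region=r.region_id)
    consumed: set[tuple[int, str]] = set()

    def port_for_side(side) -> tuple[int, str]:
        cut = side.pos if side.direction == ASCENDING else side.pos - 1
        b = _region_port_of_cut(cut, boundaries, merge_radius)
        if side.direction == ASCENDING:
            return (regions[b].region_id, "R")  # flank at coords <= boundary
        return (regions[b + 1].region_id, "L")  # flank at coords >= boundary

    for i, spec in enumerate(specs):
        # the left side's port faces *into* the junction from its flank;
        # the right side symmetric. Directions: ascending flank sits low
        # of the boundary for a left side but high for a right side.
        lcut = spec.left.pos if spec.left.direction == ASCENDING else spec.left.pos - 1
        lb = _region_port_of_cut(lcut, boundaries, merge_radius)
        lport = (
            (regions[lb].region_id, "R")
            if spec.left.direction == ASCENDING
            else (regions[lb + 1].region_id, "L")
        )
        rcut = (
            spec.right.pos - 1 if spec.right.direction == ASCENDING else spec.right.pos
        )
        rb = _region_port_of_cut(rcut, boundaries, merge_radius)
        rport = (
            (regions[rb + 1].region_id, "L")
            if spec.right.direction == ASCENDING
            else (regions[rb].region_id, "R")
        )
        g.add_edge(lport, rport, junction=i, kind="junction")
        consumed.update([lport, rport])

    by_id = {r.region_id: r for r in regions}
    for i, b in enumerate(boundaries):
        left_r, right_r = regions[i], regions[i + 1]
        pa, pb = (left_r.region_id, "R"), (right_r.region_id, "L")
        if pa in consumed or pb in consumed:
            continue
        if left_r.copy_number == 0 or right_r.copy_number == 0:
            continue
        g.add_edge(pa, pb, kind="reference")
    for r in regions:
        if r.copy_number == 0:
            g.remove_nodes_from([(r.region_id, "L"), (r.region_id, "R")])
    return g


def _walk_sections(
    g: nx.MultiGraph, regions: list[Region]
) -> tuple[list[list[tuple[int, str]]], dict[int, int]]:
    """Maximal unambiguous oriented paths through the port graph.

    Each junction/reference edge is traversed at most once and each region
    is visited at most copy-number times. At a branch point the walk
    prefers the edge looping back into the same region when copies remain
    (a tandem duplication traverses its segment twice in a row); any other
    ambiguity ends the section. Returns the sections plus the leftover
    visit budget per region (copies with no placement evidence).
    """
    budget = {r.region_id: r.copy_number for r in regions if r.copy_number > 0}
    budget = {rid: n for rid, n in budget.items() if (rid, "L") in g.nodes}
    used: set[tuple] = set()

    def edge_key(u, v, k):
        return (min(u, v), max(u, v), k)

    def unused_at(port):
        return sorted(
            (v, k) for _, v, k in g.edges(port, keys=True)
            if edge_key(port, v, k) not in used
        )

    sections: list[list[tuple[int, str]]] = []
    while True:
        starts = [
            p for p in sorted(g.nodes)
            if budget.get(g.nodes[p]["region"], 0) > 0
            and not unused_at(p) and unused_at((p[0], "R" if p[1] == "L" else "L"))
        ]
        if not starts:
            break
        port = starts[0]
        section: list[tuple[int, str]] = []
        while True:
            rid = g.nodes[port]["region"]
            if budget.get(rid, 0) <= 0:
                break
            budget[rid] -= 1
            section.append((rid, "F" if port[1] == "L" else "R"))
            exit_port = (rid, "R" if port[1] == "L" else "L")
            cands = unused_at(exit_port)
            if not cands:
                break
            if len(cands) > 1:
                loops = [c for c in cands if g.nodes[c[0]]["region"] == rid
                         and budget.get(rid, 0) > 0]
                viable = [c for c in cands if budget.get(g.nodes[c[0]]["region"], 0) > 0]
                if len(loops) == 1:
                    cands = loops
                elif len(viable) == 1:
                    cands = viable
                else:
                    break  # genuinely ambiguous: end the section here
            target, key = cands[0]
            used.add(edge_key(exit_port, target, key))
            port = target
        if section:
            sections.append(section)
        else:
            break
    return sections, {rid: n for rid, n in budget.items() if n > 0}


class ConstraintError(ValueError):
    pass


def assemble_structure(
    graph: nx.MultiGraph,
    regions: list[Region],
    constraints: list[list[int]] | None = None,
) -> DerivativeStructure:
    """Order regions into the derivative structure.

    Junction/reference edges give "certain" adjacencies inside sections;
    ``constraints`` (ordered region-id observations, e.g. from FISH) merge
    sections, and adjacencies justified only by a constraint are
    "suggested". Regions without placement evidence are reported unplaced
    rather than placed arbitrarily; copy-0 regions are absent.
    """
    present = [r for r in regions if r.copy_number > 0]
    if len(present) == 1:
        return DerivativeStructure(
            placed=[(present[0].region_id, "F")], unplaced=[], confidence=[]
        )
    sections, leftover = _walk_sections(graph, regions)

    if not constraints:
        placed, confidence = [], []
        for sec in sections:
            if placed:
                confidence.append("break")
            for j, item in enumerate(sec):
                placed.append(item)
                if j:
                    confidence.append("certain")
        unplaced = sorted(
            rid for rid, n in leftover.items() for _ in range(n)
        )
        return DerivativeStructure(placed=placed, unplaced=unplaced, confidence=confidence)

    copy_by_id = {r.region_id: r.copy_number for r in regions}
    successor: dict[int, int] = {}
    for obs in constraints:
        for a, b in zip(obs[:-1], obs[1:]):
            if copy_by_id.get(a, 1) != 1:
                continue  # multi-copy regions may legitimately recur
            if successor.get(a, b) != b:
                raise ConstraintError(
                    f"conflicting constraints: {a} followed by both "
                    f"{successor[a]} and {b}"
                )
            successor[a] = b
    placements_left = {
        r.region_id: max(r.copy_number, 1) for r in regions if r.copy_number > 0
    }
    by_head: dict[int, tuple[int, list[tuple[int, str]]]] = {}
    for si, sec in enumerate(sections):
        by_head.setdefault(sec[0][0], (si, sec))
        if len(sec) > 1:
            by_head.setdefault(
                sec[-1][0], (si, [(r, _flip(o)) for r, o in reversed(sec)])
            )
    placed: list[tuple[int, str]] = []
    confidence: list[str] = []
    used_sections: set[int] = set()
    for obs in constraints:
        for rid in obs:
            if placements_left.get(rid, 0) <= 0:
                if rid not in copy_by_id or copy_by_id[rid] == 0:
                    raise ConstraintError(f"constraint names absent region {rid}")
                continue
            si, sec = by_head.get(rid, (None, [(rid, "F")]))
            expand = (
                sec if len(sec) > 1 and si not in used_sections else [(rid, "F")]
            )
            if si is not None:
                used_sections.add(si)
            for j, item in enumerate(expand):
                if placed:
                    confidence.append("certain" if j else "suggested")
                placed.append(item)
                placements_left[item[0]] = placements_left.get(item[0], 1) - 1
    unplaced = sorted(rid for rid, left in placements_left.items() if left > 0)
    return DerivativeStructure(placed=placed, unplaced=unplaced, confidence=confidence)


def _flip(orient: str) -> str:
    return "R" if orient == "F" else "F"


# --- dosage, genes, mutation burden --------------------------------------


@dataclass(frozen=True)
class DosageSummary:
    fraction_deleted: float
    fraction_duplicated: float
    deleted_intervals: tuple[GenomeInterval, ...]
    duplicated_intervals: tuple[GenomeInterval, ...]


def dosage_summary(regions: list[Region], chrom_length: int) -> DosageSummary:
    """Fractions of the chromosome at copy 0 and copy >= 2."""
    total = sum(r.span for r in regions)
    if total != chrom_length:
        raise SegmentationError(
            f"regions span {total} bp, chromosome is {chrom_length} bp"
        )
    deleted = merge_intervals(r.interval for r in regions if r.copy_number == 0)
    duplicated = merge_intervals(r.interval for r in regions if r.copy_number >= 2)
    return DosageSummary(
        fraction_deleted=union_spans(deleted) / chrom_length,
        fraction_duplicated=union_spans(duplicated) / chrom_length,
        deleted_intervals=tuple(deleted),
        duplicated_intervals=tuple(duplicated),
    )


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon blocks, as read from BED12 (all blocks coding)."""

    gene_id: str
    seq_name: str
    start: int
    stop: int
    strand: str
    exons: tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        for ex in self.exons:
            if not (self.start <= ex.start and ex.stop <= self.stop):
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex} outside gene bounds"
                )

    @property
    def coding_length(self) -> int:
        return sum(e.span for e in self.exons)


def parse_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start0, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomeInterval(chrom, start0 + o + 1, start0 + o + s)
                for o, s in zip(offs, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name, seq_name=chrom, start=start0 + 1, stop=end,
                    strand=strand, exons=exons,
                )
            )
    return genes


def _junction_positions(spec: JunctionSpec) -> list[int]:
    return [spec.left.pos, spec.right.pos]


def gene_status(
    genes: list[GeneModel],
    regions: list[Region],
    junctions: list[JunctionSpec | BreakpointCall],
) -> tuple[list[GeneStatus], list[FusionCandidate]]:
    """Classify each gene from region overlaps and junction positions.

    A junction side strictly inside the gene body (between first and last
    exon bounds, introns included — transcript continuity is broken either
    way) marks the gene disrupted. Two genes disrupted by the two sides of
    the same junction with compatible transcriptional orientation form a
    fusion candidate; the fusion is in frame when the upstream coding
    length before the junction plus any inserted bases preserves the
    downstream gene's reading-frame phase.
    """
    specs = [j.junction if isinstance(j, BreakpointCall) else j for j in junctions]
    losses = merge_intervals(r.interval for r in regions if r.copy_number == 0)
    gains = merge_intervals(r.interval for r in regions if r.copy_number >= 2)

    statuses = []
    disrupted_by: dict[int, list[tuple[str, GeneModel, str]]] = {}
    for gene in genes:
        body = GenomeInterval(gene.seq_name, gene.start, gene.stop)
        hit_junctions = []
        for ji, spec in enumerate(specs):
            for side_name, side in (("left", spec.left), ("right", spec.right)):
                if side.seq_name == gene.seq_name and gene.start < side.pos < gene.stop:
                    hit_junctions.append(ji)
                    disrupted_by.setdefault(ji, []).append((side_name, gene, ""))
        loss_bp = _overlap_bp(body, losses)
        gain_bp = _overlap_bp(body, gains)
        if hit_junctions:
            status = "disrupted"
        elif loss_bp == body.span:
            status = "deleted"
        elif loss_bp > 0:
            status = "partially_deleted"
        elif gain_bp == body.span:
            status = "duplicated"
        elif gain_bp > 0:
            status = "partially_duplicated"
        else:
            status = "one_copy"
        statuses.append(
            GeneStatus(
                gene_id=gene.gene_id, status=status,
                disrupting_junctions=tuple(sorted(set(hit_junctions))),
            )
        )

    fusions = []
    for ji, hits in sorted(disrupted_by.items()):
        sides = {}
        for side_name, gene, _ in hits:
            sides.setdefault(side_name, []).append(gene)
        for up in sides.get("left", []):
            for down in sides.get("right", []):
                if up.gene_id == down.gene_id:
                    continue
                spec = specs[ji]
                fusions.append(
                    FusionCandidate(
                        upstream_gene=up.gene_id,
                        downstream_gene=down.gene_id,
                        junction_index=ji,
                        in_frame=_fusion_in_frame(up, down, spec),
                    )
                )
    return statuses, fusions


def _coding_len_retained(gene: GeneModel, pos: int, keep_low: bool) -> int:
    """Coding bases of ``gene`` on the retained side of a junction at ``pos``."""
    total = 0
    for ex in gene.exons:
        if keep_low:
            if ex.stop <= pos:
                total += ex.span
            elif ex.start <= pos:
                total += pos - ex.start + 1
        else:
            if ex.start >= pos:
                total += ex.span
            elif ex.stop >= pos:
                total += ex.stop - pos + 1
    return total


def _fusion_in_frame(up: GeneModel, down: GeneModel, spec: JunctionSpec) -> bool:
    # the left flank enters the junction: it occupies coords <= pos when
    # ascending; the right flank leaves it: coords >= pos when ascending
    u = _coding_len_retained(up, spec.left.pos, spec.left.direction == ASCENDING)
    down_retained = _coding_len_retained(
        down, spec.right.pos, spec.right.direction != ASCENDING
    )
    down_phase = (down.coding_length - down_retained) % 3
    return (u + len(spec.inserted)) % 3 == down_phase


def expected_mutation_count(
    chrom_length: int, target_size: int, rate_per_gy: float, dose_gy: float
) -> float:
    """Expected point-mutation burden: (length / target size) x rate x dose.

    With a 48.1 Mb chromosome, a 1 kb gene target, 1e-6 mutations per Gy
    and a 200 Gy dose this is ~10 mutations.
    """
    if min(chrom_length, target_size) <= 0 or rate_per_gy < 0 or dose_gy < 0:
        raise ValueError("all arguments must be positive")
    return (chrom_length / target_size) * rate_per_gy * dose_gy
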
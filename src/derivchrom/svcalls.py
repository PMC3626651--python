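"""Structural-rearrangement detection from discordant read pairs.

Pipeline: screen mapped pairs (quality > 35, over-distance / wrong
orientation / cross-sequence), classify each discordant pair's
orientation signature (+- over-distance = deletion, ++ / -- = inversion,
-+ = tandem duplication, cross-sequence), single-linkage cluster pairs
describing the same event, confirm clusters seen in >= 2 pairs across
>= 3 libraries, and refine confirmed clusters to base-pair resolution by
local assembly of reads near the breakpoints.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .insert_size import InsertProfile
from .junction_anatomy import JunctionAnatomy, JunctionAnatomyError, characterize_junction
from .mapping import PairCategory, ReadPairRecord
from .notation import JunctionSide, JunctionSpec
from .sequtil import ASCENDING, DESCENDING, advance, oriented_context, revcomp


class OrientationSignature(enum.Enum):
    FR_DELETION = "FR_deletion"
    FF_INVERSION = "FF_inversion"
    RF_TANDEM_DUP = "RF_tandem_dup"
    RR_INVERSION = "RR_inversion"
    CROSS_SEQUENCE = "cross_sequence"


@dataclass
class SVCluster:
    cluster_id: int
    signature: OrientationSignature
    seq_a: str
    seq_b: str
    interval_a: tuple[int, int]  # leftmost-mate coordinate range, side A
    interval_b: tuple[int, int]
    pair_ids: tuple[str, ...]
    libraries: frozenset[str]
    quality_floor: int
    window: int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def confirmed(self) -> bool:
        return self.n_pairs >= 2 and len(self.libraries) >= 3

    def confirmed_with(self, large_insert_override: frozenset[str] = frozenset()) -> bool:
        """Confirmation, allowing an override for events only visible to
        large-insert libraries (repeats longer than the small-insert span)."""
        if self.confirmed:
            return True
        return bool(self.libraries) and self.libraries <= large_insert_override


@dataclass(frozen=True)
class BreakpointCall:
    junction: JunctionSpec
    cluster_id: int
    resolution: str  # "assembled" | "read_pair"
    uncertainty_bp: int = 0
    anatomy: JunctionAnatomy | None = None


def screen_discordant(
    pairs: list[ReadPairRecord],
    profiles: dict[str, InsertProfile],
    min_quality: int = 35,
) -> list[ReadPairRecord]:
    """Pairs with quality strictly > ``min_quality`` that violate their
    library's insert expectation (cross-sequence, wrong orientation, or
    over-distance)."""
    out = []
    for rec in pairs:
        if rec.library not in profiles:
            raise KeyError(f"no insert profile for library {rec.library!r}")
        if rec.quality <= min_quality or rec.duplicate:
            continue
        if rec.mate1.seq_name is None or rec.mate2.seq_name is None:
            continue
        threshold = profiles[rec.library].upper_threshold
        insert = rec.insert_size
        if not rec.same_sequence:
            out.append(rec)
        elif insert == 0 or insert > threshold:  # wrong orientation or too far
            out.append(rec)
    return out


def classify_orientation(rec: ReadPairRecord) -> OrientationSignature:
    """Signature from mate strands ordered by leftmost coordinate."""
    if not rec.same_sequence:
        return OrientationSignature.CROSS_SEQUENCE
    left, right = sorted((rec.mate1, rec.mate2), key=lambda m: m.pos)
    return {
        ("+", "-"): OrientationSignature.FR_DELETION,
        ("+", "+"): OrientationSignature.FF_INVERSION,
        ("-", "+"): OrientationSignature.RF_TANDEM_DUP,
        ("-", "-"): OrientationSignature.RR_INVERSION,
    }[(left.strand, right.strand)]


def _loci(rec: ReadPairRecord) -> tuple[str, int, str, int]:
    """(seq_a, pos_a, seq_b, pos_b) with a canonical A/B ordering."""
    m1, m2 = rec.mate1, rec.mate2
    if (m1.seq_name, m1.pos) <= (m2.seq_name, m2.pos):
        return m1.seq_name, m1.pos, m2.seq_name, m2.pos
    return m2.seq_name, m2.pos, m1.seq_name, m1.pos


def cluster_events(
    pairs: list[ReadPairRecord],
    profiles: dict[str, InsertProfile],
    min_quality: int = 35,
) -> list[SVCluster]:
    """Single-linkage clustering of screened discordant pairs.

    Two pairs co-cluster iff they share an orientation signature and
    sequence pair and both loci lie within the clustering window — the
    larger of the two libraries' upper insert thresholds. Output order is
    canonical (sorted by signature and loci), independent of input order.
    """
    annotated = [
        (classify_orientation(rec), *_loci(rec), rec) for rec in pairs
    ]
    annotated.sort(key=lambda t: (t[0].value, t[1], t[3], t[2], t[4], t[5].pair_id))
    parent = list(range(len(annotated)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def window(r1: ReadPairRecord, r2: ReadPairRecord) -> int:
        return max(
            profiles[r1.library].upper_threshold,
            profiles[r2.library].upper_threshold,
        )

    for i in range(len(annotated)):
        sig_i, sa_i, pa_i, sb_i, pb_i, rec_i = annotated[i]
        for j in range(i + 1, len(annotated)):
            sig_j, sa_j, pa_j, sb_j, pb_j, rec_j = annotated[j]
            if (sig_j, sa_j, sb_j) != (sig_i, sa_i, sb_i):
                break
            w = window(rec_i, rec_j)
            if pa_j - pa_i > w:
                break
            if abs(pb_j - pb_i) <= w:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(annotated)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for cid, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        recs = [annotated[i] for i in members]
        sig = recs[0][0]
        pas = [r[2] for r in recs]
        pbs = [r[4] for r in recs]
        libs = frozenset(r[5].library for r in recs)
        clusters.append(
            SVCluster(
                cluster_id=cid,
                signature=sig,
                seq_a=recs[0][1],
                seq_b=recs[0][3],
                interval_a=(min(pas), max(pas)),
                interval_b=(min(pbs), max(pbs)),
                pair_ids=tuple(sorted(r[5].pair_id for r in recs)),
                libraries=libs,
                quality_floor=min_quality,
                window=max(profiles[r[5].library].upper_threshold for r in recs),
            )
        )
    return clusters


# Approximate oriented junction sides implied by a cluster's signature.
# Side A carries the lower-coordinate mates, side B the higher. For a
# deletion (+-) the sequence runs A-forward into the junction and resumes
# B-forward; for a tandem duplication (-+) it runs B-forward into the
# junction and resumes A-forward; inversions flip one side.
def cluster_sides(
    cluster: SVCluster, read_length: int
) -> tuple[JunctionSide, JunctionSide]:
    a_lo, a_hi = cluster.interval_a
    b_lo, b_hi = cluster.interval_b
    sig = cluster.signature
    if sig == OrientationSignature.FR_DELETION:
        left = JunctionSide(cluster.seq_a, a_hi + read_length, ASCENDING)
        right = JunctionSide(cluster.seq_b, b_lo, ASCENDING)
    elif sig == OrientationSignature.FF_INVERSION:
        left = JunctionSide(cluster.seq_a, a_hi + read_length, ASCENDING)
        right = JunctionSide(cluster.seq_b, b_hi + read_length, DESCENDING)
    elif sig == OrientationSignature.RR_INVERSION:
        left = JunctionSide(cluster.seq_b, b_lo, DESCENDING)
        right = JunctionSide(cluster.seq_a, a_lo, ASCENDING)
    elif sig == OrientationSignature.RF_TANDEM_DUP:
        left = JunctionSide(cluster.seq_b, b_hi + read_length, ASCENDING)
        right = JunctionSide(cluster.seq_a, a_lo, ASCENDING)
    else:
        raise ValueError("cross-sequence clusters need side hints from both sequences")
    return left, right


def assemble_junction(
    cluster: SVCluster,
    reads: list[str],
    reference: dict[str, str],
    read_length: int,
    assembly_k: int = 25,
    max_fragment: int = 800,
    fallback_reads: list[str] | None = None,
) -> BreakpointCall:
    """Refine a confirmed cluster to base-pair resolution by local assembly.

    ``reads`` are the sequences of rearrangement-informative reads near
    the cluster's breakpoints (cluster members and unmapped
    junction-crossers); ``fallback_reads`` may carry all reads in the
    assembly window (4 kb) and is consulted when the informative set is
    too sparse — at a duplication boundary the concordant reads would
    otherwise let the reference adjacency outvote the junction, so they
    are a second resort only. A k-mer majority-extension consensus is
    seeded from the reference just inside the junction's left flank and
    walked across; the resulting fragment is characterized against the
    reference. Falls back to a read-pair-resolution call (± the
    clustering window) when no read crosses the junction.
    """
    left, right = cluster_sides(cluster, read_length)
    # also try the junction read in the other direction: near duplicated
    # sequence one side's consensus walk can hit a branch that the other
    # side's does not
    flipped = {ASCENDING: DESCENDING, DESCENDING: ASCENDING}
    side_hypotheses = [
        (left, right),
        (
            JunctionSide(right.seq_name, right.pos, flipped[right.direction]),
            JunctionSide(left.seq_name, left.pos, flipped[left.direction]),
        ),
    ]
    read_sets = [reads]
    if fallback_reads:
        read_sets.append(list(reads) + list(fallback_reads))
    max_back = cluster.window + read_length
    backs: list[int] = []
    back = 2 * read_length
    while back < max_back:
        backs.append(back)
        back = int(back * 1.5)
    backs.append(max_back)

    for read_set in read_sets:
        counts: dict[str, dict[str, int]] = {}
        for seq in read_set:
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - assembly_k):
                    d = counts.setdefault(s[i : i + assembly_k], {})
                    nxt = s[i + assembly_k]
                    d[nxt] = d.get(nxt, 0) + 1
        for hyp_left, hyp_right in side_hypotheses:
            ctx, idx = oriented_context(
                reference[hyp_left.seq_name], hyp_left.pos, hyp_left.direction,
                before=max_back + assembly_k, after=0,
            )
            # anchor just upstream of the estimated junction (the estimate
            # sits at or before the true position); step further upstream
            # only if needed — long consensus walks fail on coverage gaps
            for back in backs:
                for jitter in range(0, 150, 5):  # slide around coverage gaps
                    start = idx - back - jitter
                    if start < 0:
                        continue
                    seedseq = ctx[start : start + assembly_k]
                    if seedseq not in counts:
                        continue
                    fragment = _extend(seedseq, counts, max_fragment + back + jitter)
                    if len(fragment) < assembly_k + min(40, back):
                        continue
                    try:
                        anatomy = characterize_junction(
                            fragment, hyp_left, hyp_right, reference,
                            search_window=cluster.window + read_length,
                            infer_deletions=False,
                        )
                    except JunctionAnatomyError:
                        continue
                    return BreakpointCall(
                        junction=anatomy.to_spec(), cluster_id=cluster.cluster_id,
                        resolution="assembled", uncertainty_bp=0, anatomy=anatomy,
                    )
    spec = JunctionSpec(left=left, right=right)
    return BreakpointCall(
        junction=spec, cluster_id=cluster.cluster_id,
        resolution="read_pair", uncertainty_bp=cluster.window,
    )


def _extend(seed: str, counts: dict[str, dict[str, int]], max_len: int) -> str:
    out = seed
    k = len(seed)
    while len(out) < max_len:
        nexts = counts.get(out[-k:])
        if not nexts:
            break
        best = max(sorted(nexts), key=lambda b: nexts[b])
        out += best
    return out
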
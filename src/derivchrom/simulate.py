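"""Synthetic-data generator: rearranged graft chromosome + paired-end reads.

Emulates the study design this package targets: a single-copy "graft"
chromosome (the transferred human chromosome) rearranged by irradiation
into deletions, duplications and inversions joined by non-homologous
end-joining (NHEJ) style junctions (0-4 bp micro-homology, occasional
inserted bases, small flanking deletions), carried on a diploid "host"
(mouse) background, sequenced with a mix of small- and large-insert
paired-end libraries.

Micro-homology is *planted*: the homologous bases pre-exist in the graft
reference (the left flank's terminal bases are copied onto the right
segment's first bases before segments are extracted), so the emitted truth
junctions satisfy the both-flank property against the reference, exactly
as a real NHEJ junction would.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomeInterval
from .notation import JunctionSide, JunctionSpec
from .sequtil import ASCENDING, DESCENDING, advance, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PlanError(ValueError):
    """Raised for rearrangement plans inconsistent with the reference."""


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


@dataclass
class CompositeReference:
    """Host chromosomes (diploid, copy 2) plus a single-copy graft chromosome."""

    host: dict[str, str]
    graft_name: str
    graft_seq: str

    def __post_init__(self) -> None:
        if self.graft_name in self.host:
            raise ValueError(f"duplicate sequence name {self.graft_name!r}")

    @property
    def sequences(self) -> dict[str, str]:
        return {**self.host, self.graft_name: self.graft_seq}

    def copy_number(self, name: str) -> int:
        return 1 if name == self.graft_name else 2

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def make_composite_reference(
    graft_length: int,
    host_lengths: dict[str, int],
    seed: int,
    graft_name: str = "graft21",
    gc: float = 0.42,
    shared_block_rate: float = 0.0,
    shared_block_length: int = 200,
) -> CompositeReference:
    """Random composite reference, optionally planting host<->graft shared blocks.

    ``shared_block_rate`` is blocks per graft megabase; each block copies
    ``shared_block_length`` bp of graft sequence into a random host location,
    emulating conserved sequence that confounds unique mapping.
    """
    rng = np.random.default_rng(seed)
    graft = random_sequence(graft_length, rng, gc)
    host = {name: random_sequence(n, rng, gc) for name, n in host_lengths.items()}
    n_blocks = int(round(shared_block_rate * graft_length / 1e6))
    for _ in range(n_blocks):
        src = int(rng.integers(0, graft_length - shared_block_length))
        block = graft[src : src + shared_block_length]
        name = list(host)[int(rng.integers(len(host)))]
        dst = int(rng.integers(0, len(host[name]) - shared_block_length))
        host[name] = host[name][:dst] + block + host[name][dst + len(block):]
    return CompositeReference(host=host, graft_name=graft_name, graft_seq=graft)


@dataclass(frozen=True)
class JunctionPlan:
    """Decoration of one adjacency in a rearrangement plan."""

    microhomology_len: int = 0
    inserted: str = ""
    deleted_left: int = 0   # bp trimmed from the junction end of the left segment
    deleted_right: int = 0  # bp trimmed from the junction start of the right segment

    def __post_init__(self) -> None:
        if self.microhomology_len and self.inserted:
            raise PlanError("micro-homology and insertion are mutually exclusive")
        if self.microhomology_len < 0 or not 0 <= self.microhomology_len <= 100:
            raise PlanError("micro-homology length out of range")


@dataclass(frozen=True)
class RearrangementPlan:
    """Ordered, oriented graft segments with per-adjacency junction decorations."""

    segments: tuple[tuple[GenomeInterval, str], ...]  # (interval, "F"/"R")
    junctions: tuple[JunctionPlan, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.junctions and len(self.junctions) != len(self.segments) - 1:
            raise PlanError("need one junction decoration per adjacent segment pair")


@dataclass
class DerivativeResult:
    derivative: str
    truth_junctions: list[JunctionSpec]
    reference: CompositeReference  # graft possibly edited by micro-homology planting


def _seg_side(interval: GenomeInterval, orient: str, which: str) -> JunctionSide:
    """Oriented junction side at a segment's entry ('start') or exit ('end')."""
    if orient == "F":
        pos = interval.stop if which == "end" else interval.start
        direction = ASCENDING
    else:
        pos = interval.start if which == "end" else interval.stop
        direction = DESCENDING
    return JunctionSide(interval.seq_name, pos, direction)


def _trim(interval: GenomeInterval, orient: str, which: str, n: int):
    """Trim ``n`` bp from a segment's junction-facing edge.

    Returns (trimmed interval, deleted interval or None) in reference coords.
    """
    if n == 0:
        return interval, None
    s, e = interval.start, interval.stop
    trim_high = (orient == "F") == (which == "end")
    if trim_high:
        deleted = GenomeInterval(interval.seq_name, e - n + 1, e)
        kept = GenomeInterval(interval.seq_name, s, e - n)
    else:
        deleted = GenomeInterval(interval.seq_name, s, s + n - 1)
        kept = GenomeInterval(interval.seq_name, s + n, e)
    return kept, deleted


def _oriented_seq(seq: str, interval: GenomeInterval, orient: str) -> str:
    sub = seq[interval.start - 1 : interval.stop]
    return sub if orient == "F" else revcomp(sub)


def build_derivative(
    reference: CompositeReference, plan: RearrangementPlan
) -> DerivativeResult:
    """Assemble the derivative chromosome a plan describes.

    The derivative is the concatenation of the plan's oriented segments
    (edges trimmed by the planned flanking deletions), joined with the
    planned inserted bases; for a junction with micro-homology *h* the
    right segment's first *h* bases are made identical to the left flank's
    last *h* (edited into the graft reference), appear once in the
    derivative, and are attributable to either side.
    """
    graft = list(reference.graft_seq)
    glen = len(graft)
    for iv, _ in plan.segments:
        if iv.seq_name != reference.graft_name:
            raise PlanError(f"segment {iv} is not on the graft chromosome")
        if iv.stop > glen:
            raise PlanError(f"segment {iv} exceeds graft length {glen}")
    junctions = plan.junctions or tuple(
        JunctionPlan() for _ in range(len(plan.segments) - 1)
    )

    # pass 1: trim segment edges and plant micro-homology bases in the graft
    kept: list[tuple[GenomeInterval, str]] = []
    deleted_left: list[GenomeInterval | None] = [None] * len(plan.segments)
    deleted_right: list[GenomeInterval | None] = [None] * len(plan.segments)
    for i, (iv, orient) in enumerate(plan.segments):
        if i > 0:
            iv, deleted_right[i] = _trim(iv, orient, "start", junctions[i - 1].deleted_right)
        if i < len(plan.segments) - 1:
            iv, deleted_left[i] = _trim(iv, orient, "end", junctions[i].deleted_left)
        kept.append((iv, orient))
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i, jp in enumerate(junctions):
        h = jp.microhomology_len
        left_iv, left_or = kept[i]
        right_iv, right_or = kept[i + 1]
        if min(left_iv.span, right_iv.span) <= h:
            raise PlanError("segment too short for planned micro-homology")
        left_end = _seg_side(left_iv, left_or, "end")
        right_start = _seg_side(right_iv, right_or, "start")
        if h:
            mh = "".join(
                _oriented_base_list(graft, advance(left_end.pos, left_end.direction, -k), left_end.direction)
                for k in range(h - 1, -1, -1)
            )
            for k in range(h):
                _set_oriented_base(
                    graft, advance(right_start.pos, right_start.direction, k),
                    right_start.direction, mh[k],
                )
        # make the planned decomposition maximal: the reference base just
        # past each flank must not extend the shared stretch by chance
        if (
            h == 0 and not jp.inserted and left_or == right_or
            and advance(left_end.pos, left_end.direction, 1) == right_start.pos
        ):
            continue  # pure reference adjacency: nothing to disambiguate
        glen_ok = lambda p: 1 <= p <= glen
        deriv_next = (
            jp.inserted[0] if jp.inserted
            else _oriented_base_list(
                graft, advance(right_start.pos, right_start.direction, h),
                right_start.direction)
        )
        p_after_left = advance(left_end.pos, left_end.direction, 1)
        if glen_ok(p_after_left) and \
                _oriented_base_list(graft, p_after_left, left_end.direction) == deriv_next:
            _set_oriented_base(graft, p_after_left, left_end.direction, other[deriv_next])
        deriv_prev = (
            jp.inserted[-1] if jp.inserted
            else _oriented_base_list(
                graft, advance(left_end.pos, left_end.direction, -h),
                left_end.direction)
        )
        p_before_right = advance(right_start.pos, right_start.direction, -1)
        if glen_ok(p_before_right) and \
                _oriented_base_list(graft, p_before_right, right_start.direction) == deriv_prev:
            _set_oriented_base(graft, p_before_right, right_start.direction, other[deriv_prev])

    edited = replace(reference, graft_seq="".join(graft))
    gseq = edited.graft_seq

    # pass 2: concatenate and emit truth junctions
    parts: list[str] = []
    truth: list[JunctionSpec] = []
    for i, (iv, orient) in enumerate(kept):
        seg = _oriented_seq(gseq, iv, orient)
        if i == 0:
            parts.append(seg)
            continue
        jp = junctions[i - 1]
        h = jp.microhomology_len
        parts.append(jp.inserted)
        parts.append(seg[h:])  # micro-homology bases already present in the left part
        left_side = _seg_side(kept[i - 1][0], kept[i - 1][1], "end")
        right_side = _seg_side(iv, orient, "start")
        mh = seg[:h]
        truth.append(
            JunctionSpec(
                left=left_side,
                right=right_side,
                microhomology=mh,
                inserted=jp.inserted,
                deleted_proximal=deleted_left[i - 1],
                deleted_distal=deleted_right[i],
            )
        )
    derivative = "".join(parts)
    expected = (
        sum(iv.span for iv, _ in plan.segments)
        - sum(j.deleted_left + j.deleted_right + j.microhomology_len for j in junctions)
        + sum(len(j.inserted) for j in junctions)
    )
    assert len(derivative) == expected, "derivative length arithmetic violated"
    return DerivativeResult(derivative=derivative, truth_junctions=truth, reference=edited)


def _oriented_base_list(seq: list[str], pos: int, direction: str) -> str:
    b = seq[pos - 1]
    return b if direction == ASCENDING else revcomp(b)


def _set_oriented_base(seq: list[str], pos: int, direction: str, base: str) -> None:
    seq[pos - 1] = base if direction == ASCENDING else revcomp(base)


@dataclass(frozen=True)
class LibrarySpec:
    """One paired-end sequencing library."""

    name: str
    insert_mean: float
    insert_sd: float
    read_length: int
    n_pairs: int
    duplicate_fraction: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.insert_mean <= 2 * self.read_length:
            raise PlanError(
                f"library {self.name}: insert mean {self.insert_mean} must exceed "
                f"twice the read length ({2 * self.read_length})"
            )
        for frac in (self.duplicate_fraction, self.error_rate):
            if not 0.0 <= frac <= 1.0:
                raise PlanError(f"library {self.name}: fraction {frac} outside [0,1]")


@dataclass(frozen=True)
class TruthPlacement:
    pair_id: str
    library: str
    seq_name: str
    start: int      # 1-based leftmost coordinate of the fragment
    insert: int
    duplicate_of: str | None = None


@dataclass
class SimulatedReads:
    pairs: list[tuple[str, str, str]]  # (pair id, read1, read2)
    truth: list[TruthPlacement]


def simulate_pairs(
    sequences: dict[str, str],
    copy_numbers: dict[str, int],
    libraries: list[LibrarySpec],
    seed: int,
) -> SimulatedReads:
    """Draw read pairs from a genome (e.g. host at copy 2 + derivative at 1).

    Fragments are placed uniformly, weighted by sequence length x copy
    number; insert sizes are normal draws truncated at +/- 3.5 sd (and
    within [2 x read length, 2 x mean]), emulating library size selection;
    read 1 is the fragment start (forward), read 2 the reverse complement
    of the fragment end. Duplicates are exact coordinate copies; base
    errors are independent substitutions.
    """
    if not libraries:
        raise PlanError("at least one library is required")
    rng = np.random.default_rng(seed)
    names = list(sequences)
    weights = np.array([len(sequences[n]) * copy_numbers.get(n, 1) for n in names], float)
    weights /= weights.sum()

    pairs: list[tuple[str, str, str]] = []
    truth: list[TruthPlacement] = []
    lens = np.array([len(sequences[n]) for n in names])
    for lib in libraries:
        n_dup = int(round(lib.duplicate_fraction * lib.n_pairs))
        n_unique = lib.n_pairs - n_dup
        idx = rng.choice(len(names), size=n_unique, p=weights)
        # size selection truncates the insert distribution at +/- 3.5 sd
        lo = max(2 * lib.read_length, int(lib.insert_mean - 3.5 * lib.insert_sd))
        hi = min(int(2 * lib.insert_mean), int(lib.insert_mean + 3.5 * lib.insert_sd))
        inserts = np.clip(
            np.rint(rng.normal(lib.insert_mean, lib.insert_sd, size=n_unique)), lo, hi
        ).astype(int)
        inserts = np.minimum(inserts, lens[idx])
        starts = np.floor(rng.random(n_unique) * (lens[idx] - inserts + 1)).astype(int)
        placements = [
            (names[i], int(s), int(ins)) for i, s, ins in zip(idx, starts, inserts)
        ]
        dup_src = (
            rng.integers(0, n_unique, size=n_dup) if n_unique and n_dup else []
        )
        for j, (name, start, insert) in enumerate(
            placements + [placements[k] for k in dup_src]
        ):
            pid = f"{lib.name}:{j:07d}"
            seq = sequences[name]
            r1 = seq[start : start + lib.read_length]
            r2 = revcomp(seq[start + insert - lib.read_length : start + insert])
            if lib.error_rate > 0:
                r1 = _add_errors(r1, lib.error_rate, rng)
                r2 = _add_errors(r2, lib.error_rate, rng)
            pairs.append((pid, r1, r2))
            truth.append(
                TruthPlacement(
                    pair_id=pid,
                    library=lib.name,
                    seq_name=name,
                    start=start + 1,
                    insert=insert,
                    duplicate_of=(
                        f"{lib.name}:{dup_src[j - n_unique]:07d}" if j >= n_unique else None
                    ),
                )
            )
    return SimulatedReads(pairs=pairs, truth=truth)


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode()


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq_pairs(reads: SimulatedReads, path1: str, path2: str) -> None:
    recs1, recs2 = [], []
    for pid, r1, r2 in reads.pairs:
        recs1.append(_fastq_record(f"{pid}/1", r1))
        recs2.append(_fastq_record(f"{pid}/2", r2))
    SeqIO.write(recs1, path1, "fastq")
    SeqIO.write(recs2, path2, "fastq")


def read_fastq_pairs(path1: str, path2: str) -> list[tuple[str, str, str]]:
    out = []
    for rec1, rec2 in zip(SeqIO.parse(path1, "fastq"), SeqIO.parse(path2, "fastq")):
        pid = rec1.id.rsplit("/", 1)[0]
        out.append((pid, str(rec1.seq), str(rec2.seq)))
    return out


def _fastq_record(name: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec
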
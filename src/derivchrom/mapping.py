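"""Minimal deterministic paired-end mapper + minimal-SAM interoperability.

The mapper seeds each read with exact k-mers (default k = 31) unique in the
composite reference and extends ungapped, allowing up to 4 mismatches. It
deliberately has no gapped alignment or rescue stage: a read whose seeds
are ambiguous (e.g. drawn from sequence shared between host and graft)
gets mapping quality 0 and is excluded by the quality-35 screen downstream.

Mate quality: 60 for a unique seed with <= 1 mismatch, 37 for a unique
seed with 2-4 mismatches, 0 otherwise; pair quality = min of the mates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable

import pysam

from .sequtil import revcomp
from .simulate import CompositeReference


class PairCategory(enum.Enum):
    SHORT_CORRECT = "short_correct"
    LONG_CORRECT = "long_correct"
    RESCUED_CORRECT = "rescued_correct"
    DISCORDANT = "discordant"
    UNMAPPED = "unmapped"

    @property
    def is_correct(self) -> bool:
        return self in (
            PairCategory.SHORT_CORRECT,
            PairCategory.LONG_CORRECT,
            PairCategory.RESCUED_CORRECT,
        )


@dataclass(frozen=True)
class MateAlignment:
    seq_name: str | None
    pos: int  # 1-based leftmost reference coordinate
    strand: str  # "+" or "-"
    quality: int
    mismatches: int = 0


@dataclass(frozen=True)
class ReadPairRecord:
    pair_id: str
    library: str
    mate1: MateAlignment
    mate2: MateAlignment
    read_length: int
    duplicate: bool = False
    category: PairCategory = PairCategory.UNMAPPED

    @property
    def quality(self) -> int:
        return min(self.mate1.quality, self.mate2.quality)

    @property
    def same_sequence(self) -> bool:
        return (
            self.mate1.seq_name is not None
            and self.mate1.seq_name == self.mate2.seq_name
        )

    @property
    def insert_size(self) -> int:
        """Outer fragment span if the pair is same-sequence +/-; else 0."""
        if not self.same_sequence:
            return 0
        left, right = sorted((self.mate1, self.mate2), key=lambda m: m.pos)
        if (left.strand, right.strand) != ("+", "-"):
            return 0
        return right.pos + self.read_length - left.pos

    @property
    def leftmost(self) -> int:
        return min(self.mate1.pos, self.mate2.pos)

    def coordinate_key(self) -> tuple:
        return (
            self.mate1.seq_name, self.mate1.pos, self.mate1.strand,
            self.mate2.seq_name, self.mate2.pos, self.mate2.strand,
        )


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_AMBIGUOUS = -1


class KmerIndex:
    """Exact k-mer -> unique placement index over a set of sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 31):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("empty reference")
        self.k = k
        self.names = list(sequences)
        self.sequences = sequences
        self._index: dict[int, int] = {}
        for si, name in enumerate(self.names):
            seq = sequences[name]
            code, valid = 0, 0
            mask = (1 << (2 * k)) - 1
            for i, base in enumerate(seq):
                b = _ENC.get(base)
                if b is None:
                    code, valid = 0, 0
                    continue
                code = ((code << 2) | b) & mask
                valid += 1
                if valid >= k:
                    if code in self._index:
                        self._index[code] = _AMBIGUOUS
                    else:
                        self._index[code] = (si << 34) | (i - k + 1)

    def lookup(self, kmer: str) -> tuple[str, int] | str | None:
        """Unique placement (name, 0-based pos), "ambiguous", or None."""
        code = 0
        for base in kmer:
            b = _ENC.get(base)
            if b is None:
                return None
            code = (code << 2) | b
        hit = self._index.get(code)
        if hit is None:
            return None
        if hit == _AMBIGUOUS:
            return "ambiguous"
        return self.names[hit >> 34], hit & ((1 << 34) - 1)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _map_read(
    read: str, index: KmerIndex, max_mismatches: int = 4, n_seeds: int = 3
) -> MateAlignment:
    k = index.k
    offsets = [o for o in range(0, max(1, len(read) - k + 1), k)][:n_seeds]
    saw_ambiguous = False
    for off in offsets:
        seed = read[off : off + k]
        if len(seed) < k:
            break
        candidates: list[tuple[str, int, str]] = []
        fwd = index.lookup(seed)
        if fwd == "ambiguous":
            saw_ambiguous = True
        elif fwd is not None:
            name, p = fwd
            candidates.append((name, p - off, "+"))
        rc = index.lookup(revcomp(seed))
        if rc == "ambiguous":
            saw_ambiguous = True
        elif rc is not None:
            name, p = rc
            candidates.append((name, p - (len(read) - off - k), "-"))
        placements = []
        for name, left, strand in candidates:
            ref = index.sequences[name]
            if left < 0 or left + len(read) > len(ref):
                continue
            query = read if strand == "+" else revcomp(read)
            mm = _count_mismatches(query, ref[left : left + len(read)], max_mismatches)
            if mm <= max_mismatches:
                placements.append((name, left, strand, mm))
        if len(placements) == 1 and not saw_ambiguous:
            name, left, strand, mm = placements[0]
            q = 60 if mm <= 1 else 37
            return MateAlignment(name, left + 1, strand, q, mm)
        if placements:
            name, left, strand, mm = placements[0]
            return MateAlignment(name, left + 1, strand, 0, mm)
    return MateAlignment(None, 0, "+", 0)


def map_pairs(
    reads: Iterable[tuple[str, str, str]],
    reference: CompositeReference | dict[str, str],
    k: int = 31,
    library_of: dict[str, str] | None = None,
) -> list[ReadPairRecord]:
    """Map (pair_id, read1, read2) triples against the composite reference.

    ``library_of`` maps pair ids to library names; by default the library
    is the pair-id prefix before the first ``":"``.
    """
    sequences = (
        reference.sequences if isinstance(reference, CompositeReference) else reference
    )
    index = KmerIndex(sequences, k=k)
    records = []
    for pid, r1, r2 in reads:
        lib = library_of[pid] if library_of else pid.split(":", 1)[0]
        m1 = _map_read(r1, index)
        m2 = _map_read(r2, index)
        cat = (
            PairCategory.UNMAPPED
            if m1.seq_name is None or m2.seq_name is None
            else PairCategory.DISCORDANT
        )
        records.append(
            ReadPairRecord(
                pair_id=pid, library=lib, mate1=m1, mate2=m2,
                read_length=len(r1), category=cat,
            )
        )
    return records


def dedupe(pairs: list[ReadPairRecord]) -> list[ReadPairRecord]:
    """Keep one pair per exact mapping-coordinate tuple.

    The retained pair is the highest-quality one; ties break by input
    order (pair id order for sorted input). Idempotent. Unmapped pairs
    pass through untouched.
    """
    best: dict[tuple, ReadPairRecord] = {}
    passthrough = []
    for rec in pairs:
        if rec.mate1.seq_name is None or rec.mate2.seq_name is None:
            passthrough.append(rec)
            continue
        key = rec.coordinate_key()
        if key not in best or rec.quality > best[key].quality:
            best[key] = rec
    kept = set(id(r) for r in best.values())
    return [r for r in pairs if id(r) in kept] + passthrough


def categorize_pair(
    rec: ReadPairRecord, thresholds: dict[str, tuple[int, str]]
) -> ReadPairRecord:
    """Assign a pair category from per-library insert thresholds.

    ``thresholds`` maps library -> (upper insert threshold bp, "short" or
    "long" library class). A same-sequence +/- pair within threshold is
    short/long_correct per its library class; anything else mapped is
    discordant.
    """
    if rec.library not in thresholds:
        raise KeyError(f"no insert threshold for library {rec.library!r}")
    if rec.mate1.seq_name is None or rec.mate2.seq_name is None:
        return replace(rec, category=PairCategory.UNMAPPED)
    upper, lib_class = thresholds[rec.library]
    insert = rec.insert_size
    if rec.same_sequence and 0 < insert <= upper:
        cat = (
            PairCategory.SHORT_CORRECT if lib_class == "short"
            else PairCategory.LONG_CORRECT
        )
    else:
        cat = PairCategory.DISCORDANT
    return replace(rec, category=cat)


# --- minimal SAM dialect -------------------------------------------------

_CATEGORY_TAG = "Zc"


def write_sam(
    records: list[ReadPairRecord], lengths: dict[str, int], path: str
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": n} for name, n in lengths.items()],
        "RG": sorted(
            ({"ID": lib} for lib in {r.library for r in records}),
            key=lambda d: d["ID"],
        ),
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        refids = {name: i for i, name in enumerate(lengths)}
        for rec in records:
            for mate, other, first in ((rec.mate1, rec.mate2, True),
                                       (rec.mate2, rec.mate1, False)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.pair_id
                flag = 0x1 | (0x40 if first else 0x80)
                if mate.seq_name is None:
                    flag |= 0x4
                else:
                    a.reference_id = refids[mate.seq_name]
                    a.reference_start = mate.pos - 1
                    a.mapping_quality = mate.quality
                    a.cigarstring = f"{rec.read_length}M"
                if mate.strand == "-":
                    flag |= 0x10
                if other.strand == "-":
                    flag |= 0x20
                if other.seq_name is None:
                    flag |= 0x8
                else:
                    a.next_reference_id = refids[other.seq_name]
                    a.next_reference_start = other.pos - 1
                if rec.duplicate:
                    flag |= 0x400
                a.flag = flag
                if rec.same_sequence:
                    tlen = rec.insert_size
                    a.template_length = tlen if mate.pos <= other.pos else -tlen
                a.set_tag("RG", rec.library)
                a.set_tag(_CATEGORY_TAG, rec.category.value)
                out.write(a)


def read_sam(path: str) -> list[ReadPairRecord]:
    """Ingest the minimal SAM dialect back into pair records.

    Pairs flagged as proper (0x2) whose category tag is absent are taken
    as externally rescued alignments (``rescued_correct``).
    """
    mates: dict[str, dict[bool, tuple[pysam.AlignedSegment, str]]] = {}
    records = []
    with pysam.AlignmentFile(path, "r") as sam:
        for a in sam:
            slot = mates.setdefault(a.query_name, {})
            slot[a.is_read1] = a
            if len(slot) == 2:
                a1, a2 = slot[True], slot[False]
                records.append(_pair_from_sam(a1, a2))
                del mates[a.query_name]
    if mates:
        raise ValueError(f"{len(mates)} unpaired records in {path}")
    return records


def _pair_from_sam(a1, a2) -> ReadPairRecord:
    def mate(a) -> MateAlignment:
        if a.is_unmapped:
            return MateAlignment(None, 0, "+", 0)
        return MateAlignment(
            a.reference_name, a.reference_start + 1,
            "-" if a.is_reverse else "+", a.mapping_quality,
        )

    m1, m2 = mate(a1), mate(a2)
    if a1.has_tag(_CATEGORY_TAG):
        cat = PairCategory(a1.get_tag(_CATEGORY_TAG))
    elif m1.seq_name is None or m2.seq_name is None:
        cat = PairCategory.UNMAPPED
    elif a1.is_proper_pair:
        cat = PairCategory.RESCUED_CORRECT
    else:
        cat = PairCategory.DISCORDANT
    return ReadPairRecord(
        pair_id=a1.query_name,
        library=a1.get_tag("RG") if a1.has_tag("RG") else "default",
        mate1=m1,
        mate2=m2,
        read_length=a1.query_length or a1.infer_read_length() or 0,
        duplicate=a1.is_duplicate,
        category=cat,
    )
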
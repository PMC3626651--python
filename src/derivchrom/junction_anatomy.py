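"""Base-pair anatomy of breakpoint junctions and in-silico PCR.

Given an assembled (or truth) junction fragment and the two approximate
oriented sides, :func:`characterize_junction` aligns the fragment's ends
back to the reference: the maximal left-flank match and maximal
right-flank match either overlap (the overlap is micro-homology — bases
attributable to either side, the NHEJ hallmark), abut exactly (blunt
junction), or leave a gap (inserted bases matching neither flank). The
result is equivalent to brute-force enumeration over all split positions,
preferring maximal micro-homology.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomeInterval
from .notation import JunctionSide, JunctionSpec
from .sequtil import ASCENDING, advance, oriented_context


class JunctionAnatomyError(ValueError):
    pass


MAX_MICROHOMOLOGY = 100  # longer shared stretches are homology-mediated, not NHEJ


@dataclass(frozen=True)
class JunctionAnatomy:
    left: JunctionSide   # refined, micro-homology-inclusive
    right: JunctionSide  # refined, micro-homology-inclusive
    microhomology: str
    inserted: str
    deleted_proximal: GenomeInterval | None = None
    deleted_distal: GenomeInterval | None = None

    def to_spec(self, evidence_flags: frozenset[str] = frozenset()) -> JunctionSpec:
        return JunctionSpec(
            left=self.left,
            right=self.right,
            microhomology=self.microhomology,
            inserted=self.inserted,
            deleted_proximal=self.deleted_proximal,
            deleted_distal=self.deleted_distal,
            evidence_flags=evidence_flags,
        )


def _side_interval(pos_a: int, pos_b: int, seq_name: str) -> GenomeInterval | None:
    lo, hi = sorted((pos_a, pos_b))
    return GenomeInterval(seq_name, lo, hi)


def characterize_junction(
    fragment: str,
    left: JunctionSide,
    right: JunctionSide,
    reference: dict[str, str],
    min_flank: int = 20,
    search_window: int = 2000,
    max_microhomology: int = MAX_MICROHOMOLOGY,
    infer_deletions: bool = True,
) -> JunctionAnatomy:
    """Resolve a junction fragment to base-pair anatomy.

    ``left``/``right`` may be approximate (cluster-resolution) sides; the
    fragment's first/last ``min_flank`` bases are located within
    ``search_window`` of them and each flank match is extended maximally.
    If the provided nominal positions lie beyond the refined ones, the
    intervening reference bases are reported as flanking deletions.
    """
    if len(fragment) < 2 * min_flank:
        raise JunctionAnatomyError(
            f"fragment of {len(fragment)} bp too short for {min_flank} bp flanks"
        )
    n = len(fragment)

    # left flank: oriented reading that should contain fragment[:min_flank]
    lseq = reference[left.seq_name]
    lctx, lidx = oriented_context(
        lseq, left.pos, left.direction, before=search_window + n, after=search_window + n
    )
    a, left_ref_pos = _best_left_match(fragment, lctx, lidx, left, min_flank)
    if a < min_flank:
        raise JunctionAnatomyError("left flank matches fragment at < min_flank bases")

    rseq = reference[right.seq_name]
    rctx, ridx = oriented_context(
        rseq, right.pos, right.direction, before=search_window + n, after=search_window + n
    )
    b, right_ref_pos = _best_right_match(fragment, rctx, ridx, right, min_flank)
    if b < min_flank:
        raise JunctionAnatomyError("right flank matches fragment at < min_flank bases")
    if a >= n or b >= n:
        # one flank explains the whole fragment: no junction crossed
        raise JunctionAnatomyError("fragment does not cross a novel adjacency")

    overlap = a + b - n
    if overlap > 0:
        if overlap > max_microhomology:
            raise JunctionAnatomyError(
                f"shared stretch of {overlap} bp exceeds the micro-homology cap"
            )
        mh = fragment[n - b : a]
        ins = ""
        refined_left = left_ref_pos  # end of maximal left match (mh-inclusive)
        refined_right = right_ref_pos  # start of maximal right match (mh-inclusive)
    else:
        mh = ""
        ins = fragment[a : n - b]
        refined_left = left_ref_pos
        refined_right = right_ref_pos

    rl = JunctionSide(left.seq_name, refined_left, left.direction)
    rr = JunctionSide(right.seq_name, refined_right, right.direction)
    # flanking deletions: only meaningful when the nominal side lies
    # downstream of the refined flank end along the reading direction
    del_prox = del_dist = None
    if infer_deletions:  # only meaningful against trusted nominal positions
        lstep = 1 if left.direction == ASCENDING else -1
        if (left.pos - rl.pos) * lstep > 0:
            del_prox = _side_interval(rl.pos + lstep, left.pos, left.seq_name)
        rstep = 1 if right.direction == ASCENDING else -1
        if (rr.pos - right.pos) * rstep > 0:
            del_dist = _side_interval(right.pos, rr.pos - rstep, right.seq_name)
    return JunctionAnatomy(
        left=rl, right=rr, microhomology=mh, inserted=ins,
        deleted_proximal=del_prox, deleted_distal=del_dist,
    )


def _best_left_match(fragment, ctx, idx, side, min_flank):
    """Maximal prefix of ``fragment`` matching the left oriented context.

    Returns (match length, reference position of the last matched base).
    """
    probe = fragment[:min_flank]
    best_len, best_pos = 0, side.pos
    start = 0
    while True:
        hit = ctx.find(probe, start)
        if hit < 0:
            break
        length = min_flank
        while hit + length < len(ctx) and length < len(fragment) and \
                ctx[hit + length] == fragment[length]:
            length += 1
        if length > best_len:
            best_len = length
            # ctx index -> reference coordinate along the side's direction
            best_pos = advance(side.pos, side.direction, hit + length - 1 - idx)
        start = hit + 1
    return best_len, best_pos


def _best_right_match(fragment, ctx, idx, side, min_flank):
    """Maximal suffix of ``fragment`` matching the right oriented context.

    Returns (match length, reference position of the first matched base).
    """
    n = len(fragment)
    probe = fragment[n - min_flank :]
    best_len, best_pos = 0, side.pos
    start = 0
    while True:
        hit = ctx.find(probe, start)
        if hit < 0:
            break
        length = min_flank
        # extend leftwards from the anchored suffix
        while hit - (length - min_flank) > 0 and length < n and \
                ctx[hit - (length - min_flank) - 1] == fragment[n - length - 1]:
            length += 1
        if length > best_len:
            best_len = length
            first_ctx = hit - (length - min_flank)
            best_pos = advance(side.pos, side.direction, first_ctx - idx)
        start = hit + 1
    return best_len, best_pos


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    expected_product: int | None = None

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"{name} primer length {len(p)} outside 15-35 nt")


@dataclass(frozen=True)
class PcrProduct:
    template: str
    start: int  # 1-based, inclusive; forward primer 5' end
    stop: int   # 1-based, inclusive; reverse primer 5' end
    length: int


def insilico_pcr(
    primers: PrimerPair, templates: dict[str, str], max_product: int = 10000
) -> list[PcrProduct]:
    """Exact-match PCR product prediction.

    Reports every correctly oriented (forward primer on the plus strand,
    reverse primer's reverse complement downstream) placement pair within
    ``max_product`` bp on each template. An empty list means no product —
    e.g. junction-spanning primers on the unrearranged reference.
    """
    from .sequtil import revcomp

    products = []
    rc_rev = revcomp(primers.reverse)
    for name, seq in templates.items():
        f_sites = _find_all(seq, primers.forward)
        r_sites = _find_all(seq, rc_rev)
        for f in f_sites:
            for r in r_sites:
                end = r + len(rc_rev)  # 0-based exclusive
                length = end - f
                if len(primers.forward) <= length <= max_product:
                    products.append(
                        PcrProduct(template=name, start=f + 1, stop=end, length=length)
                    )
    return products


def _find_all(seq: str, pattern: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1
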
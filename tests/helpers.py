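"""Shared test constructors and independent oracles.

These deliberately re-derive expectations with direct base-by-base string
scans, independent of the package's search-and-extend implementation.
"""

import numpy as np

from derivchrom.notation import JunctionSide, JunctionSpec
from derivchrom.sequtil import ASCENDING, advance, oriented_context, revcomp
from derivchrom.simulate import random_sequence


def build_fragment(reference, spec, flank=80):
    """Error-free junction fragment from a truth junction (mh-inclusive
    positions: the right flank resumes len(mh) bases past right.pos)."""
    seq = reference[spec.left.seq_name]
    lctx, lidx = oriented_context(seq, spec.left.pos, spec.left.direction, flank - 1, 0)
    h = len(spec.microhomology)
    rstart = advance(spec.right.pos, spec.right.direction, h)
    rseq = reference[spec.right.seq_name]
    rctx, _ = oriented_context(rseq, rstart, spec.right.direction, 0, flank - 1)
    return lctx[: lidx + 1] + spec.inserted + rctx


def plant_junction(rng, mh="", inserted="", n=4000, left_dir=ASCENDING,
                   right_dir=ASCENDING):
    """Random reference with a junction planted at fixed loci; micro-homology
    bases are written into both flanks, and the bases adjacent to each flank
    are forced to mismatch so the planted decomposition is maximal."""
    seq = list(random_sequence(n, rng))
    lpos, rpos = n // 3, 2 * n // 3
    h = len(mh)
    left = JunctionSide("ref", lpos, left_dir)
    right = JunctionSide("ref", rpos, right_dir)

    def put(side, offset, base):
        p = advance(side.pos, side.direction, offset)
        seq[p - 1] = base if side.direction == ASCENDING else revcomp(base)

    def get(side, offset):
        p = advance(side.pos, side.direction, offset)
        b = seq[p - 1]
        return b if side.direction == ASCENDING else revcomp(b)

    for k, base in enumerate(mh):
        put(left, k - h + 1, base)
        put(right, k, base)
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    nxt = inserted[0] if inserted else get(right, h)
    if get(left, 1) == nxt:
        put(left, 1, other[nxt])
    prev = inserted[-1] if inserted else get(left, -h)
    if get(right, -1) == prev:
        put(right, -1, other[prev])
    spec = JunctionSpec(left=left, right=right, microhomology=mh, inserted=inserted)
    return {"ref": "".join(seq)}, spec


def exhaustive_flank_matches(fragment, reference, spec, window=400, min_flank=20):
    """Brute-force maximal flank matches: scan every anchor placement of the
    fragment's first/last ``min_flank`` bases in oriented context and extend
    base by base. Returns (best_left_len, best_right_len)."""
    n = len(fragment)
    lctx, _ = oriented_context(
        reference[spec.left.seq_name], spec.left.pos, spec.left.direction,
        window, window)
    rctx, _ = oriented_context(
        reference[spec.right.seq_name], spec.right.pos, spec.right.direction,
        window, window)
    best_a = 0
    for s in range(len(lctx) - min_flank + 1):
        if lctx[s : s + min_flank] != fragment[:min_flank]:
            continue
        a = min_flank
        while a < n and s + a < len(lctx) and lctx[s + a] == fragment[a]:
            a += 1
        best_a = max(best_a, a)
    best_b = 0
    for end in range(min_flank, len(rctx) + 1):
        if rctx[end - min_flank : end] != fragment[-min_flank:]:
            continue
        b = min_flank
        while b < n and end - b - 1 >= 0 and rctx[end - b - 1] == fragment[n - b - 1]:
            b += 1
        best_b = max(best_b, b)
    return best_a, best_b


def random_anatomy_case(rng):
    """Draw a random micro-homology or insertion junction."""
    h = int(rng.integers(0, 5))
    ins_len = 0 if h else int(rng.integers(0, 8))
    bases = "ACGT"
    mh = "".join(bases[int(b)] for b in rng.integers(0, 4, h))
    ins = "".join(bases[int(b)] for b in rng.integers(0, 4, ins_len))
    return plant_junction(rng, mh=mh, inserted=ins)
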
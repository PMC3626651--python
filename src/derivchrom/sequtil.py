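"""Strand-aware sequence helpers shared by the simulator and junction tools."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ASCENDING = "ascending"
DESCENDING = "descending"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def advance(pos: int, direction: str, n: int) -> int:
    """Move ``n`` bases along an oriented reading (ascending: +, descending: -)."""
    return pos + n if direction == ASCENDING else pos - n


def oriented_context(
    seq: str, pos: int, direction: str, before: int, after: int
) -> tuple[str, int]:
    """Oriented reading of ``seq`` around 1-based coordinate ``pos``.

    Returns ``(text, idx)`` where ``text`` reads along ``direction``
    (ascending = forward strand toward higher coordinates, descending =
    reverse complement toward lower coordinates) and ``text[idx]`` is the
    base at ``pos``. Requests past the sequence ends are clipped.
    """
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside sequence of length {n}")
    if direction == ASCENDING:
        lo = max(1, pos - before)
        hi = min(n, pos + after)
        return seq[lo - 1 : hi], pos - lo
    elif direction == DESCENDING:
        lo = max(1, pos - after)
        hi = min(n, pos + before)
        return revcomp(seq[lo - 1 : hi]), hi - pos
    raise ValueError(f"unknown direction {direction!r}")


def oriented_base(seq: str, pos: int, direction: str) -> str:
    base = seq[pos - 1]
    return base if direction == ASCENDING else revcomp(base)
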
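"""Breakpoint-junction notation: oriented sides, micro-homology, insertions.

A junction joins two oriented reference flanks. The printed arrow notation
writes the left side as ``→POS`` or ``←POS`` and the right side as ``POS→``
or ``POS←``; an arrow pointing right (``→``) means the flank reads along the
forward strand toward higher coordinates (*ascending*), an arrow pointing
left (``←``) means the flank is the reverse complement read toward lower
coordinates (*descending*). Between the two sides the notation may carry

* ``**BASES**`` — micro-homology: bases present at the junction that match
  both flanks, so they could originate from either side (printed bold);
* ``_BASES_`` — bases inserted at the junction that match neither flank
  (printed underlined). ``_N<count>_`` denotes an insertion of known length
  but unknown sequence (e.g. satellite or unplaced-contig material).

Sequence semantics (shared with the simulator and the junction
characterizer): with micro-homology of length *h*, the derivative sequence
reads ``...left flank through left.pos`` then ``inserted`` then the right
flank resuming *h* bases past ``right.pos`` — both printed positions include
the micro-homology, which appears once in the derivative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .intervals import GenomeInterval
from .sequtil import ASCENDING, DESCENDING

_VALID_BASES = frozenset("ACGTN")

PCR_VERIFIED = "pcr_verified"
LARGE_INSERT_ONLY = "large_insert_only"


class JunctionParseError(ValueError):
    """Raised when a junction notation row cannot be parsed."""


@dataclass(frozen=True)
class JunctionSide:
    """One oriented flank of a junction.

    ``direction`` is ``"ascending"`` (forward strand, coordinates <= pos
    enter the junction reading toward pos) or ``"descending"`` (reverse
    complement, coordinates >= pos enter reading toward pos).
    """

    seq_name: str
    pos: int
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (ASCENDING, DESCENDING):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.pos < 1:
            raise ValueError(f"bad position {self.pos}")


@dataclass(frozen=True)
class JunctionSpec:
    """A breakpoint junction: two oriented sides plus junction anatomy."""

    left: JunctionSide
    right: JunctionSide
    microhomology: str = ""
    inserted: str = ""
    deleted_proximal: GenomeInterval | None = None
    deleted_distal: GenomeInterval | None = None
    evidence_flags: frozenset[str] = field(default_factory=frozenset)
    prefix: str = ""  # display-only bases printed 5' of the left position
    uncertainty_bp: int = 0

    def __post_init__(self) -> None:
        for name, bases in (("microhomology", self.microhomology),
                            ("inserted", self.inserted),
                            ("prefix", self.prefix)):
            if not set(bases) <= _VALID_BASES:
                raise ValueError(f"{name} contains non-ACGTN bases: {bases!r}")
        if self.microhomology and self.inserted:
            raise ValueError(
                "a junction cannot carry both micro-homology and inserted bases"
            )

    @property
    def pcr_verified(self) -> bool:
        return PCR_VERIFIED in self.evidence_flags

    @property
    def large_insert_only(self) -> bool:
        return LARGE_INSERT_ONLY in self.evidence_flags


def reverse_junction(spec: JunctionSpec) -> JunctionSpec:
    """The same junction read in the opposite direction.

    Reading the derivative's reverse complement swaps the sides, flips
    both directions and reverse-complements the micro-homology/inserted
    bases; the two readings describe one physical junction.
    """
    from .sequtil import revcomp

    def flip(direction: str) -> str:
        return DESCENDING if direction == ASCENDING else ASCENDING

    return JunctionSpec(
        left=JunctionSide(spec.right.seq_name, spec.right.pos, flip(spec.right.direction)),
        right=JunctionSide(spec.left.seq_name, spec.left.pos, flip(spec.left.direction)),
        microhomology=revcomp(spec.microhomology),
        inserted=revcomp(spec.inserted),
        deleted_proximal=spec.deleted_distal,
        deleted_distal=spec.deleted_proximal,
        evidence_flags=spec.evidence_flags,
        uncertainty_bp=spec.uncertainty_bp,
    )


def junction_key(spec: JunctionSpec) -> tuple:
    """Orientation-invariant identity of a junction (sides + anatomy)."""
    def one(s: JunctionSpec) -> tuple:
        return (
            s.left.seq_name, s.left.pos, s.left.direction,
            s.right.seq_name, s.right.pos, s.right.direction,
            s.microhomology, s.inserted,
        )

    return min(one(spec), one(reverse_junction(spec)))


_ROW_RE = re.compile(
    r"^(?P<prefix>[ACGTN]*)"
    r"(?P<larrow>[→←])\s*(?P<lpos>\d+)"
    r"\s*(?P<middle>.*?)\s*"
    r"(?P<rpos>\d+)\s*(?P<rarrow>[→←])$"
)
_MIDDLE_RE = re.compile(r"\*\*(?P<bold>[ACGTN]+)\*\*|_(?P<ins>[ACGTN]+|N\d+)_")


def _arrow_dir(arrow: str) -> str:
    return ASCENDING if arrow == "→" else DESCENDING


def _dir_arrow(direction: str) -> str:
    return "→" if direction == ASCENDING else "←"


def expand_insert_token(token: str) -> str:
    """``"N800"`` -> 800 N's; literal base strings pass through."""
    m = re.fullmatch(r"N(\d+)", token)
    return "N" * int(m.group(1)) if m else token


def _compress_insert(bases: str) -> str:
    if len(bases) > 1 and set(bases) == {"N"}:
        return f"N{len(bases)}"
    return bases


def parse_junction_notation(
    text_row: str,
    seq_name: str = "chr21",
    bold: str | None = None,
    **extra,
) -> JunctionSpec:
    """Parse one arrow-notation row into a :class:`JunctionSpec`.

    Markup inside the row (``**bold**`` micro-homology, ``_underlined_``
    insertion) is honoured; alternatively an unstyled middle may be
    classified by passing ``bold="CTT"`` (the bases known to be printed
    bold). An unstyled middle with no hint is treated as inserted bases,
    per the table convention that shared bases are always marked.

    ``extra`` keyword arguments (deleted intervals, evidence flags, ...)
    are forwarded to :class:`JunctionSpec`.
    """
    m = _ROW_RE.match(text_row.strip())
    if m is None:
        raise JunctionParseError(f"row does not match arrow grammar: {text_row!r}")
    middle = m.group("middle").strip()
    mh, ins = "", ""
    if middle:
        pos = 0
        for tok in _MIDDLE_RE.finditer(middle):
            if middle[pos:tok.start()].strip():
                raise JunctionParseError(
                    f"unrecognized junction token {middle[pos:tok.start()]!r}"
                )
            if tok.group("bold"):
                mh += tok.group("bold")
            else:
                ins += expand_insert_token(tok.group("ins"))
            pos = tok.end()
        rest = middle[pos:].strip()
        if rest:
            if not set(rest) <= _VALID_BASES:
                raise JunctionParseError(f"unrecognized junction token {rest!r}")
            if bold is not None and rest == bold:
                mh += rest
            else:
                ins += rest
    return JunctionSpec(
        left=JunctionSide(seq_name, int(m.group("lpos")), _arrow_dir(m.group("larrow"))),
        right=JunctionSide(seq_name, int(m.group("rpos")), _arrow_dir(m.group("rarrow"))),
        microhomology=mh,
        inserted=ins,
        prefix=m.group("prefix"),
        **extra,
    )


def serialize_junction_notation(spec: JunctionSpec) -> str:
    """Canonical arrow-notation row for a junction (inverse of parsing)."""
    if spec.microhomology:
        middle = f" **{spec.microhomology}** "
    elif spec.inserted:
        middle = f" _{_compress_insert(spec.inserted)}_ "
    else:
        middle = " "
    return (
        f"{spec.prefix}{_dir_arrow(spec.left.direction)}{spec.left.pos}"
        f"{middle}{spec.right.pos}{_dir_arrow(spec.right.direction)}"
    )
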
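"""Genomic interval algebra on 1-based inclusive coordinates.

All coordinates in this package are 1-based and inclusive, matching the
convention of printed breakpoint tables and aCGH segment lists. Conversion
to 0-based half-open happens only at BED import/export boundaries
(:func:`to_bed_fields`, :func:`from_bed_fields`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence


class IntervalError(ValueError):
    """Raised for ill-formed intervals or invalid interval arithmetic."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A closed interval ``[start, stop]`` on a named sequence.

    Invariants: ``start >= 1`` and ``stop >= start``. The span of an
    interval is ``stop - start + 1`` base pairs.
    """

    seq_name: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.stop < self.start:
            raise IntervalError(
                f"stop ({self.stop}) must be >= start ({self.start})"
            )

    @property
    def span(self) -> int:
        return self.stop - self.start + 1

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start <= other.start
            and other.stop <= self.stop
        )

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start <= other.stop
            and other.start <= self.stop
        )

    def shifted(self, offset: int) -> "GenomeInterval":
        return GenomeInterval(self.seq_name, self.start + offset, self.stop + offset)

    def __str__(self) -> str:  # e.g. "chr21:46,869,870-47,319,181"
        return f"{self.seq_name}:{self.start:,}-{self.stop:,}"


def span_length(interval: GenomeInterval, retained: GenomeInterval | None = None) -> int:
    """Span of ``interval`` in bp, minus the span of a ``retained`` sub-interval.

    Used for reporting the effective size of a deletion in which an internal
    block of sequence is retained.

    Raises :class:`IntervalError` if ``retained`` does not lie within
    ``interval``.
    """
    if retained is None:
        return interval.span
    if not interval.contains(retained):
        raise IntervalError(
            f"retained interval {retained} does not lie within {interval}"
        )
    return interval.span - retained.span


def union_spans(intervals: Iterable[GenomeInterval]) -> int:
    """Total bp covered by the union of intervals (per sequence)."""
    return sum(iv.span for iv in merge_intervals(intervals))


def merge_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Merge overlapping or book-ended intervals into a disjoint sorted list."""
    ivs = sorted(intervals, key=lambda i: (i.seq_name, i.start, i.stop))
    merged: list[GenomeInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].seq_name == iv.seq_name
            and iv.start <= merged[-1].stop + 1
        ):
            if iv.stop > merged[-1].stop:
                merged[-1] = GenomeInterval(iv.seq_name, merged[-1].start, iv.stop)
        else:
            merged.append(iv)
    return merged


def subtract_interval(
    interval: GenomeInterval, holes: Sequence[GenomeInterval]
) -> list[GenomeInterval]:
    """Parts of ``interval`` not covered by any of ``holes``."""
    pieces: list[GenomeInterval] = []
    cursor = interval.start
    for hole in merge_intervals(h for h in holes if h.overlaps(interval)):
        if hole.start > cursor:
            pieces.append(GenomeInterval(interval.seq_name, cursor, hole.start - 1))
        cursor = max(cursor, hole.stop + 1)
    if cursor <= interval.stop:
        pieces.append(GenomeInterval(interval.seq_name, cursor, interval.stop))
    return pieces


def round_printed(value_bp: int, unit: str, decimals: int = 0) -> float:
    """Round a bp count to the precision a report would print.

    ``unit`` is ``"bp"``, ``"kb"`` or ``"Mb"``; rounding is half-up at the
    printed digit (so 958,834 bp -> 959 kb, 2,729,526 bp -> 2.7 Mb).
    """
    scale = {"bp": 1, "kb": 1_000, "Mb": 1_000_000}[unit]
    q = Decimal(1).scaleb(-decimals)
    out = (Decimal(value_bp) / scale).quantize(q, rounding=ROUND_HALF_UP)
    return float(out)


def to_bed_fields(interval: GenomeInterval) -> tuple[str, int, int]:
    """(chrom, chromStart, chromEnd) with BED's 0-based half-open convention."""
    return interval.seq_name, interval.start - 1, interval.stop


def from_bed_fields(chrom: str, chrom_start: int, chrom_end: int) -> GenomeInterval:
    return GenomeInterval(chrom, chrom_start + 1, chrom_end)
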
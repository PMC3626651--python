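"""Packaged breakpoint/copy-number fixture for the rearranged chromosome.

The package ships a transcription of the published evidence for the
irradiated human chromosome 21 carried by the transchromosomic mouse line:
27 breakpoint junctions in arrow notation (with micro-homology, inserted
bases, flanking deletions and verification flags) and the aCGH-derived
copy-number intervals (three deletions, one with an internal retained
block, and six duplications) on GRCh37 chr21 (48,129,895 bp).
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field

from .intervals import GenomeInterval
from .notation import (
    LARGE_INSERT_ONLY,
    PCR_VERIFIED,
    JunctionSpec,
    parse_junction_notation,
    serialize_junction_notation,
)

CHR21_LENGTH = 48_129_895  # GRCh37 chromosome 21


class CorruptFixtureError(RuntimeError):
    """Packaged fixture failed checksum or shape validation."""


@dataclass(frozen=True)
class FixtureCorpus:
    """The transcribed junction table and printed aCGH intervals."""

    junctions: tuple[JunctionSpec, ...]
    acgh_deletions: tuple[tuple[GenomeInterval, GenomeInterval | None], ...]
    acgh_duplications: tuple[GenomeInterval, ...]
    chrom_length: int = CHR21_LENGTH
    seq_name: str = "chr21"
    analyzed_span: tuple[int, int] = (1, CHR21_LENGTH)
    notes: dict[int, str] = field(default_factory=dict)


def _parse_opt_interval(text: str, seq_name: str) -> GenomeInterval | None:
    if text in (".", ""):
        return None
    start, stop = (int(x) for x in text.split("-"))
    return GenomeInterval(seq_name, start, stop)


def _fmt_opt_interval(iv: GenomeInterval | None) -> str:
    return "." if iv is None else f"{iv.start}-{iv.stop}"


def serialize_fixture(corpus: FixtureCorpus) -> str:
    """Canonical text form of the corpus (used for checksums/round-trips)."""
    lines = [f"{corpus.seq_name} {corpus.chrom_length} "
             f"{corpus.analyzed_span[0]}-{corpus.analyzed_span[1]}"]
    for j in corpus.junctions:
        lines.append(
            "\t".join(
                [
                    serialize_junction_notation(j),
                    _fmt_opt_interval(j.deleted_proximal),
                    _fmt_opt_interval(j.deleted_distal),
                    "1" if j.pcr_verified else "0",
                    "1" if j.large_insert_only else "0",
                    str(j.uncertainty_bp),
                ]
            )
        )
    for iv, retained in corpus.acgh_deletions:
        lines.append(f"del\t{_fmt_opt_interval(iv)}\t{_fmt_opt_interval(retained)}")
    for iv in corpus.acgh_duplications:
        lines.append(f"dup\t{_fmt_opt_interval(iv)}")
    return "\n".join(lines) + "\n"


def _load_raw() -> tuple[list[dict], dict]:
    root = importlib.resources.files("derivchrom") / "data"
    with (root / "junctions.tsv").open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    meta = json.loads((root / "acgh_segments.json").read_text(encoding="utf-8"))
    return rows, meta


def load_fixture(verify_checksum: bool = True) -> FixtureCorpus:
    """Load and validate the packaged corpus.

    Raises :class:`CorruptFixtureError` on shape or checksum mismatch.
    """
    rows, meta = _load_raw()
    seq_name = meta["seq_name"]
    junctions: list[JunctionSpec] = []
    notes: dict[int, str] = {}
    for row in rows:
        flags = set()
        if row["pcr_verified"] == "1":
            flags.add(PCR_VERIFIED)
        if row["large_insert_only"] == "1":
            flags.add(LARGE_INSERT_ONLY)
        spec = parse_junction_notation(
            row["notation"],
            seq_name=seq_name,
            deleted_proximal=_parse_opt_interval(row["deleted_proximal"], seq_name),
            deleted_distal=_parse_opt_interval(row["deleted_distal"], seq_name),
            evidence_flags=frozenset(flags),
            uncertainty_bp=int(row["uncertainty_bp"]),
        )
        if serialize_junction_notation(spec) != row["notation"]:
            raise CorruptFixtureError(
                f"junction row {row['id']} does not round-trip: {row['notation']!r}"
            )
        junctions.append(spec)
        if row.get("note", ".") not in (".", ""):
            notes[int(row["id"])] = row["note"]

    deletions = tuple(
        (
            GenomeInterval(seq_name, *d["interval"]),
            GenomeInterval(seq_name, *d["retained"]) if d["retained"] else None,
        )
        for d in meta["deletions"]
    )
    duplications = tuple(
        GenomeInterval(seq_name, *iv) for iv in meta["duplications"]
    )
    corpus = FixtureCorpus(
        junctions=tuple(junctions),
        acgh_deletions=deletions,
        acgh_duplications=duplications,
        chrom_length=int(meta["chrom_length"]),
        seq_name=seq_name,
        analyzed_span=tuple(meta["analyzed_span"]),
        notes=notes,
    )
    if len(corpus.junctions) != 27:
        raise CorruptFixtureError(f"expected 27 junctions, got {len(corpus.junctions)}")
    if len(corpus.acgh_deletions) != 3 or len(corpus.acgh_duplications) != 6:
        raise CorruptFixtureError("expected 3 deletions and 6 duplications")
    for iv, retained in corpus.acgh_deletions:
        if retained is not None and not iv.contains(retained):
            raise CorruptFixtureError(f"retained block {retained} outside {iv}")
    if verify_checksum:
        digest = hashlib.sha256(serialize_fixture(corpus).encode()).hexdigest()
        if digest != meta["sha256"]:
            raise CorruptFixtureError(
                f"fixture checksum mismatch: {digest} != {meta['sha256']}"
            )
    return corpus
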
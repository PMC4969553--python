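"""Sequence and interval I/O with one fixed coordinate convention.

All in-memory coordinates are 0-based half-open.  Conversion to the 1-based
inclusive convention of GFF3 (and from BED's 0-based half-open intervals)
happens only at file boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """A file could not be parsed (malformed record, illegal character)."""


class ValidationError(ValueError):
    """Well-formed input that violates a semantic constraint."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercased on construction."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        comp = str.maketrans("ACGTN", "TGCAN")
        return SequenceRecord(self.id, self.seq.translate(comp)[::-1])


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Breakpoint:
    seq_id: str
    pos: int
    label: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative breakpoint position {self.pos}")


@dataclass
class BreakpointSet:
    """Genomic point events (breakpoints / hotspots) on named sequences."""

    points: list[Breakpoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def _locate_illegal_character(path) -> tuple[int, str]:
    """Return (line_number, char) of the first non-IUPAC sequence character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") or not line.strip():
                continue
            for ch in line.strip():
                if ch.upper() not in VALID_BASES:
                    return lineno, ch
    return -1, ""


def read_fasta(path, respect_mask: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, in file order.

    Sequences are uppercased; multi-line entries are concatenated.  With
    ``respect_mask=True``, soft-masked (lowercase) bases are converted to N
    so masked runs never seed or extend a motif tract.  An empty file yields
    an empty list.

    Raises
    ------
    ParseError
        If the file is not FASTA-formatted or contains a non-IUPAC
        character (the error names the offending line).
    """
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython message passthrough
        raise ParseError(f"{path}: not valid FASTA: {exc}") from exc
    with open(path) as fh:
        head = fh.read(1)
    if head and head != ">" and not head.isspace():
        raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in parsed:
        raw = str(rec.seq)
        if respect_mask:
            raw = re.sub(r"[a-z]", "N", raw)
        try:
            records.append(SequenceRecord(rec.id, raw))
        except ValidationError as exc:
            lineno, ch = _locate_illegal_character(path)
            raise ParseError(
                f"{path}: line {lineno}: illegal sequence character {ch!r}"
            ) from exc
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_bed_points(path) -> BreakpointSet:
    """Read breakpoints from a 3+ column BED file.

    BED is 0-based half-open.  Unit intervals (end == start + 1) map to
    their single base; wider records are reduced to the midpoint
    floor((start + end) / 2) with a warning, because breakpoints are
    conceptually points.  Column 4 supplies the label when present.
    """
    points: list[Breakpoint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            seq_id = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ValidationError(
                    f"{path}: line {lineno}: empty or inverted interval "
                    f"{start}-{end}"
                )
            if end == start + 1:
                pos = start
            else:
                pos = (start + end) // 2
                warnings.warn(
                    f"{path}: line {lineno}: {end - start} bp BED record reduced "
                    f"to midpoint {pos}",
                    stacklevel=2,
                )
            label = cols[3] if len(cols) >= 4 and cols[3] else f"bp{len(points) + 1}"
            points.append(Breakpoint(seq_id, pos, label))
    return BreakpointSet(points)


def write_bed_points(bps: BreakpointSet, path) -> None:
    with open(path, "w") as fh:
        for bp in bps:
            fh.write(f"{bp.seq_id}\t{bp.pos}\t{bp.pos + 1}\t{bp.label}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read a BED3/BED4 file as intervals (for region masks)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            out.append(GenomicInterval(cols[0], start, end))
    return out


_GFF3_ESCAPE = {";": "%3B", "=": "%3D", ",": "%2C", "&": "%26"}


def _gff3_escape(value: str) -> str:
    for raw, esc in _GFF3_ESCAPE.items():
        value = value.replace(raw, esc)
    return value


def _hit_sort_key(hit):
    iv = hit.interval
    return (iv.seq_id, iv.start, -(iv.end - iv.start))


def write_hits_gff3(hits, path, seq_lengths: dict[str, int] | None = None) -> None:
    """Write motif hits as GFF3 (1-based, inclusive).

    Mirror-repeat hits get type ``triplex_motif`` with arm/spacer/mismatch
    attributes; Z-DNA hits get type ``Z_DNA_motif`` with score attributes.
    Hits are ordered by (seq_id, start, longer-first).  When ``seq_lengths``
    is given, out-of-bounds hits raise ValidationError.
    """
    from nonbscan.hdna import MirrorRepeatHit
    from nonbscan.zdna import ZdnaHit

    lines = ["##gff-version 3"]
    for i, hit in enumerate(sorted(hits, key=_hit_sort_key), start=1):
        iv = hit.interval
        if seq_lengths is not None:
            length = seq_lengths.get(iv.seq_id)
            if length is None or iv.end > length:
                raise ValidationError(
                    f"hit {iv.seq_id}:{iv.start}-{iv.end} out of sequence bounds"
                )
        if isinstance(hit, MirrorRepeatHit):
            ftype = "triplex_motif"
            score = "."
            attrs = (
                f"ID=hdna{i};arm_len={hit.arm_len};spacer_len={hit.spacer_len};"
                f"mismatches={hit.mismatches};tract_type={hit.tract_type};"
                f"arm1_seq={hit.arm1_seq};spacer_seq={_gff3_escape(hit.spacer_seq)};"
                f"arm2_seq={hit.arm2_seq}"
            )
        elif isinstance(hit, ZdnaHit):
            ftype = "Z_DNA_motif"
            score = f"{hit.score:g}"
            attrs = (
                f"ID=zdna{i};n_steps={hit.n_steps};frame_offset={hit.frame_offset};"
                f"gc_steps={hit.step_breakdown.get('GC', 0)};"
                f"gtca_steps={hit.step_breakdown.get('GT/CA', 0)};"
                f"at_steps={hit.step_breakdown.get('AT', 0)}"
            )
        else:
            raise TypeError(f"cannot serialize hit of type {type(hit).__name__}")
        lines.append(
            "\t".join(
                [
                    iv.seq_id,
                    "nonbscan",
                    ftype,
                    str(iv.start + 1),  # GFF3 is 1-based inclusive
                    str(iv.end),
                    score,
                    iv.strand if iv.strand != "." else "+",
                    ".",
                    attrs,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3_intervals(path) -> list[GenomicInterval]:
    """Read GFF3 feature lines back as 0-based half-open intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = cols[6] if cols[6] in {"+", "-"} else "."
            out.append(GenomicInterval(cols[0], start1 - 1, end1, strand))
    return out
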
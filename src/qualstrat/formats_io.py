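"""Readers, writers and quality-variant transforms for FASTQ, FASTA, SAM and BED.

Only strict 4-line FASTQ (Sanger, Phred+33) is supported: nanopore basecallers
emit exactly that layout, and line-wrapped FASTQ is ambiguous because ``@`` is a
legal quality character. FASTA output is written unwrapped (one sequence line
per record) so that round-trips are byte-exact. SAM is consumed as text through
pysam; a headerless body is tolerated by synthesising ``@SQ`` lines from the
alignment spans before parsing.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

PRINTABLE_MIN = 33
PRINTABLE_MAX = 126

#: CIGAR operators that consume query (read) bases.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operators that consume reference bases.
REFERENCE_OPS = frozenset("MDN=X")

_CIGAR_OPS = "MIDNSHP=XB"
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class FastqParseError(ValueError):
    """Raised when a FASTQ file violates the strict 4-line contract."""


class SamParseError(ValueError):
    """Raised when a SAM record cannot be parsed or is internally inconsistent."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: id, nucleotide sequence, optional Phred+33 quality."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None:
            if len(self.quality) != len(self.sequence):
                raise ValueError(
                    f"read {self.read_id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            for ch in self.quality:
                if not PRINTABLE_MIN <= ord(ch) <= PRINTABLE_MAX:
                    raise ValueError(
                        f"read {self.read_id!r}: quality character {ch!r} "
                        f"(ordinal {ord(ch)}) outside printable range [33,126]"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BedInterval:
    """A BED3 interval: 0-based, half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM body line.

    ``position`` is the 1-based leftmost reference coordinate (0 for unmapped
    records); ``cigar`` is an ordered tuple of ``(operator, length)`` pairs.
    """

    read_id: str
    flags: int
    reference_name: str | None
    position: int
    cigar: tuple[tuple[str, int], ...]
    seq: str | None = None
    qual: str | None = None
    tags: Mapping[str, object] | None = None
    mapq: int = 0

    def __post_init__(self) -> None:
        for op, length in self.cigar:
            if op not in _CIGAR_OPS:
                raise SamParseError(f"read {self.read_id!r}: unknown CIGAR operator {op!r}")
            if length <= 0:
                raise SamParseError(f"read {self.read_id!r}: non-positive CIGAR length")
        if self.seq is not None and self.cigar:
            consumed = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if consumed != len(self.seq):
                raise SamParseError(
                    f"read {self.read_id!r}: CIGAR consumes {consumed} query bases "
                    f"but SEQ has length {len(self.seq)}"
                )
        if not self.is_unmapped and self.position < 1:
            raise SamParseError(f"read {self.read_id!r}: mapped record with POS < 1")

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & FLAG_SUPPLEMENTARY)

    @property
    def is_primary_mapped(self) -> bool:
        return not (self.is_unmapped or self.is_secondary or self.is_supplementary)

    def deleted_bases(self) -> int:
        return sum(n for op, n in self.cigar if op == "D")


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a strict 4-line FASTQ file.

    Duplicate read ids are disambiguated by suffixing ``_dupN`` (some
    basecallers emit several records per raw signal file); a warning is logged.
    """
    records: list[ReadRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FastqParseError(
            f"{path}: line count {len(lines)} is not a multiple of 4"
        )
    for idx in range(len(lines) // 4):
        header, seq, plus, qual = lines[4 * idx: 4 * idx + 4]
        if not header.startswith("@"):
            raise FastqParseError(f"{path}: record {idx}: header does not start with '@'")
        if not plus.startswith("+"):
            raise FastqParseError(f"{path}: record {idx}: separator does not start with '+'")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"{path}: record {idx}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        read_id = header[1:].split()[0] if len(header) > 1 else ""
        if read_id in seen:
            seen[read_id] += 1
            new_id = f"{read_id}_dup{seen[read_id]}"
            logger.warning("%s: duplicate read id %r renamed to %r", path, read_id, new_id)
            read_id = new_id
        else:
            seen[read_id] = 0
        try:
            records.append(ReadRecord(read_id, seq, qual))
        except ValueError as exc:
            raise FastqParseError(f"{path}: record {idx}: {exc}") from exc
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write strict 4-line FASTQ. Every record must carry a quality string."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(
                    f"read {rec.read_id!r} has no quality string; use write_fasta"
                )
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


def fake_quality(records: Iterable[ReadRecord], symbol: str = "?") -> list[ReadRecord]:
    """Replace every quality string by a run of ``symbol`` of the same length.

    Sequences and ids are untouched; the operation is idempotent.
    """
    if len(symbol) != 1 or not PRINTABLE_MIN <= ord(symbol) <= PRINTABLE_MAX:
        raise ValueError(f"fake-quality symbol {symbol!r} not a printable ASCII character")
    return [replace(rec, quality=symbol * len(rec.sequence)) for rec in records]


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write unwrapped FASTA (one header line, one sequence line per record)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")


def strip_to_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Drop quality information and write the reads as unwrapped FASTA."""
    write_fasta(records, path)


def read_fasta(path: str | Path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[BedInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(BedInterval(fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar: tuple[tuple[str, int], ...] = ()
    if a.cigartuples:
        cigar = tuple((_CIGAR_OPS[op], length) for op, length in a.cigartuples)
    qual = None
    if a.query_qualities is not None:
        qual = "".join(chr(q + 33) for q in a.query_qualities)
    return AlignmentRecord(
        read_id=a.query_name or "",
        flags=a.flag,
        reference_name=a.reference_name if a.reference_id >= 0 else None,
        position=(a.reference_start + 1) if a.reference_start is not None and a.reference_start >= 0 else 0,
        cigar=cigar,
        seq=a.query_sequence,
        qual=qual,
        tags=dict(a.get_tags()),
        mapq=a.mapping_quality,
    )


def _synthesise_header(sam_text: str) -> str:
    """Prepend @SQ lines inferred from alignment spans of a headerless SAM body."""
    spans: dict[str, int] = {}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 6 or fields[2] == "*":
            continue
        rname, pos, cigar = fields[2], int(fields[3]), fields[5]
        ref_len = 0
        if cigar != "*":
            num = ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in REFERENCE_OPS:
                        ref_len += int(num)
                    num = ""
        end = pos - 1 + ref_len
        spans[rname] = max(spans.get(rname, 0), end)
    header = "".join(f"@SQ\tSN:{name}\tLN:{end}\n" for name, end in spans.items())
    return header + sam_text


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse a text SAM file into :class:`AlignmentRecord` objects.

    Header lines are used only to resolve reference names; a body without
    ``@SQ`` lines is handled by synthesising them from the alignment spans.
    """
    text = Path(path).read_text()
    body_lines = [ln for ln in text.splitlines() if ln and not ln.startswith("@")]
    has_sq = any(ln.startswith("@SQ") for ln in text.splitlines())
    if body_lines and not has_sq:
        text = _synthesise_header(text)
    records = []
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as tmp:
        tmp.write(text)
        tmp_path = tmp.name
    try:
        with pysam.AlignmentFile(tmp_path, "r", check_sq=False) as fh:
            for a in fh:
                records.append(_from_pysam(a))
    except (ValueError, OSError) as exc:
        raise SamParseError(f"{path}: {exc}") from exc
    finally:
        Path(tmp_path).unlink(missing_ok=True)
    return records
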
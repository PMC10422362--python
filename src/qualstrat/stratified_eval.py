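"""CIGAR-stratified alignment statistics, grouped by FASTQ quality symbol.

The central computation: walk each primary alignment's CIGAR against the
read's per-base quality string and assign every read base exactly one outcome

* ``matched``    — aligned, identical to the reference (``=``),
* ``mismatched`` — aligned, substituted (``X``),
* ``inserted``   — present in the read, absent from the reference (``I``),
* ``clipped``    — soft- or hard-clipped flank (``S``/``H``),

then tally the outcomes per quality symbol. Deletions consume reference bases
only — a deleted base has no read quality symbol — so they are accumulated as
a separate total rather than per symbol.

Ambiguous ``M`` operators are resolved to match/mismatch through the MD tag
when present, or through the reference sequence when supplied; with neither,
the classification aborts rather than guess.

Reverse-strand alignments store SEQ/QUAL in reference orientation; positions
are mapped back to original read coordinates, which leaves the per-symbol
tallies strand-invariant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import AlignmentRecord, ReadRecord, reverse_complement
from .quality_models import phred_from_symbol
from .util import round_half_up


class BaseOutcome(str, Enum):
    MATCHED = "matched"
    MISMATCHED = "mismatched"
    INSERTED = "inserted"
    CLIPPED = "clipped"


class UnresolvableMatchError(ValueError):
    """An ``M`` operator could not be resolved to match/mismatch."""


class ConsistencyError(ValueError):
    """SAM record and original FASTQ read disagree."""


@dataclass
class SymbolTally:
    matched: int = 0
    mismatched: int = 0
    inserted: int = 0
    clipped: int = 0
    total_in_fastq: int = 0
    total_in_mapped_reads: int = 0

    @property
    def outcome_total(self) -> int:
        return self.matched + self.mismatched + self.inserted + self.clipped

    @property
    def aligned(self) -> int:
        """Bases of this symbol aligned to the reference (incl. insertions)."""
        return self.matched + self.mismatched + self.inserted


@dataclass
class StratifiedCounts:
    per_symbol: dict[str, SymbolTally] = field(default_factory=dict)
    deletions_total: int = 0

    def tally(self, symbol: str) -> SymbolTally:
        return self.per_symbol.setdefault(symbol, SymbolTally())

    def check_conservation(self) -> None:
        """Per symbol, matched+mismatched+inserted+clipped must equal the
        symbol's base count in reads that have a primary alignment."""
        for symbol, t in self.per_symbol.items():
            if t.outcome_total != t.total_in_mapped_reads:
                raise AssertionError(
                    f"symbol {symbol!r}: outcomes {t.outcome_total} != "
                    f"bases in mapped reads {t.total_in_mapped_reads}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for symbol in sorted(self.per_symbol):
            t = self.per_symbol[symbol]
            qs = phred_from_symbol(symbol)
            aligned_ref = t.matched + t.mismatched
            rows.append({
                "symbol": symbol,
                "phred": qs.phred,
                "total_in_fastq": t.total_in_fastq,
                "matched": t.matched,
                "mismatched": t.mismatched,
                "inserted": t.inserted,
                "clipped": t.clipped,
                "mapped_fraction": (t.aligned / t.total_in_fastq) if t.total_in_fastq else 0.0,
                "empirical_error_rate": (t.mismatched / aligned_ref) if aligned_ref else float("nan"),
                "theoretical_error_rate": qs.error_prob,
            })
        return pd.DataFrame(rows)


@dataclass
class SymbolDistribution:
    """Fraction of all read bases carrying each quality symbol."""

    per_symbol: dict[str, float]
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"symbol": s, "phred": phred_from_symbol(s).phred,
             "fraction": f, "count": round(f * self.n_total)}
            for s, f in sorted(self.per_symbol.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class ReadSetSummary:
    """Read-set level percentages (BBMap-style report row).

    ``mapped_pct`` is aligned query bases over all FASTQ bases; the four error
    percentages share the alignment-column denominator
    (matched + mismatched + inserted + deleted), so they sum to 100.
    """

    n_reads: int
    sum_bp: int
    mapped_pct: float
    match_pct: float
    sub_pct: float
    del_pct: float
    ins_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


# ---------------------------------------------------------------------------
# MD tag resolution
# ---------------------------------------------------------------------------

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


def md_aligned_columns(md: str) -> list[str | None]:
    """Expand an MD tag into one entry per aligned (non-insertion) column.

    ``None`` marks a match; a base letter is the reference base at a mismatch.
    Deleted reference bases (after ``^``) occupy no aligned column and are
    skipped.
    """
    cols: list[str | None] = []
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise ValueError(f"malformed MD tag {md!r}")
        pos = m.end()
        num, deletion, base = m.groups()
        if num is not None:
            cols.extend([None] * int(num))
        elif base is not None:
            cols.append(base.upper())
        # deletion: no aligned column
    if pos != len(md):
        raise ValueError(f"malformed MD tag {md!r}")
    return cols


# ---------------------------------------------------------------------------
# Per-base classification
# ---------------------------------------------------------------------------

def classify_alignment_bases(
    aln: AlignmentRecord,
    original: ReadRecord,
    reference: Mapping[str, str] | None = None,
) -> list[tuple[int, str | None, BaseOutcome]]:
    """Assign an outcome to every base of ``original``, in read coordinates.

    Returns ``(read_position, quality_symbol, outcome)`` triples covering all
    ``len(original)`` positions exactly once. ``aln`` must be a mapped primary
    alignment of ``original``; hard-clipped bases (absent from SAM SEQ) are
    recovered from the original read.
    """
    if aln.is_unmapped:
        raise ValueError(f"read {aln.read_id!r}: cannot classify an unmapped record")
    length = len(original.sequence)
    reverse = aln.is_reverse
    stored = reverse_complement(original.sequence) if reverse else original.sequence
    stored_upper = stored.upper()

    # Hard clips bracket the SAM SEQ; check what SEQ there is against the read.
    if aln.seq is not None:
        lead_h = aln.cigar[0][1] if aln.cigar and aln.cigar[0][0] == "H" else 0
        tail_h = aln.cigar[-1][1] if aln.cigar and aln.cigar[-1][0] == "H" else 0
        expected = stored_upper[lead_h: length - tail_h]
        if aln.seq.upper() != expected:
            raise ConsistencyError(
                f"read {aln.read_id!r}: SAM SEQ disagrees with the original read"
            )

    md = None
    if aln.tags and "MD" in aln.tags:
        md = md_aligned_columns(str(aln.tags["MD"]))
    md_cursor = 0
    ref_seq = None
    if reference is not None and aln.reference_name is not None:
        ref_seq = reference.get(aln.reference_name)

    outcomes: list[BaseOutcome | None] = [None] * length
    stored_pos = 0
    ref_pos = aln.position - 1

    for op, n in aln.cigar:
        if op in ("S", "H"):
            for k in range(n):
                outcomes[stored_pos + k] = BaseOutcome.CLIPPED
            stored_pos += n
        elif op == "=":
            for k in range(n):
                outcomes[stored_pos + k] = BaseOutcome.MATCHED
            stored_pos += n
            ref_pos += n
            md_cursor += n
        elif op == "X":
            for k in range(n):
                outcomes[stored_pos + k] = BaseOutcome.MISMATCHED
            stored_pos += n
            ref_pos += n
            md_cursor += n
        elif op == "M":
            for k in range(n):
                if md is not None:
                    col = md[md_cursor + k]
                    mismatch = col is not None  # ref base recorded => mismatch (incl. 'N')
                elif ref_seq is not None:
                    ref_base = ref_seq[ref_pos + k].upper()
                    mismatch = ref_base == "N" or ref_base != stored_upper[stored_pos + k]
                else:
                    raise UnresolvableMatchError(
                        f"read {aln.read_id!r}: CIGAR 'M' with neither an MD tag "
                        "nor a reference sequence"
                    )
                outcomes[stored_pos + k] = (
                    BaseOutcome.MISMATCHED if mismatch else BaseOutcome.MATCHED
                )
            stored_pos += n
            ref_pos += n
            md_cursor += n
        elif op == "I":
            for k in range(n):
                outcomes[stored_pos + k] = BaseOutcome.INSERTED
            stored_pos += n
        elif op in ("D", "N"):
            ref_pos += n
        elif op == "P":
            pass
        else:
            raise ValueError(f"read {aln.read_id!r}: unsupported CIGAR operator {op!r}")

    if stored_pos != length or any(o is None for o in outcomes):
        raise ConsistencyError(
            f"read {aln.read_id!r}: CIGAR covers {stored_pos} of {length} read bases"
        )

    result = []
    for sp in range(length):
        read_pos = (length - 1 - sp) if reverse else sp
        symbol = original.quality[read_pos] if original.quality is not None else None
        result.append((read_pos, symbol, outcomes[sp]))
    result.sort(key=lambda t: t[0])
    return result


# ---------------------------------------------------------------------------
# Read-set level accumulation
# ---------------------------------------------------------------------------

def symbol_distribution(reads: Sequence[ReadRecord]) -> SymbolDistribution:
    """Fraction of all nucleotides carrying each quality symbol."""
    counts: dict[str, int] = {}
    total = 0
    for rec in reads:
        if rec.quality is None:
            raise ValueError(f"read {rec.read_id!r} has no quality string")
        for ch in rec.quality:
            counts[ch] = counts.get(ch, 0) + 1
        total += len(rec.quality)
    fractions = {s: c / total for s, c in counts.items()} if total else {}
    return SymbolDistribution(per_symbol=fractions, n_total=total)


def _index_reads(reads: Sequence[ReadRecord]) -> dict[str, ReadRecord]:
    return {rec.read_id: rec for rec in reads}


def stratify(
    alignments: Iterable[AlignmentRecord],
    reads: Sequence[ReadRecord],
    reference: Mapping[str, str] | None = None,
) -> StratifiedCounts:
    """Accumulate per-symbol outcome counts over primary mapped alignments.

    Every FASTQ base contributes to ``total_in_fastq``; bases of reads with a
    primary alignment additionally contribute to ``total_in_mapped_reads`` and
    exactly one outcome. Secondary and supplementary alignments are skipped to
    avoid double-counting.
    """
    alignments = list(alignments)
    by_id = _index_reads(reads)
    counts = StratifiedCounts()
    for rec in reads:
        if rec.quality is None:
            raise ValueError(f"read {rec.read_id!r} has no quality string")
        for ch in rec.quality:
            counts.tally(ch).total_in_fastq += 1

    missing = sorted({a.read_id for a in alignments if a.read_id not in by_id})
    if missing:
        raise KeyError(f"SAM read ids absent from FASTQ: {', '.join(missing[:10])}")

    for aln in alignments:
        if not aln.is_primary_mapped:
            continue
        original = by_id[aln.read_id]
        for _, symbol, outcome in classify_alignment_bases(aln, original, reference):
            t = counts.tally(symbol)
            t.total_in_mapped_reads += 1
            if outcome is BaseOutcome.MATCHED:
                t.matched += 1
            elif outcome is BaseOutcome.MISMATCHED:
                t.mismatched += 1
            elif outcome is BaseOutcome.INSERTED:
                t.inserted += 1
            else:
                t.clipped += 1
        counts.deletions_total += aln.deleted_bases()
    counts.check_conservation()
    return counts


def mapped_fraction(counts: StratifiedCounts) -> dict[str, float]:
    """Per symbol: aligned bases (matched+mismatched+inserted) over all FASTQ
    bases of that symbol. Clipped bases count as unmapped."""
    return {
        s: t.aligned / t.total_in_fastq
        for s, t in counts.per_symbol.items()
        if t.total_in_fastq > 0
    }


def summarize(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[ReadRecord],
    reference: Mapping[str, str] | None = None,
    counts: StratifiedCounts | None = None,
) -> ReadSetSummary:
    """Read-set percentages: mapped fraction and match/sub/del/ins split."""
    if counts is None:
        counts = stratify(alignments, reads, reference)
    matched = sum(t.matched for t in counts.per_symbol.values())
    mismatched = sum(t.mismatched for t in counts.per_symbol.values())
    inserted = sum(t.inserted for t in counts.per_symbol.values())
    deleted = counts.deletions_total
    total_bp = sum(len(r) for r in reads)
    aligned = matched + mismatched + inserted
    columns = matched + mismatched + inserted + deleted
    pct = lambda num, den: round_half_up(100.0 * num / den, 2) if den else 0.0
    return ReadSetSummary(
        n_reads=len(reads),
        sum_bp=total_bp,
        mapped_pct=pct(aligned, total_bp),
        match_pct=pct(matched, columns),
        sub_pct=pct(mismatched, columns),
        del_pct=pct(deleted, columns),
        ins_pct=pct(inserted, columns),
    )
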
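"""Apply repeat intervals to a reference genome by N-substitution.

Repeat discovery itself (RepeatModeler/RepeatMasker style) is out of scope:
this module consumes BED3 intervals, which such tools can emit, and performs
the hard-masking step — every base inside the merged interval union becomes an
uppercase ``'N'`` — plus the bookkeeping: how many bases were masked, per
sequence and in total, and the masked percentage.

Bases that were already ``'N'`` before masking are counted in ``masked_bp``
(they are N in the output) but also reported separately as ``premasked_bp`` so
the two conventions can be reconciled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .formats_io import BedInterval, ReadRecord, read_fasta, write_fasta
from .util import round_half_up

logger = logging.getLogger(__name__)


def masking_percent(masked_bp: int, total_bp: int) -> float:
    """Masked percentage, half-up to two decimals (printed-report style)."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return round_half_up(100.0 * masked_bp / total_bp, 2)


@dataclass
class MaskingReport:
    """Masked/total base counts per sequence and overall."""

    per_sequence: dict[str, tuple[int, int]] = field(default_factory=dict)
    masked_bp_total: int = 0
    total_bp: int = 0
    premasked_bp: int = 0

    @property
    def masked_percent(self) -> float:
        return masking_percent(self.masked_bp_total, self.total_bp)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tmasked_bp\ttotal_bp\tmasked_percent\n")
            for chrom, (masked, total) in sorted(self.per_sequence.items()):
                fh.write(f"{chrom}\t{masked}\t{total}\t{masking_percent(masked, total):.2f}\n")
            fh.write(
                f"TOTAL\t{self.masked_bp_total}\t{self.total_bp}\t{self.masked_percent:.2f}\n"
            )


def merge_intervals(intervals: Iterable[BedInterval]) -> list[BedInterval]:
    """Union of intervals: per-chromosome sorted, overlaps and adjacencies merged."""
    by_chrom: dict[str, list[BedInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[BedInterval] = []
    for chrom in sorted(by_chrom):
        current_start = current_end = None
        for iv in sorted(by_chrom[chrom], key=lambda i: (i.start, i.end)):
            if current_start is None:
                current_start, current_end = iv.start, iv.end
            elif iv.start <= current_end:  # overlap or adjacency
                current_end = max(current_end, iv.end)
            else:
                merged.append(BedInterval(chrom, current_start, current_end))
                current_start, current_end = iv.start, iv.end
        if current_start is not None:
            merged.append(BedInterval(chrom, current_start, current_end))
    return merged


def mask_sequences(
    sequences: Sequence[ReadRecord], intervals: Iterable[BedInterval]
) -> tuple[list[ReadRecord], MaskingReport]:
    """Mask in memory; see :func:`mask_reference` for the file-level wrapper."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[BedInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    known = {rec.read_id for rec in sequences}
    for chrom in by_chrom:
        if chrom not in known:
            raise ValueError(f"BED interval references unknown sequence {chrom!r}")

    report = MaskingReport()
    masked_records: list[ReadRecord] = []
    for rec in sequences:
        seq = bytearray(rec.sequence, "ascii")
        length = len(seq)
        masked_here = 0
        for iv in by_chrom.get(rec.read_id, []):
            start, end = iv.start, iv.end
            if end > length:
                logger.warning(
                    "interval %s:%d-%d extends past sequence end (%d bp); clipped",
                    iv.chrom, iv.start, iv.end, length,
                )
                end = length
            if start >= length:
                continue
            report.premasked_bp += rec.sequence.count("N", start, end) + rec.sequence.count("n", start, end)
            seq[start:end] = b"N" * (end - start)
            masked_here += end - start
        report.per_sequence[rec.read_id] = (masked_here, length)
        report.masked_bp_total += masked_here
        report.total_bp += length
        masked_records.append(ReadRecord(rec.read_id, seq.decode("ascii")))
    return masked_records, report


def mask_reference(
    reference: str | Path,
    intervals: Iterable[BedInterval],
    out_path: str | Path,
) -> tuple[Path, MaskingReport]:
    """Read a FASTA reference, hard-mask the intervals, write unwrapped FASTA."""
    sequences = read_fasta(reference)
    masked, report = mask_sequences(sequences, intervals)
    write_fasta(masked, out_path)
    return Path(out_path), report
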
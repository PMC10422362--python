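"""Quality-aware long-read simulator with ground-truth alignments.

Generates a random reference and reads whose per-base quality symbols are
drawn from a configurable profile, with substitution / insertion / deletion
errors conditioned on each base's symbol. By default the substitution rate of
a base with symbol of Phred value Q is exactly the Phred expectation
``10^(-Q/10)`` (perfect calibration); a ``miscalibration_factor`` scales all
rates so that calibration-recovery can be tested against a known ground
truth. Unalignable flanks of geometric length are appended to both read ends
and labelled ``clipped``.

Every read is emitted together with a :class:`TruthAlignment` carrying the
per-base outcome labels and an ``=``/``X``-resolved CIGAR, so the evaluation
pipeline can be checked base-for-base with zero tolerance.

Errors are i.i.d. per base given the symbol — no homopolymer or k-mer context
effects — because the downstream analysis is symbol-marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pysam

from .formats_io import ReadRecord, reverse_complement
from .quality_models import phred_from_symbol, symbol_from_phred
from .stratified_eval import BaseOutcome, StratifiedCounts

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ErrorModel:
    """Symbol profile plus symbol-conditioned error rates.

    ``symbol_profile`` maps quality symbols to sampling probabilities (must sum
    to 1). Unless a custom ``calibration`` is given, a symbol with Phred value
    Q gets ``sub_rate = miscalibration_factor * 10^(-Q/10)`` and insertion /
    deletion rates that are fixed fractions of the substitution rate
    (defaults 0.5 each, mimicking the indel-heavy nanopore error profile).
    ``clip_flank_mean`` is the mean length of random unalignable sequence
    appended per read end.

    Deletions are applied at the profile-averaged deletion rate
    (:meth:`mean_deletion_rate`) rather than per drawn symbol: a deleted base
    carries no quality symbol, and conditioning the deletion decision on a
    drawn symbol would bias the emitted FASTQ symbol distribution away from
    ``symbol_profile``.
    """

    symbol_profile: dict[str, float]
    ins_fraction: float = 0.5
    del_fraction: float = 0.5
    miscalibration_factor: float = 1.0
    clip_flank_mean: float = 30.0
    calibration: Callable[[str], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        total = sum(self.symbol_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"symbol profile sums to {total}, not 1")
        if self.miscalibration_factor <= 0:
            raise ValueError("miscalibration_factor must be positive")
        if self.clip_flank_mean < 0:
            raise ValueError("clip_flank_mean must be non-negative")
        for symbol in self.symbol_profile:
            sub, ins, dele = self.rates(symbol)
            if not (0 <= sub < 1 and 0 <= ins < 1 and 0 <= dele < 1):
                raise ValueError(f"symbol {symbol!r}: rates outside [0,1)")
            if sub + ins + dele >= 1:
                raise ValueError(
                    f"symbol {symbol!r}: sub+ins+del = {sub + ins + dele:.3f} >= 1"
                )

    def rates(self, symbol: str) -> tuple[float, float, float]:
        """(substitution, insertion, deletion) rates for one symbol."""
        if self.calibration is not None:
            sub, ins, dele = self.calibration(symbol)
        else:
            err = phred_from_symbol(symbol).error_prob
            sub, ins, dele = err, self.ins_fraction * err, self.del_fraction * err
        f = self.miscalibration_factor
        return f * sub, f * ins, f * dele

    def mean_deletion_rate(self) -> float:
        """Deletion rate averaged over the symbol profile."""
        return sum(p * self.rates(s)[2] for s, p in self.symbol_profile.items())

    @classmethod
    def uniform_phred(cls, q_min: int = 5, q_max: int = 30, **kwargs) -> "ErrorModel":
        """Uniform symbol profile over Phred values ``q_min..q_max`` inclusive."""
        symbols = [symbol_from_phred(q) for q in range(q_min, q_max + 1)]
        prob = 1.0 / len(symbols)
        return cls(symbol_profile={s: prob for s in symbols}, **kwargs)


@dataclass(frozen=True)
class TruthAlignment:
    """Ground-truth alignment of one simulated read.

    ``per_base_outcome`` is in original read coordinates and covers every read
    base exactly once; ``cigar`` is stored in SAM (reference) orientation with
    ``=``/``X``-resolved operators.
    """

    read_id: str
    ref_start: int
    strand: str  # '+' or '-'
    per_base_outcome: tuple[tuple[int, str, BaseOutcome], ...]
    cigar: tuple[tuple[str, int], ...]

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def simulate_reference(length: int, gc: float = 0.5, seed: int = 0) -> ReadRecord:
    """Random reference sequence with the given GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0,1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    idx = rng.choice(4, size=length, p=probs)
    seq = "".join(_BASES[i] for i in idx)
    return ReadRecord(read_id="ref", sequence=seq)


def _rle(ops: Sequence[str]) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return tuple(out)


def simulate_reads(
    reference: ReadRecord,
    n: int,
    read_length: tuple[float, float],
    model: ErrorModel,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[TruthAlignment]]:
    """Simulate ``n`` reads from ``reference`` with truth alignments.

    Read core lengths (reference span) are normal(mean, sd), clipped to the
    reference; strands are chosen uniformly. Per reference base: the base is
    deleted with the profile-averaged deletion rate; otherwise a symbol is
    drawn from the profile and the base is substituted with that symbol's
    substitution rate; an insertion (fresh profile symbol, random base)
    follows with the insertion rate. Deterministic for a fixed seed.
    """
    mean_len, sd_len = read_length
    ref = reference.sequence.upper()
    ref_len = len(ref)
    if ref_len < 10:
        raise ValueError("reference too short")
    rng = np.random.default_rng(seed)

    symbols = sorted(model.symbol_profile)
    probs = np.array([model.symbol_profile[s] for s in symbols])
    probs = probs / probs.sum()
    rate_arr = np.array([model.rates(s) for s in symbols])  # (nsym, 3)
    sub_arr, ins_arr = rate_arr[:, 0], rate_arr[:, 1]
    mean_del = model.mean_deletion_rate()
    nsym = len(symbols)
    flank_p = 1.0 / (1.0 + model.clip_flank_mean) if model.clip_flank_mean > 0 else None

    reads: list[ReadRecord] = []
    truths: list[TruthAlignment] = []
    for i in range(n):
        span = int(round(rng.normal(mean_len, sd_len)))
        span = max(10, min(span, ref_len))
        start = int(rng.integers(0, ref_len - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"

        sym_idx = rng.choice(nsym, size=span, p=probs)
        u_del = rng.random(span)
        u_sub = rng.random(span)
        u_ins = rng.random(span)
        sub_off = rng.integers(1, 4, size=span)
        ins_sym_idx = rng.choice(nsym, size=span, p=probs)
        ins_base_idx = rng.integers(0, 4, size=span)

        core: list[tuple[str, str, BaseOutcome]] = []  # (base, symbol, outcome)
        ops: list[str] = []
        for j in range(span):
            si = sym_idx[j]
            if u_del[j] < mean_del:
                ops.append("D")
            else:
                ref_base = ref[start + j]
                if ref_base in _BASE_INDEX:
                    if u_sub[j] < sub_arr[si]:
                        base = _BASES[(_BASE_INDEX[ref_base] + sub_off[j]) % 4]
                        outcome = BaseOutcome.MISMATCHED
                    else:
                        base = ref_base
                        outcome = BaseOutcome.MATCHED
                else:  # reference 'N' column: any call is a mismatch
                    base = _BASES[ins_base_idx[j]]
                    outcome = BaseOutcome.MISMATCHED
                core.append((base, symbols[si], outcome))
                ops.append("=" if outcome is BaseOutcome.MATCHED else "X")
            if u_ins[j] < ins_arr[si]:
                core.append((
                    _BASES[ins_base_idx[j]],
                    symbols[ins_sym_idx[j]],
                    BaseOutcome.INSERTED,
                ))
                ops.append("I")

        def flank() -> list[tuple[str, str, BaseOutcome]]:
            if flank_p is None:
                return []
            ln = int(rng.geometric(flank_p)) - 1
            if ln == 0:
                return []
            bases = rng.integers(0, 4, size=ln)
            syms = rng.choice(nsym, size=ln, p=probs)
            return [
                (_BASES[b], symbols[s], BaseOutcome.CLIPPED)
                for b, s in zip(bases, syms)
            ]

        left, right = flank(), flank()

        if strand == "+":
            body = core
        else:
            body = [
                (reverse_complement(base), sym, outcome)
                for base, sym, outcome in reversed(core)
            ]
        read_triplets = left + body + right
        read_seq = "".join(t[0] for t in read_triplets)
        read_qual = "".join(t[1] for t in read_triplets)
        per_base = tuple(
            (pos, sym, outcome)
            for pos, (_, sym, outcome) in enumerate(read_triplets)
        )

        # CIGAR in SAM (reference) orientation: the stored sequence is the
        # reverse complement of the read on the minus strand, so the read's
        # right flank leads and the left flank trails.
        lead, trail = (left, right) if strand == "+" else (right, left)
        cigar_ops: list[tuple[str, int]] = []
        if lead:
            cigar_ops.append(("S", len(lead)))
        cigar_ops.extend(_rle(ops))
        if trail:
            cigar_ops.append(("S", len(trail)))

        read_id = f"read{i:05d}"
        reads.append(ReadRecord(read_id, read_seq, read_qual))
        truths.append(TruthAlignment(
            read_id=read_id,
            ref_start=start,
            strand=strand,
            per_base_outcome=per_base,
            cigar=tuple(cigar_ops),
        ))
    return reads, truths


def emit_truth_sam(
    truths: Sequence[TruthAlignment],
    reads: Sequence[ReadRecord],
    reference: ReadRecord,
    path: str | Path,
    provenance: str | None = None,
) -> None:
    """Write the truth alignments as a valid SAM file (pysam text writer)."""
    by_id = {r.read_id: r for r in reads}
    header: dict = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference.read_id, "LN": len(reference.sequence)}],
    }
    if provenance:
        header["CO"] = [provenance]
    cigar_code = {op: i for i, op in enumerate("MIDNSHP=XB")}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for truth in truths:
            read = by_id.get(truth.read_id)
            if read is None:
                raise ValueError(f"truth {truth.read_id!r} has no matching read")
            consumed = sum(n for op, n in truth.cigar if op in "MIS=X")
            if consumed != len(read.sequence):
                raise ValueError(
                    f"truth {truth.read_id!r}: CIGAR consumes {consumed} bases, "
                    f"read has {len(read.sequence)}"
                )
            a = pysam.AlignedSegment(out.header)
            a.query_name = truth.read_id
            a.flag = 16 if truth.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = truth.ref_start
            a.mapping_quality = 60
            a.cigartuples = [(cigar_code[op], n) for op, n in truth.cigar]
            if truth.strand == "-":
                a.query_sequence = reverse_complement(read.sequence)
                quals = [ord(c) - 33 for c in read.quality[::-1]]
            else:
                a.query_sequence = read.sequence
                quals = [ord(c) - 33 for c in read.quality]
            a.query_qualities = quals
            out.write(a)


def truth_counts(truths: Sequence[TruthAlignment]) -> StratifiedCounts:
    """Per-symbol outcome tallies straight from the truth labels (the oracle)."""
    counts = StratifiedCounts()
    for truth in truths:
        for _, symbol, outcome in truth.per_base_outcome:
            t = counts.tally(symbol)
            t.total_in_fastq += 1
            t.total_in_mapped_reads += 1
            if outcome is BaseOutcome.MATCHED:
                t.matched += 1
            elif outcome is BaseOutcome.MISMATCHED:
                t.mismatched += 1
            elif outcome is BaseOutcome.INSERTED:
                t.inserted += 1
            else:
                t.clipped += 1
        counts.deletions_total += sum(n for op, n in truth.cigar if op == "D")
    return counts
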
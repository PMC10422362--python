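"""Quality-invariance harness: does a downstream tool use FASTQ quality at all?

From one FASTQ three input variants are derived that share every read id and
every sequence byte and differ only in the quality information:

* ``real`` — the original FASTQ,
* ``fake`` — the same FASTQ with every quality symbol replaced by a constant
  (``'?'`` by default, i.e. Phred 30),
* ``none`` — a FASTA with the quality lines removed.

An arbitrary downstream command is run once per variant and the outputs are
compared pairwise. If all three outputs agree, the tool demonstrably ignores
the estimated per-base quality. Downstream tools are treated as opaque
command templates; verdicts are only meaningful for deterministic commands
(pass a fixed seed through the template if the tool supports one).
"""

from __future__ import annotations

import itertools
import logging
import shlex
import subprocess
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from Bio import SeqIO

from .formats_io import fake_quality, read_fastq, strip_to_fasta, write_fastq

logger = logging.getLogger(__name__)

VARIANT_LABELS = ("real", "fake", "none")


class HarnessError(RuntimeError):
    pass


@dataclass(frozen=True)
class VariantSet:
    fastq_real: Path
    fastq_fake: Path
    fasta: Path

    def path_for(self, label: str) -> Path:
        return {"real": self.fastq_real, "fake": self.fastq_fake, "none": self.fasta}[label]


@dataclass
class InvarianceReport:
    per_pair: dict[tuple[str, str], str] = field(default_factory=dict)  # 'identical'/'differs'
    detail: dict[tuple[str, str], str | None] = field(default_factory=dict)

    @property
    def overall_invariant(self) -> bool:
        return all(v == "identical" for v in self.per_pair.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_a\tvariant_b\tverdict\tdetail\n")
            for (a, b), verdict in sorted(self.per_pair.items()):
                fh.write(f"{a}\t{b}\t{verdict}\t{self.detail.get((a, b)) or ''}\n")
            fh.write(f"overall\t\t{'identical' if self.overall_invariant else 'differs'}\t\n")


def make_variants(fastq: str | Path, outdir: str | Path, symbol: str = "?") -> VariantSet:
    """Write the real/fake/none variants of ``fastq`` into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_fastq(fastq)
    stem = Path(fastq).stem
    real_path = outdir / f"{stem}.real.fastq"
    fake_path = outdir / f"{stem}.fake.fastq"
    fasta_path = outdir / f"{stem}.fasta"
    write_fastq(records, real_path)
    faked = fake_quality(records, symbol)
    write_fastq(faked, fake_path)
    strip_to_fasta(records, fasta_path)

    # Validate the identical-sequence invariant before handing the set out.
    fake_back = read_fastq(fake_path)
    fasta_back = [(r.id, str(r.seq)) for r in SeqIO.parse(str(fasta_path), "fasta")]
    ids_seqs = [(r.read_id, r.sequence) for r in records]
    if [(r.read_id, r.sequence) for r in fake_back] != ids_seqs or fasta_back != ids_seqs:
        raise HarnessError("variant files do not share identical ids/sequences")
    return VariantSet(real_path, fake_path, fasta_path)


# ---------------------------------------------------------------------------
# Output comparators
# ---------------------------------------------------------------------------

def _compare_bytes(a: Path, b: Path) -> str | None:
    if a.read_bytes() != b.read_bytes():
        return "byte content differs"
    return None


def _filtered_lines(path: Path, drop_prefixes: tuple[str, ...]) -> list[str]:
    return [
        ln for ln in path.read_text().splitlines()
        if not any(ln.startswith(p) for p in drop_prefixes)
    ]


def _first_diff(lines_a: list[str], lines_b: list[str]) -> str | None:
    for i, (la, lb) in enumerate(itertools.zip_longest(lines_a, lines_b)):
        if la != lb:
            return f"record {i}: {la!r} != {lb!r}"
    return None


def _compare_vcf(a: Path, b: Path) -> str | None:
    # '##' meta lines (dates, command lines) are ignored; records and the
    # '#CHROM' column header are compared.
    return _first_diff(_filtered_lines(a, ("##",)), _filtered_lines(b, ("##",)))


def _compare_tsv(a: Path, b: Path) -> str | None:
    return _first_diff(_filtered_lines(a, ("#",)), _filtered_lines(b, ("#",)))


def _compare_sam(a: Path, b: Path) -> str | None:
    return _first_diff(_filtered_lines(a, ("@PG",)), _filtered_lines(b, ("@PG",)))


def _compare_fasta(a: Path, b: Path) -> str | None:
    rec_a = [(r.id, str(r.seq)) for r in SeqIO.parse(str(a), "fasta")]
    rec_b = [(r.id, str(r.seq)) for r in SeqIO.parse(str(b), "fasta")]
    for i, (ra, rb) in enumerate(itertools.zip_longest(rec_a, rec_b)):
        if ra != rb:
            return f"record {i}: {ra!r} != {rb!r}"
    return None


COMPARATORS: dict[str, Callable[[Path, Path], str | None]] = {
    "bytes": _compare_bytes,
    "fasta_records": _compare_fasta,
    "vcf_records": _compare_vcf,
    "sam_records": _compare_sam,
    "tsv": _compare_tsv,
}


def run_and_compare(
    variants: VariantSet,
    command_template: str,
    comparator: str = "tsv",
    workdir: str | Path | None = None,
) -> InvarianceReport:
    """Run ``command_template`` on each variant and compare outputs pairwise.

    The template must contain ``{input}`` and may contain ``{output}``; without
    ``{output}`` the command's stdout is captured as its output. Verdicts are
    symmetric by construction (each unordered pair is compared once).
    """
    if "{input}" not in command_template:
        raise ValueError("command template must contain an {input} placeholder")
    if comparator not in COMPARATORS:
        raise ValueError(
            f"unknown comparator {comparator!r}; choose from {sorted(COMPARATORS)}"
        )
    workdir = Path(workdir) if workdir is not None else variants.fastq_real.parent
    workdir.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, Path] = {}
    for label in VARIANT_LABELS:
        out_path = workdir / f"invariance.{label}.out"
        cmd = command_template.format(input=variants.path_for(label), output=out_path)
        logger.info("running %s variant: %s", label, cmd)
        proc = subprocess.run(cmd, shell=True, capture_output=True)
        if proc.returncode != 0:
            raise HarnessError(
                f"{label} variant command exited {proc.returncode}: "
                f"{proc.stderr.decode(errors='replace')[-1000:]}"
            )
        if "{output}" not in command_template:
            out_path.write_bytes(proc.stdout)
        elif not out_path.exists():
            raise HarnessError(f"{label} variant produced no output file {out_path}")
        outputs[label] = out_path

    report = InvarianceReport()
    compare = COMPARATORS[comparator]
    for a, b in itertools.combinations(VARIANT_LABELS, 2):
        diff = compare(outputs[a], outputs[b])
        report.per_pair[(a, b)] = "identical" if diff is None else "differs"
        report.detail[(a, b)] = diff
    return report


def quality_agnostic_template() -> str:
    """A built-in toy downstream command that never reads quality lines."""
    return f'"{sys.executable}" -m qualstrat.toycmds count-reads {{input}}'


def quality_aware_template() -> str:
    """A built-in toy downstream command whose output depends on quality."""
    return f'"{sys.executable}" -m qualstrat.toycmds qual-sum {{input}}'
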
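"""Orchestration of the full workflow: mask -> map (or truth SAM) -> stratify.

The external mapper is optional passthrough only: tests and the simulator use
truth SAM files, so no aligner binary is required. All machine-readable
outputs are TSV with a ``#``-prefixed provenance header (tool version and a
hash of the configuration), and re-running on identical inputs yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .formats_io import read_bed, read_fasta, read_fastq, read_sam
from .reference_masking import mask_reference
from .stratified_eval import stratify, summarize, symbol_distribution

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Exactly one of ``sam`` (pre-computed alignments) or ``mapper_cmd`` (a shell
    template with ``{reference}``, ``{fastq}`` and ``{sam}`` placeholders, e.g.
    a minimap2 invocation with the ``map-ont`` preset) must be set.
    """

    fastq: str
    out_prefix: str
    sam: str | None = None
    mapper_cmd: str | None = None
    reference: str | None = None
    bed: str | None = None
    preset: str = "map-ont"
    log_level: str = "info"
    seed: int | None = None

    def validate(self) -> None:
        if (self.sam is None) == (self.mapper_cmd is None):
            raise ValueError("exactly one of sam / mapper_cmd must be set")
        if self.bed is not None and self.reference is None:
            raise ValueError("BED masking requires a reference")

    def digest(self) -> str:
        """Hash of the fields that determine the computed numbers (output
        location and verbosity excluded, so identical inputs hash alike)."""
        fields = {k: v for k, v in vars(self).items()
                  if k not in ("out_prefix", "log_level")}
        blob = repr(sorted(fields.items())).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key=value`` config file (one pair per line, '#' comments)."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" in values:
        values["seed"] = int(values["seed"])  # type: ignore[assignment]
    return PipelineConfig(**values)  # type: ignore[arg-type]


def _write_tsv(frame: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance + "\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run masking (optional), mapping (optional), and the stratified analysis.

    Returns a map of output names to paths: ``stratified``, ``summary``,
    ``distribution`` and, when a BED is given, ``masked_reference`` and
    ``mask_report``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level.upper())
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    provenance = f"# qualstrat {__version__} config={config.digest()}"
    outputs: dict[str, Path] = {}

    reference_path = config.reference
    if config.bed is not None:
        intervals = read_bed(config.bed)
        masked_path = Path(f"{prefix}.masked.fasta")
        _, report = mask_reference(config.reference, intervals, masked_path)
        report_path = Path(f"{prefix}.mask_report.tsv")
        report.to_tsv(report_path)
        outputs["masked_reference"] = masked_path
        outputs["mask_report"] = report_path
        reference_path = str(masked_path)
        logger.info(
            "masking: %d of %d bp (%.2f%%)",
            report.masked_bp_total, report.total_bp, report.masked_percent,
        )

    if config.mapper_cmd is not None:
        sam_path = Path(f"{prefix}.mapped.sam")
        cmd = config.mapper_cmd.format(
            reference=reference_path, fastq=config.fastq, sam=sam_path,
            preset=config.preset,
        )
        logger.info("mapping: %s", cmd)
        proc = subprocess.run(cmd, shell=True, capture_output=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"mapping stage failed (exit {proc.returncode}): "
                f"{proc.stderr.decode(errors='replace')[-1000:]}"
            )
        outputs["mapped_sam"] = sam_path
    else:
        sam_path = Path(config.sam)

    reads = read_fastq(config.fastq)
    alignments = read_sam(sam_path)
    logger.info("stratify stage: %d reads, %d alignment records",
                len(reads), len(alignments))
    reference_map = None
    if reference_path is not None:
        reference_map = {r.read_id: r.sequence for r in read_fasta(reference_path)}

    counts = stratify(alignments, reads, reference_map)
    summary = summarize(alignments, reads, reference_map, counts=counts)
    dist = symbol_distribution(reads)

    stratified_path = Path(f"{prefix}.stratified.tsv")
    summary_path = Path(f"{prefix}.summary.tsv")
    dist_path = Path(f"{prefix}.distribution.tsv")
    _write_tsv(counts.to_frame(), stratified_path, provenance)
    _write_tsv(summary.to_frame(), summary_path, provenance)
    _write_tsv(dist.to_frame(), dist_path, provenance)
    outputs["stratified"] = stratified_path
    outputs["summary"] = summary_path
    outputs["distribution"] = dist_path
    return outputs
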
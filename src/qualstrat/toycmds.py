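"""Tiny built-in downstream commands for exercising the invariance harness.

Run as ``python -m qualstrat.toycmds {count-reads|qual-sum} INPUT``. The input
may be FASTQ or FASTA (detected from the first byte). ``count-reads`` ignores
quality entirely; ``qual-sum`` sums quality ordinals (0 for FASTA), so its
output differs between the real/fake/none variants.
"""

from __future__ import annotations

import sys
from pathlib import Path


def _records(path: str) -> list[tuple[str, str, str | None]]:
    text = Path(path).read_text()
    if not text.strip():
        return []
    if text.lstrip().startswith(">"):
        records = []
        name, chunks = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks), None))
                name, chunks = line[1:].split()[0] if len(line) > 1 else "", []
            else:
                chunks.append(line.strip())
        if name is not None:
            records.append((name, "".join(chunks), None))
        return records
    lines = text.splitlines()
    return [
        (lines[i][1:].split()[0], lines[i + 1], lines[i + 3])
        for i in range(0, len(lines) - 3, 4)
    ]


def main(argv: list[str] | None = None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 2 or argv[0] not in ("count-reads", "qual-sum"):
        print("usage: python -m qualstrat.toycmds {count-reads|qual-sum} INPUT",
              file=sys.stderr)
        return 2
    mode, path = argv
    records = _records(path)
    if mode == "count-reads":
        print(len(records))
    else:
        total = sum(
            sum(ord(c) for c in qual) for _, _, qual in records if qual is not None
        )
        print(total)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
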
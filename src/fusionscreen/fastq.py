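"""Minimal FASTQ plumbing shared by the simulator and the screen.

Reads are (id, sequence) pairs; the screen ignores base qualities, so the
writer emits a constant placeholder quality and the reader drops qualities.
Gzipped files are handled transparently (by suffix on write, by content on
read via pysam).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pysam

PLACEHOLDER_QUALITY = "I"  # Phred+33 Q40


class Read(NamedTuple):
    id: str
    sequence: str


class SimulatedRead(NamedTuple):
    """A simulated read with its emission provenance (for oracle tracking)."""

    id: str
    sequence: str
    template_id: str
    start: int  # 0-based start on the template, forward strand
    is_revcomp: bool


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate (id, sequence) over a FASTQ or FASTQ.gz file."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield Read(entry.name, entry.sequence.upper())


def write_fastq(reads: Iterable, path: str | Path) -> int:
    """Write reads (anything with .id/.sequence or (id, seq) pairs) as FASTQ.

    A ``.gz`` suffix selects gzip output.  Returns the number of reads written.
    """
    path = Path(path)
    opener = (lambda p: gzip.open(p, "wt", compresslevel=1)) if path.suffix == ".gz" else (
        lambda p: open(p, "wt")
    )
    n = 0
    with opener(path) as out:
        for r in reads:
            rid, seq = (r.id, r.sequence) if hasattr(r, "sequence") else (r[0], r[1])
            out.write(f"@{rid}\n{seq}\n+\n{PLACEHOLDER_QUALITY * len(seq)}\n")
            n += 1
    return n
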
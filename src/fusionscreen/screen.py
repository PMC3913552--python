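"""The junction screen: anchor counting, junction-spanning reads, chimera
cross-checks, and positive/negative calls per sample and per cohort.

The procedure mirrors a targeted fusion search in raw FASTQ data:

1. count reads containing the donor anchor (last ``k`` bases of the donor
   exon before the putative break) and, per candidate acceptor exon, reads
   containing the acceptor anchor (its first ``k`` bases);
2. find junction-spanning reads — reads containing the full ``2k`` junction
   sequence, i.e. covering the breakpoint with ``k`` bases on each side;
3. cross-check the anchor read sets for chimeras: reads carrying both a
   donor and an acceptor anchor;
4. call the sample positive when junction-spanning evidence reaches the
   configured threshold (one read by default).

Matching is exact by default; a substitution tolerance and reverse-
complement search are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fastq import read_fastq
from .gene_models import (
    AnchorSet,
    FusionForm,
    anchor_set_from_forms,
    reverse_complement,
    _validate_dna,
)
from .matching import contains

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ScreenParams:
    """Screen configuration.

    max_mismatch is the substitution tolerance per anchor/junction match
    (0 = exact, the default); search_revcomp also searches each pattern's
    reverse complement, for unstranded libraries; min_junction_reads is the
    evidence threshold for a positive call.
    """

    k: int = 20
    max_mismatch: int = 0
    search_revcomp: bool = True
    min_junction_reads: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("anchor length k must be positive")
        if self.max_mismatch < 0 or self.max_mismatch >= self.k / 2:
            raise ValueError("max_mismatch must satisfy 0 <= max_mismatch < k/2")
        if self.min_junction_reads < 1:
            raise ValueError("min_junction_reads must be >= 1")


@dataclass
class ScreenResult:
    """Per-sample screen outcome."""

    sample_id: str
    donor_anchor_reads: int
    acceptor_anchor_reads: dict[int, int]
    junction_reads: dict[str, list[str]]  # form name -> read ids
    chimera_crosscheck: int
    call: str

    @property
    def total_junction_reads(self) -> int:
        return sum(len(v) for v in self.junction_reads.values())

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "donor_anchor_reads": self.donor_anchor_reads,
            "acceptor_anchor_reads": {str(k): v for k, v in self.acceptor_anchor_reads.items()},
            "junction_reads": self.junction_reads,
            "total_junction_reads": self.total_junction_reads,
            "chimera_crosscheck": self.chimera_crosscheck,
            "call": self.call,
        }


def _as_pairs(reads: Iterable) -> Iterable[tuple[str, str]]:
    for r in reads:
        if hasattr(r, "sequence"):
            yield r.id, r.sequence
        else:
            rid, seq = r
            yield rid, seq


def _patterns(pattern: str, params: ScreenParams) -> list[str]:
    pats = [pattern]
    if params.search_revcomp:
        rc = reverse_complement(pattern)
        if rc != pattern:
            pats.append(rc)
    return pats


def count_anchor_reads(
    reads: Iterable, anchor: str, params: ScreenParams | None = None
) -> tuple[int, set[str]]:
    """Count reads containing the anchor (or its reverse complement).

    Each read is counted at most once even if the anchor occurs at several
    positions or in both orientations.  Returns (count, read id set).
    """
    params = params or ScreenParams(k=len(anchor))
    anchor = _validate_dna(anchor, "anchor")
    pats = _patterns(anchor, params)
    hits: set[str] = set()
    for rid, seq in _as_pairs(reads):
        if any(contains(seq, p, params.max_mismatch) for p in pats):
            hits.add(rid)
    return len(hits), hits


def find_junction_reads(
    reads: Iterable, form: FusionForm, params: ScreenParams | None = None
) -> list[str]:
    """Ids of reads containing the full 2k junction sequence of ``form``."""
    params = params or ScreenParams(k=form.anchor_len)
    pats = _patterns(form.junction_sequence, params)
    out = []
    for rid, seq in _as_pairs(reads):
        if any(contains(seq, p, params.max_mismatch) for p in pats):
            out.append(rid)
    return out


def cross_check(
    donor_read_set: set[str], acceptor_read_sets: Mapping[int, set[str]]
) -> int:
    """Number of reads carrying both the donor anchor and >= 1 acceptor anchor."""
    if not acceptor_read_sets:
        return 0
    union = set().union(*acceptor_read_sets.values())
    return len(donor_read_set & union)


def classify_sample(result: ScreenResult, params: ScreenParams) -> str:
    """Positive iff total junction-spanning reads reach the threshold."""
    return (
        POSITIVE
        if result.total_junction_reads >= params.min_junction_reads
        else NEGATIVE
    )


def screen_sample(
    reads: Iterable,
    forms: Sequence[FusionForm],
    params: ScreenParams | None = None,
    sample_id: str = "sample",
    anchors: AnchorSet | None = None,
) -> ScreenResult:
    """Run the full screen (anchors, junctions, cross-check, call) on one sample."""
    if not forms:
        raise ValueError("no fusion forms to screen for")
    params = params or ScreenParams(k=forms[0].anchor_len)
    anchors = anchors or anchor_set_from_forms(forms)
    reads = list(_as_pairs(reads))

    _, donor_ids = count_anchor_reads(reads, anchors.donor_anchor, params)
    acceptor_ids = {
        exon: count_anchor_reads(reads, anchor, params)[1]
        for exon, anchor in anchors.acceptor_anchors.items()
    }
    junction = {f.name: find_junction_reads(reads, f, params) for f in forms}
    result = ScreenResult(
        sample_id=sample_id,
        donor_anchor_reads=len(donor_ids),
        acceptor_anchor_reads={e: len(s) for e, s in acceptor_ids.items()},
        junction_reads=junction,
        chimera_crosscheck=cross_check(donor_ids, acceptor_ids),
        call=NEGATIVE,
    )
    result.call = classify_sample(result, params)
    return result


@dataclass
class CohortReport:
    """Aggregated screen outcome over a cohort of samples."""

    n_samples: int
    n_positive: int
    results: list[ScreenResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_samples == 0

    def summary(self) -> str:
        return f"{self.n_positive}/{self.n_samples} samples fusion-positive"

    def anchor_count_table(self, forms: Sequence[FusionForm]) -> pd.DataFrame:
        """Cohort-total anchor counts, one row per (gene, exon) anchor."""
        donor_total = sum(r.donor_anchor_reads for r in self.results)
        rows = [
            {
                "gene": forms[0].donor_gene,
                "exon": f"Exon {forms[0].donor_exon}",
                "number_of_reads": donor_total,
            }
        ]
        for f in forms:
            rows.append(
                {
                    "gene": f.acceptor_gene,
                    "exon": f"Exon {f.acceptor_exon}",
                    "number_of_reads": sum(
                        r.acceptor_anchor_reads.get(f.acceptor_exon, 0)
                        for r in self.results
                    ),
                }
            )
        return pd.DataFrame(rows)

    def calls_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.results],
                "call": [r.call for r in self.results],
                "junction_reads": [r.total_junction_reads for r in self.results],
            }
        )

    def write(self, outdir: str | Path, forms: Sequence[FusionForm]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for r in self.results:
            (outdir / f"{r.sample_id}.screen.json").write_text(
                json.dumps(r.to_dict(), indent=2) + "\n"
            )
        self.anchor_count_table(forms).to_csv(
            outdir / "cohort_anchor_counts.tsv", sep="\t", index=False
        )
        self.calls_table().to_csv(outdir / "cohort_calls.tsv", sep="\t", index=False)


def screen_cohort(
    samples: Iterable[tuple[str, object]],
    forms: Sequence[FusionForm],
    params: ScreenParams | None = None,
) -> CohortReport:
    """Screen every sample and aggregate positive calls.

    ``samples`` yields (sample_id, source) where source is a FASTQ path or an
    in-memory read iterable.  An unreadable sample is recorded as a failure
    and the run continues.
    """
    params = params or (ScreenParams(k=forms[0].anchor_len) if forms else ScreenParams())
    anchors = anchor_set_from_forms(forms)
    report = CohortReport(n_samples=0, n_positive=0)
    for sample_id, source in samples:
        report.n_samples += 1
        try:
            if isinstance(source, (str, Path)):
                reads: Iterable = read_fastq(source)
            else:
                reads = source
            result = screen_sample(
                reads, forms, params, sample_id=sample_id, anchors=anchors
            )
        except (OSError, ValueError) as exc:
            report.failures[sample_id] = str(exc)
            continue
        report.results.append(result)
        if result.call == POSITIVE:
            report.n_positive += 1
    return report
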
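"""Which single structural rearrangement can create a given 5'->3' gene fusion.

A fusion transcript with gene A 5' of gene B requires a genomic
configuration in which A's 5' portion lies upstream of B's 3' portion in a
consistent transcriptional orientation.  Under a single-event model the
feasible event class is fully determined by the partners' relative position
and orientation on the chromosome arm:

* different chromosomes                                  -> translocation
* same orientation, 5' partner upstream of 3' partner    -> deletion
* same orientation, 5' partner downstream of 3' partner  -> tandem duplication
* opposite orientations                                  -> inversion

"Upstream" is read along the direction of transcription.  For two
same-orientation neighbours transcribed centromere->telomere with the 3'
partner proximal (the ESRRA–C11orf20 configuration, ESRRA distal and 5' in
the chimera), a simple deletion or inversion cannot produce the fusion;
only a tandem duplication — with one breakpoint in each gene's required
intron — places a copy of the distal gene's 5' end upstream of the proximal
gene's 3' end.

``simulate_rearrangement`` applies events to a toy chromosome of oriented
segments and serves as the exhaustive oracle for the classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

Segment = tuple[str, str]  # (label, "+" | "-") along the centromere->telomere axis


class RearrangementClass(str, Enum):
    DELETION = "deletion"
    INVERSION = "inversion"
    TANDEM_DUPLICATION = "tandem_duplication"
    TRANSLOCATION = "translocation"


TOWARD_TELOMERE = "toward_telomere"
TOWARD_CENTROMERE = "toward_centromere"


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position and transcriptional orientation on a chromosome arm.

    arm_position is distance from the centromere (smaller = more proximal);
    orientation is the direction of transcription along the
    centromere->telomere axis.
    """

    gene_symbol: str
    chromosome: str
    arm_position: float
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in (TOWARD_TELOMERE, TOWARD_CENTROMERE):
            raise ValueError(
                f"orientation must be {TOWARD_TELOMERE!r} or {TOWARD_CENTROMERE!r}"
            )


def feasible_single_events(
    five_prime: GeneLocus, three_prime: GeneLocus
) -> set[RearrangementClass]:
    """The single-event class able to fuse five_prime (5') to three_prime (3')."""
    if (
        five_prime.chromosome == three_prime.chromosome
        and five_prime.arm_position == three_prime.arm_position
    ):
        raise ValueError("loci must be distinct")
    if five_prime.chromosome != three_prime.chromosome:
        return {RearrangementClass.TRANSLOCATION}
    if five_prime.orientation != three_prime.orientation:
        return {RearrangementClass.INVERSION}
    if five_prime.orientation == TOWARD_TELOMERE:
        upstream = five_prime.arm_position < three_prime.arm_position
    else:
        upstream = five_prime.arm_position > three_prime.arm_position
    return (
        {RearrangementClass.DELETION}
        if upstream
        else {RearrangementClass.TANDEM_DUPLICATION}
    )


def excluded_single_events(
    five_prime: GeneLocus, three_prime: GeneLocus
) -> set[RearrangementClass]:
    return set(RearrangementClass) - feasible_single_events(five_prime, three_prime)


def simulate_rearrangement(
    chromosome: Sequence[Segment],
    event: RearrangementClass,
    breakpoints: tuple[int, int],
) -> list[Segment]:
    """Apply one event to an oriented-segment chromosome.

    Breakpoints (b1, b2) are cut positions between segments, 0-based, with
    0 <= b1 < b2 <= len(chromosome); the event acts on the slice [b1:b2].
    Deletion removes it, inversion reverses it and flips each segment's
    orientation, tandem duplication inserts a copy of it immediately after
    itself.
    """
    segs = [(str(l), o) for l, o in chromosome]
    for _, o in segs:
        if o not in ("+", "-"):
            raise ValueError("segment orientation must be '+' or '-'")
    b1, b2 = breakpoints
    if not (0 <= b1 < b2 <= len(segs)):
        raise ValueError(
            f"breakpoints must satisfy 0 <= b1 < b2 <= {len(segs)}, got {breakpoints}"
        )
    mid = segs[b1:b2]
    if event is RearrangementClass.DELETION:
        return segs[:b1] + segs[b2:]
    if event is RearrangementClass.INVERSION:
        flipped = [(l, "-" if o == "+" else "+") for l, o in reversed(mid)]
        return segs[:b1] + flipped + segs[b2:]
    if event is RearrangementClass.TANDEM_DUPLICATION:
        return segs[:b2] + mid + segs[b2:]
    raise ValueError(f"cannot simulate {event} on a single chromosome")


def fusion_adjacency_present(
    segments: Sequence[Segment], five_prime_label: str, three_prime_label: str
) -> bool:
    """True if the 5' partner's segment is read immediately before the 3'
    partner's segment in a consistent orientation (either both '+' in order,
    or both '-' in reverse reading order)."""
    for (l1, o1), (l2, o2) in zip(segments, segments[1:]):
        if l1 == five_prime_label and l2 == three_prime_label and o1 == o2 == "+":
            return True
        if l1 == three_prime_label and l2 == five_prime_label and o1 == o2 == "-":
            return True
    return False


def verdict_report(
    five_prime: GeneLocus, three_prime: GeneLocus, path: str | Path | None = None
) -> dict:
    """JSON-ready feasibility verdict with one-line rationales."""
    feasible = feasible_single_events(five_prime, three_prime)
    rationale = {
        RearrangementClass.DELETION: "removing the intervening segment joins the partners only if the 5' partner already lies upstream in transcriptional orientation",
        RearrangementClass.INVERSION: "an inversion flips orientation, so it can join partners only when their orientations oppose",
        RearrangementClass.TANDEM_DUPLICATION: "a duplication spanning from within the 3' partner through the 5' partner places a copy of the 5' end upstream of the 3' end",
        RearrangementClass.TRANSLOCATION: "partners on different chromosomes can only be joined by an interchromosomal exchange",
    }
    report = {
        "five_prime": vars(five_prime).copy(),
        "three_prime": vars(three_prime).copy(),
        "feasible": sorted(e.value for e in feasible),
        "excluded": sorted(e.value for e in set(RearrangementClass) - feasible),
        "rationale": {e.value: rationale[e] for e in feasible},
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report


# The published configuration: both genes on 11q transcribed
# centromere->telomere, C11orf20 proximal to ESRRA, ESRRA the 5' fusion partner.
ESRRA_LOCUS = GeneLocus("ESRRA", "11q13.1", arm_position=2.0, orientation=TOWARD_TELOMERE)
C11ORF20_LOCUS = GeneLocus("C11orf20", "11q13.1", arm_position=1.0, orientation=TOWARD_TELOMERE)
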
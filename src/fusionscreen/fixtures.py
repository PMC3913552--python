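"""Default synthetic gene models for the ESRRA–C11orf20 screen.

The real RefSeq transcripts (NM_004451.4 for ESRRA, NM_001039496.1 for
C11orf20) are not redistributed here and their exon boundaries are not
printed in the screening design this package implements, so the shipped
default gene models are *synthetic*: seeded uniform-random sequences with
documented, arbitrary exon spans, into which the four published primer
sequences are written at their printed transcript coordinates (240–261 and
290–312 on the donor; 597–622 and 681–698, reverse-complemented, on the
acceptor).  The exon spans are chosen so that, exactly as in the real
design, both forward primers fall inside donor exon 2 and both reverse
primer sites inside acceptor exon 5, and all three candidate fusion forms
(donor exon 2 joined to acceptor exon 3, 4 or 5) retain every primer site.

Real transcript models can be substituted at any time via
``gene_models.read_transcripts``.
"""

from __future__ import annotations

import numpy as np

from .gene_models import FusionForm, TranscriptModel, build_fusion_forms, reverse_complement
from .insilico_pcr import F1_REV, G1P1_FWD, G1P2_FWD, REV_PAIR3
from .simulate import make_transcript

DONOR_EXON = 2
ACCEPTOR_EXONS = (3, 4, 5)

# documented, arbitrary exon spans (1-based inclusive transcript coordinates)
DONOR_EXON_LENGTHS = (200, 200, 600)  # exon 2 spans 201-400
ACCEPTOR_EXON_LENGTHS = (120, 140, 140, 160, 200, 640)  # exon 5 spans 561-760

DEFAULT_FIXTURE_SEED = 20140204


def _splice(sequence: str, start_1based: int, insert: str) -> str:
    i = start_1based - 1
    return sequence[:i] + insert + sequence[i + len(insert) :]


def default_gene_models(seed: int = DEFAULT_FIXTURE_SEED) -> tuple[TranscriptModel, TranscriptModel]:
    """Synthetic donor (ESRRA-like) and acceptor (C11orf20-like) transcripts."""
    rng = np.random.default_rng(seed)
    donor_seed, acceptor_seed = rng.integers(0, 2**31 - 1, size=2)
    donor = make_transcript(
        int(donor_seed),
        sum(DONOR_EXON_LENGTHS),
        DONOR_EXON_LENGTHS,
        gene_symbol="ESRRA",
        accession="SYN_ESRRA.1",
    )
    acceptor = make_transcript(
        int(acceptor_seed),
        sum(ACCEPTOR_EXON_LENGTHS),
        ACCEPTOR_EXON_LENGTHS,
        gene_symbol="C11orf20",
        accession="SYN_C11orf20.1",
    )
    donor_seq = donor.sequence
    for primer in (G1P1_FWD, G1P2_FWD):
        donor_seq = _splice(donor_seq, primer.declared_span[0], primer.sequence)
    acceptor_seq = acceptor.sequence
    for primer in (F1_REV, REV_PAIR3):
        acceptor_seq = _splice(
            acceptor_seq, primer.declared_span[0], reverse_complement(primer.sequence)
        )
    donor = TranscriptModel(donor.gene_symbol, donor.accession, donor_seq, donor.exons)
    acceptor = TranscriptModel(
        acceptor.gene_symbol, acceptor.accession, acceptor_seq, acceptor.exons
    )
    return donor, acceptor


def default_fusion_forms(
    seed: int = DEFAULT_FIXTURE_SEED, k: int = 20
) -> tuple[TranscriptModel, TranscriptModel, list[FusionForm]]:
    """Fixture models plus the three candidate fusion forms (exon 2 | exon 3/4/5)."""
    donor, acceptor = default_gene_models(seed)
    forms = build_fusion_forms(donor, DONOR_EXON, acceptor, list(ACCEPTOR_EXONS), k=k)
    return donor, acceptor, forms
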
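"""In-silico nested RT-PCR: primer-site matching and amplicon prediction.

PCR is modelled as site matching plus product enumeration — no thermal
cycling, efficiency or quantity.  A forward primer primes at sense-strand
sites where it matches the template; a reverse primer (given 5'->3') primes
where its reverse complement appears on the sense strand.  A product forms
for every (forward site upstream, reverse site downstream) pair whose length
falls within configured limits.  Nested PCR reruns an inner primer pair on
every first-round product.

Primer 3'-end anchoring is the specificity proxy: the 3'-terminal bases of
a primer must match exactly for extension, regardless of the overall
mismatch tolerance.

The default primer set is the published nested design for the
ESRRA–C11orf20 screen: outer pair G1P1-FWD / REV_pair3, inner (nested)
pair G1P2-FWD / F1-REV, with their printed transcript spans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.constants import Avogadro

from .gene_models import TranscriptModel, _validate_dna, reverse_complement
from .matching import match_positions


@dataclass(frozen=True)
class Primer:
    """A PCR primer, sequence written 5'->3'.

    declared_span, when present, is the primer's printed footprint on its
    source transcript in 1-based inclusive coordinates and must be exactly
    as long as the sequence.
    """

    name: str
    sequence: str
    declared_span: tuple[int, int] | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_dna(self.sequence, "primer"))
        if self.declared_span is not None:
            start, end = self.declared_span
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"{self.name}: declared span {start}-{end} does not match "
                    f"primer length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PcrParams:
    max_mismatch: int = 0
    three_prime_exact: int = 3  # 3'-terminal bases requiring exact match
    max_product_len: int = 5000
    min_product_len: int | None = None  # default: sum of primer lengths

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.three_prime_exact < 0:
            raise ValueError("tolerances must be nonnegative")


@dataclass(frozen=True)
class Amplicon:
    """A predicted product on a template's sense strand (1-based inclusive)."""

    template_id: str
    start: int
    end: int
    sequence: str
    fwd_primer: str = ""
    rev_primer: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {
            "template_id": self.template_id,
            "start": self.start,
            "end": self.end,
            "length": self.length,
            "sequence": self.sequence,
            "fwd_primer": self.fwd_primer,
            "rev_primer": self.rev_primer,
        }


@dataclass(frozen=True)
class NestedAmplicon:
    """A second-round product located within a first-round product."""

    amplicon: Amplicon  # coordinates relative to the outer amplicon
    outer_index: int
    template_start: int  # coordinates on the original template
    template_end: int


def primer_span(start: int, primer_len: int) -> int:
    """End coordinate (1-based inclusive) of a primer starting at ``start``."""
    if start < 1 or primer_len < 1:
        raise ValueError("start and primer_len must be >= 1")
    return start + primer_len - 1


def find_primer_sites(
    template: str, primer: Primer, params: PcrParams | None = None
) -> list[tuple[int, str]]:
    """Priming sites as (1-based position, strand) on the template.

    '+' sites: the primer matches the sense strand left-to-right (position
    is the site of the primer's 5' base).  '-' sites: the primer anneals to
    the sense strand, i.e. its reverse complement occurs there (position is
    the leftmost template base of the site, which faces the primer's 3'
    end).  In both orientations the primer's 3'-terminal
    ``three_prime_exact`` bases must match exactly.
    """
    params = params or PcrParams()
    template = _validate_dna(template, "template")
    if params.three_prime_exact > len(primer):
        raise ValueError("three_prime_exact exceeds primer length")
    t3 = params.three_prime_exact
    sites: list[tuple[int, str]] = []
    for pos in match_positions(template, primer.sequence, params.max_mismatch):
        if t3 == 0 or template[pos + len(primer) - t3 : pos + len(primer)] == primer.sequence[-t3:]:
            sites.append((pos + 1, "+"))
    rc = reverse_complement(primer.sequence)
    for pos in match_positions(template, rc, params.max_mismatch):
        # primer's 3' end maps to the leftmost bases of the rc occurrence
        if t3 == 0 or template[pos : pos + t3] == rc[:t3]:
            sites.append((pos + 1, "-"))
    return sorted(sites)


def predict_amplicons(
    template: str,
    fwd: Primer,
    rev: Primer,
    params: PcrParams | None = None,
    template_id: str = "template",
) -> list[Amplicon]:
    """All products with a sense forward site upstream of an antisense
    reverse site, within the configured length window."""
    params = params or PcrParams()
    template = _validate_dna(template, "template")
    min_len = (
        params.min_product_len
        if params.min_product_len is not None
        else len(fwd) + len(rev)
    )
    fwd_sites = [p for p, s in find_primer_sites(template, fwd, params) if s == "+"]
    rev_sites = [p for p, s in find_primer_sites(template, rev, params) if s == "-"]
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev) - 1
            length = end - f + 1
            if f <= r and min_len <= length <= params.max_product_len:
                out.append(
                    Amplicon(
                        template_id=template_id,
                        start=f,
                        end=end,
                        sequence=template[f - 1 : end],
                        fwd_primer=fwd.name,
                        rev_primer=rev.name,
                    )
                )
    return sorted(out, key=lambda a: (a.start, a.end))


def nested_pcr(
    template: str,
    outer: tuple[Primer, Primer],
    inner: tuple[Primer, Primer],
    params: PcrParams | None = None,
    template_id: str = "template",
) -> tuple[list[Amplicon], list[NestedAmplicon]]:
    """Two-round PCR: the inner pair is applied to each first-round product.

    Nested products carry coordinates relative to their outer amplicon and
    to the original template.
    """
    params = params or PcrParams()
    outer_amps = predict_amplicons(template, *outer, params, template_id=template_id)
    nested: list[NestedAmplicon] = []
    for i, amp in enumerate(outer_amps):
        for sub in predict_amplicons(
            amp.sequence, *inner, params, template_id=f"{template_id}|outer{i}"
        ):
            nested.append(
                NestedAmplicon(
                    amplicon=sub,
                    outer_index=i,
                    template_start=amp.start + sub.start - 1,
                    template_end=amp.start + sub.end - 1,
                )
            )
    return outer_amps, nested


_MEAN_BP_MASS_G_PER_MOL = 650.0  # average mass of one double-stranded base pair


def copies_from_mass(mass_fg: float, template_len_bp: int) -> float:
    """Copy number of a double-stranded template from its mass in femtograms."""
    if mass_fg < 0:
        raise ValueError("mass must be >= 0")
    if template_len_bp <= 0:
        raise ValueError("template length must be positive")
    grams = mass_fg * 1e-15
    return grams * Avogadro / (template_len_bp * _MEAN_BP_MASS_G_PER_MOL)


def plasmid_control(
    donor: TranscriptModel,
    acceptor: TranscriptModel,
    donor_exon: int = 2,
    acceptor_exon: int = 5,
    backbone_pad: int = 200,
    seed: int = 0,
) -> str:
    """Synthetic positive-control insert: donor exon + acceptor exon, with
    random backbone padding on each side (the real construct's backbone and
    size are not modelled)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    pad1 = bases[rng.integers(0, 4, size=backbone_pad)].tobytes().decode()
    pad2 = bases[rng.integers(0, 4, size=backbone_pad)].tobytes().decode()
    return (
        pad1
        + donor.exon_sequence(donor_exon)
        + acceptor.exon_sequence(acceptor_exon)
        + pad2
    )


# Published nested RT-PCR design for the ESRRA–C11orf20 screen.  Spans are
# 1-based inclusive transcript coordinates on NM_004451.4 (ESRRA) and
# NM_001039496.1 (C11orf20); reverse primers are written 5'->3' on the
# antisense strand, so their spans locate the reverse complement on the
# transcript.
G1P1_FWD = Primer("G1P1-FWD", "GGCATTGAGCCTCTCTACATCA", (240, 261), gene="ESRRA")
REV_PAIR3 = Primer("REV_pair3", "GGGTCAGGCTTGGGTCTG", (681, 698), gene="C11orf20")
G1P2_FWD = Primer("G1P2-FWD", "AAAGGGTTCCTCGGAGACAGAGA", (290, 312), gene="ESRRA")
F1_REV = Primer("F1-REV", "TAATTCACGTACAGCCTCTTGCTCCG", (597, 622), gene="C11orf20")

DEFAULT_OUTER_PAIR = (G1P1_FWD, REV_PAIR3)
DEFAULT_INNER_PAIR = (G1P2_FWD, F1_REV)
DEFAULT_PRIMERS = [G1P1_FWD, REV_PAIR3, G1P2_FWD, F1_REV]


def read_primers(path: str | Path) -> list[Primer]:
    """Load primers from a TSV with columns (name, sequence[, start, end, gene])."""
    table = pd.read_csv(path, sep="\t")
    if not {"name", "sequence"} <= set(table.columns):
        raise ValueError("primer table must have columns (name, sequence)")
    primers = []
    for row in table.to_dict("records"):
        span = None
        if pd.notna(row.get("start")) and pd.notna(row.get("end")):
            span = (int(row["start"]), int(row["end"]))
        gene = str(row["gene"]) if pd.notna(row.get("gene")) else None
        primers.append(Primer(str(row["name"]), str(row["sequence"]), span, gene))
    return primers


def amplicon_report(
    outer: Sequence[Amplicon],
    nested: Sequence[NestedAmplicon],
    path: str | Path | None = None,
) -> dict:
    report = {
        "n_outer": len(outer),
        "n_nested": len(nested),
        "outer": [a.to_dict() for a in outer],
        "nested": [
            {
                **n.amplicon.to_dict(),
                "outer_index": n.outer_index,
                "template_start": n.template_start,
                "template_end": n.template_end,
            }
            for n in nested
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report
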
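"""Transcript models and candidate fusion-junction construction.

A fusion transcript joining a 5' (donor) gene to a 3' (acceptor) gene has a
single breakpoint: the donor contributes everything up to the end of one of
its exons, the acceptor everything from the start of one of its exons.  A
read screen for such a fusion needs, per candidate junction, two fixed-length
*anchors* — the last ``k`` bases of the donor exon and the first ``k`` bases
of the acceptor exon — and their concatenation, the ``2k``-long *junction
sequence* that only a junction-spanning read can contain.

Coordinates are 1-based inclusive transcript coordinates throughout, so
printed primer/exon spans can be asserted verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    s = seq.upper()
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise ValueError(f"non-DNA characters in {what}: {bad}")
    return s


@dataclass(frozen=True)
class Exon:
    """One exon in 1-based inclusive transcript coordinates."""

    number: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"exon number must be positive, got {self.number}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid exon span {self.start}-{self.end} (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's sequence plus its ordered exon structure.

    Invariants enforced on construction: exons are contiguous and
    non-overlapping, the first exon starts at 1, the last ends at the
    sequence length, and exon numbers strictly increase.
    """

    gene_symbol: str
    accession: str
    sequence: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_dna(self.sequence))
        exons = tuple(
            e if isinstance(e, Exon) else Exon(*e) for e in self.exons
        )
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.accession}: transcript must have >= 1 exon")
        if exons[0].start != 1:
            raise ValueError(f"{self.accession}: first exon must start at 1")
        if exons[-1].end != len(self.sequence):
            raise ValueError(
                f"{self.accession}: last exon ends at {exons[-1].end}, "
                f"sequence length is {len(self.sequence)}"
            )
        for prev, cur in zip(exons, exons[1:]):
            if cur.number <= prev.number:
                raise ValueError(f"{self.accession}: exon numbers must increase")
            if cur.start != prev.end + 1:
                raise ValueError(
                    f"{self.accession}: exons must be contiguous "
                    f"({prev.end} -> {cur.start})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def exon(self, number: int) -> Exon:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"{self.accession}: no exon {number}")

    def exon_sequence(self, number: int) -> str:
        e = self.exon(number)
        return self.sequence[e.start - 1 : e.end]


@dataclass(frozen=True)
class FusionForm:
    """One candidate junction: donor exon suffix joined to acceptor exon prefix."""

    donor_gene: str
    donor_exon: int
    acceptor_gene: str
    acceptor_exon: int
    anchor_len: int
    donor_anchor: str
    acceptor_anchor: str

    def __post_init__(self) -> None:
        if self.anchor_len < 1:
            raise ValueError("anchor_len must be positive")
        for name in ("donor_anchor", "acceptor_anchor"):
            anchor = _validate_dna(getattr(self, name), name)
            if len(anchor) != self.anchor_len:
                raise ValueError(
                    f"{name} has length {len(anchor)}, expected {self.anchor_len}"
                )
            object.__setattr__(self, name, anchor)

    @property
    def junction_sequence(self) -> str:
        return self.donor_anchor + self.acceptor_anchor

    @property
    def name(self) -> str:
        return (
            f"{self.donor_gene}_exon{self.donor_exon}|"
            f"{self.acceptor_gene}_exon{self.acceptor_exon}"
        )

    def to_dict(self) -> dict:
        return {
            "donor_gene": self.donor_gene,
            "donor_exon": self.donor_exon,
            "acceptor_gene": self.acceptor_gene,
            "acceptor_exon": self.acceptor_exon,
            "anchor_len": self.anchor_len,
            "donor_anchor": self.donor_anchor,
            "acceptor_anchor": self.acceptor_anchor,
            "junction_sequence": self.junction_sequence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FusionForm":
        return cls(
            donor_gene=d["donor_gene"],
            donor_exon=int(d["donor_exon"]),
            acceptor_gene=d["acceptor_gene"],
            acceptor_exon=int(d["acceptor_exon"]),
            anchor_len=int(d["anchor_len"]),
            donor_anchor=d["donor_anchor"],
            acceptor_anchor=d["acceptor_anchor"],
        )


@dataclass(frozen=True)
class AnchorSet:
    """The donor anchor plus one acceptor anchor per candidate acceptor exon."""

    donor_anchor: str
    acceptor_anchors: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.donor_anchor)
        object.__setattr__(self, "donor_anchor", _validate_dna(self.donor_anchor))
        fixed = {}
        for exon, anchor in self.acceptor_anchors.items():
            a = _validate_dna(anchor, f"acceptor anchor (exon {exon})")
            if len(a) != k:
                raise ValueError("all anchors must have equal length")
            fixed[int(exon)] = a
        object.__setattr__(self, "acceptor_anchors", fixed)

    @property
    def k(self) -> int:
        return len(self.donor_anchor)


DEFAULT_ANCHOR_LEN = 20


def extract_donor_anchor(t: TranscriptModel, exon_number: int, k: int = DEFAULT_ANCHOR_LEN) -> str:
    """Last ``k`` bases of the named exon — the donor-side breakpoint anchor."""
    if k < 1:
        raise ValueError("anchor length k must be >= 1")
    exon_seq = t.exon_sequence(exon_number)
    if k > len(exon_seq):
        raise ValueError(
            f"anchor length {k} exceeds exon {exon_number} length {len(exon_seq)} "
            f"in {t.accession} (misconfigured gene model?)"
        )
    return exon_seq[-k:]


def extract_acceptor_anchor(t: TranscriptModel, exon_number: int, k: int = DEFAULT_ANCHOR_LEN) -> str:
    """First ``k`` bases of the named exon — the acceptor-side breakpoint anchor."""
    if k < 1:
        raise ValueError("anchor length k must be >= 1")
    exon_seq = t.exon_sequence(exon_number)
    if k > len(exon_seq):
        raise ValueError(
            f"anchor length {k} exceeds exon {exon_number} length {len(exon_seq)} "
            f"in {t.accession} (misconfigured gene model?)"
        )
    return exon_seq[:k]


def build_fusion_forms(
    donor: TranscriptModel,
    donor_exon: int,
    acceptor: TranscriptModel,
    acceptor_exons: Sequence[int],
    k: int = DEFAULT_ANCHOR_LEN,
) -> list[FusionForm]:
    """One FusionForm per acceptor exon, in the given order.

    Each form's junction sequence is the donor-exon suffix anchor followed by
    the acceptor-exon prefix anchor (length ``2k``).
    """
    if not donor.exons:
        raise ValueError("donor model has no exons")
    donor_anchor = extract_donor_anchor(donor, donor_exon, k)
    forms = []
    for ae in acceptor_exons:
        forms.append(
            FusionForm(
                donor_gene=donor.gene_symbol,
                donor_exon=donor_exon,
                acceptor_gene=acceptor.gene_symbol,
                acceptor_exon=ae,
                anchor_len=k,
                donor_anchor=donor_anchor,
                acceptor_anchor=extract_acceptor_anchor(acceptor, ae, k),
            )
        )
    return forms


def anchor_set_from_forms(forms: Sequence[FusionForm]) -> AnchorSet:
    """Collapse fusion forms sharing one donor anchor into an AnchorSet."""
    if not forms:
        raise ValueError("no fusion forms given")
    donor_anchors = {f.donor_anchor for f in forms}
    if len(donor_anchors) != 1:
        raise ValueError("fusion forms do not share a single donor anchor")
    return AnchorSet(
        donor_anchor=forms[0].donor_anchor,
        acceptor_anchors={f.acceptor_exon: f.acceptor_anchor for f in forms},
    )


# ---------------------------------------------------------------------------
# I/O: FASTA sequences, TSV gene-model tables, JSON fusion-form lists
# ---------------------------------------------------------------------------

def read_transcripts(fasta_path: str | Path, table_path: str | Path) -> dict[str, TranscriptModel]:
    """Load transcript models from a FASTA file plus a gene-model TSV.

    The TSV has columns (gene_symbol, accession, exon_number, start, end),
    one row per exon; FASTA record ids must equal the accession.  Soft-masked
    (lowercase) FASTA sequence is accepted and uppercased.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(table_path, sep="\t")
    required = {"gene_symbol", "accession", "exon_number", "start", "end"}
    if not required <= set(table.columns):
        raise ValueError(f"gene-model table must have columns {sorted(required)}")
    models: dict[str, TranscriptModel] = {}
    for acc, rows in table.groupby("accession", sort=False):
        if acc not in seqs:
            raise ValueError(f"accession {acc} in table but not in FASTA")
        rows = rows.sort_values("exon_number")
        models[str(acc)] = TranscriptModel(
            gene_symbol=str(rows["gene_symbol"].iloc[0]),
            accession=str(acc),
            sequence=seqs[str(acc)],
            exons=tuple(
                Exon(int(r.exon_number), int(r.start), int(r.end))
                for r in rows.itertuples()
            ),
        )
    return models


def write_transcripts(
    models: Iterable[TranscriptModel], fasta_path: str | Path, table_path: str | Path
) -> None:
    models = list(models)
    records = [
        SeqRecord(Seq(m.sequence), id=m.accession, description=m.gene_symbol)
        for m in models
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "gene_symbol": m.gene_symbol,
            "accession": m.accession,
            "exon_number": e.number,
            "start": e.start,
            "end": e.end,
        }
        for m in models
        for e in m.exons
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def forms_to_json(forms: Sequence[FusionForm], path: str | Path | None = None) -> str:
    text = json.dumps([f.to_dict() for f in forms], indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def forms_from_json(source: str | Path) -> list[FusionForm]:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    return [FusionForm.from_dict(d) for d in json.loads(text)]
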
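"""Seeded synthetic transcripts, fusion spike-ins, reads, and cohorts.

The generator emulates the statistical structure a targeted fusion screen
assumes: two neighbouring same-orientation genes, a donor-exon-2 |
acceptor-exon-3/4/5 junction model, strongly asymmetric expression (the
donor gene far more expressed than the acceptor, as in the motivating
read counts of 2,705 donor-anchor vs ~50-60 acceptor-anchor reads), and
cohorts whose fusion prevalence is 0% or ~15%.  Per-sample read counts are
a desk-scale stand-in for the tens of millions of reads of a real
sequencing run; defaults are 20,000 reads of 100 bp.

Everything is deterministic under a seed: the same seed yields byte-identical
FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fastq import SimulatedRead, write_fastq
from .gene_models import Exon, FusionForm, TranscriptModel, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one sample's read simulation.

    expression_weights maps template id -> nonnegative weight; weights are
    normalised on construction.  read_len must not exceed the shortest
    template (validated at simulation time, when templates are known).
    """

    seed: int
    n_reads: int
    expression_weights: Mapping[str, float]
    read_len: int = 100
    error_rate: float = 0.0
    orient_prob: float = 0.5
    paired: bool = False
    fragment_len: int = 300

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be nonnegative")
        if self.read_len < 1:
            raise ValueError("read_len must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.orient_prob <= 1.0):
            raise ValueError("orient_prob must be in [0, 1]")
        total = float(sum(self.expression_weights.values()))
        if total <= 0 or any(w < 0 for w in self.expression_weights.values()):
            raise ValueError("expression weights must be nonnegative, sum > 0")
        norm = {k: float(v) / total for k, v in self.expression_weights.items()}
        object.__setattr__(self, "expression_weights", norm)
        if self.paired and self.fragment_len < self.read_len:
            raise ValueError("fragment_len must be >= read_len in paired mode")


@dataclass(frozen=True)
class SampleSpec:
    """Fusion status of one synthetic sample."""

    sample_id: str
    fusion_present: bool
    fusion_form: int = 0  # index into the FusionForm list
    fusion_weight: float = 0.0  # fraction of expression given to the fusion

    def __post_init__(self) -> None:
        if self.fusion_present != (self.fusion_weight > 0):
            raise ValueError("fusion_weight must be > 0 iff fusion_present")


@dataclass(frozen=True)
class CohortSpec:
    """A seeded cohort: size, fusion prevalence, and a per-sample template.

    The number of fusion-positive samples is round(prevalence * n_samples),
    and which samples are positive is decided deterministically from the
    master seed.
    """

    n_samples: int
    prevalence: float
    params: SimParams
    master_seed: int
    fusion_weight: float = 0.2

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 < self.fusion_weight < 1.0):
            raise ValueError("fusion_weight must be in (0, 1)")

    @property
    def n_positive(self) -> int:
        # round-half-even would under-count 10/67; use arithmetic rounding
        return int(np.floor(self.prevalence * self.n_samples + 0.5))


def make_transcript(
    seed: int,
    length: int,
    exon_lengths: Sequence[int],
    gene_symbol: str = "GENE",
    accession: str | None = None,
) -> TranscriptModel:
    """Uniform-random DNA transcript of the given length and exon structure."""
    if sum(exon_lengths) != length:
        raise ValueError(
            f"exon lengths sum to {sum(exon_lengths)}, expected {length}"
        )
    if any(l < 1 for l in exon_lengths):
        raise ValueError("exon lengths must be positive")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    exons, pos = [], 1
    for i, l in enumerate(exon_lengths, start=1):
        exons.append(Exon(i, pos, pos + l - 1))
        pos += l
    return TranscriptModel(
        gene_symbol=gene_symbol,
        accession=accession or f"SYN_{gene_symbol}.{seed}",
        sequence=seq,
        exons=tuple(exons),
    )


def make_fusion_transcript(
    donor: TranscriptModel,
    donor_exon: int,
    acceptor: TranscriptModel,
    acceptor_exon: int,
) -> str:
    """Donor sequence through the end of donor_exon, then acceptor sequence
    from the start of acceptor_exon to its 3' end."""
    d = donor.exon(donor_exon)
    a = acceptor.exon(acceptor_exon)
    return donor.sequence[: d.end] + acceptor.sequence[a.start - 1 :]


def simulate_reads(
    templates: Mapping[str, str],
    params: SimParams,
    read_prefix: str = "read",
) -> list[SimulatedRead]:
    """Draw exactly n_reads reads of length read_len from weighted templates.

    Per read: template chosen by expression weight, start uniform over valid
    starts, each base substituted independently with error_rate, and the read
    reverse-complemented with probability orient_prob.  Deterministic under
    params.seed.  In paired mode two reads (mates) are emitted per fragment;
    mates share a fragment but are returned as independent reads.
    """
    ids = sorted(params.expression_weights)
    missing = [t for t in ids if t not in templates]
    if missing:
        raise ValueError(f"weights name templates not supplied: {missing}")
    weights = np.array([params.expression_weights[t] for t in ids])
    R = params.read_len
    for t in ids:
        if weights[ids.index(t)] > 0 and len(templates[t]) < (
            params.fragment_len if params.paired else R
        ):
            raise ValueError(
                f"template {t} (length {len(templates[t])}) shorter than "
                f"{'fragment' if params.paired else 'read'} length"
            )
    rng = np.random.default_rng(params.seed)

    if params.paired:
        n_frag = params.n_reads // 2
        tidx = rng.choice(len(ids), size=n_frag, p=weights)
        u = rng.random(n_frag)
        reads: list[SimulatedRead] = []
        flip = rng.random(n_frag) < params.orient_prob
        for i in range(n_frag):
            tid = ids[tidx[i]]
            seq = templates[tid]
            start = int(u[i] * (len(seq) - params.fragment_len + 1))
            frag_rc = bool(flip[i])
            mate1 = (start, False)
            mate2 = (start + params.fragment_len - R, True)
            for mate_no, (s, rc) in enumerate(
                (mate2, mate1) if frag_rc else (mate1, mate2), start=1
            ):
                reads.append(
                    SimulatedRead(
                        id=f"{read_prefix}{i}/{mate_no}",
                        sequence="",  # filled below
                        template_id=tid,
                        start=s,
                        is_revcomp=rc,
                    )
                )
        reads = _fill_sequences(reads, templates, R, params.error_rate, rng)
        return reads

    n = params.n_reads
    tidx = rng.choice(len(ids), size=n, p=weights) if n else np.array([], dtype=int)
    u = rng.random(n)
    flip = rng.random(n) < params.orient_prob
    reads = []
    for i in range(n):
        tid = ids[tidx[i]]
        start = int(u[i] * (len(templates[tid]) - R + 1))
        reads.append(
            SimulatedRead(
                id=f"{read_prefix}{i}",
                sequence="",
                template_id=tid,
                start=start,
                is_revcomp=bool(flip[i]),
            )
        )
    return _fill_sequences(reads, templates, R, params.error_rate, rng)


def _fill_sequences(
    reads: list[SimulatedRead],
    templates: Mapping[str, str],
    R: int,
    error_rate: float,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    n = len(reads)
    n_err = (
        rng.binomial(R, error_rate, size=n) if error_rate > 0 else np.zeros(n, dtype=int)
    )
    out = []
    for i, r in enumerate(reads):
        seq = templates[r.template_id][r.start : r.start + R]
        k = int(n_err[i])
        if k:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            pos = rng.choice(R, size=k, replace=False)
            # substitute with a different base: shift 1..3 in base order
            cur = np.searchsorted(_BASES, arr[pos])
            arr[pos] = _BASES[(cur + rng.integers(1, 4, size=k)) % 4]
            seq = arr.tobytes().decode("ascii")
        if r.is_revcomp:
            seq = reverse_complement(seq)
        out.append(r._replace(sequence=seq))
    return out


def simulate_sample(
    spec: SampleSpec,
    params: SimParams,
    base_templates: Mapping[str, str],
    forms: Sequence[FusionForm],
    fusion_templates: Sequence[str],
) -> list[SimulatedRead]:
    """Simulate one sample, spiking in a fusion transcript when present.

    For a positive sample the fusion takes fusion_weight of the expression
    and the wild-type templates share the rest in their given proportions —
    the fusion is driven by the donor promoter, so it competes with, rather
    than adds to, wild-type expression.
    """
    templates = dict(base_templates)
    weights = dict(params.expression_weights)
    if spec.fusion_present:
        form = forms[spec.fusion_form]
        fusion_id = f"fusion_{form.name}"
        templates[fusion_id] = fusion_templates[spec.fusion_form]
        w = spec.fusion_weight
        weights = {k: v * (1.0 - w) for k, v in weights.items()}
        weights[fusion_id] = w
    p = replace(params, expression_weights=weights)
    return simulate_reads(templates, p, read_prefix=f"{spec.sample_id}:")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for a generated cohort."""

    samples: tuple[SampleSpec, ...]
    seeds: tuple[int, ...]
    fastq_paths: tuple[str, ...] = ()

    @property
    def n_positive(self) -> int:
        return sum(s.fusion_present for s in self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "fusion_present": [int(s.fusion_present) for s in self.samples],
                "form": [s.fusion_form if s.fusion_present else -1 for s in self.samples],
                "seed": list(self.seeds),
            }
        )


def plan_cohort(spec: CohortSpec, n_forms: int) -> CohortTruth:
    """Deterministically assign fusion status, form, and seed per sample."""
    rng = np.random.default_rng(spec.master_seed)
    n_pos = spec.n_positive
    order = rng.permutation(spec.n_samples)
    positive = set(order[:n_pos].tolist())
    form_choice = rng.integers(0, max(n_forms, 1), size=spec.n_samples)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_samples)
    width = max(len(str(spec.n_samples)), 3)
    samples = tuple(
        SampleSpec(
            sample_id=f"S{i:0{width}d}",
            fusion_present=i in positive,
            fusion_form=int(form_choice[i]) if i in positive else 0,
            fusion_weight=spec.fusion_weight if i in positive else 0.0,
        )
        for i in range(spec.n_samples)
    )
    return CohortTruth(samples=samples, seeds=tuple(int(s) for s in seeds))


def make_cohort(
    spec: CohortSpec,
    forms: Sequence[FusionForm],
    donor: TranscriptModel,
    acceptor: TranscriptModel,
    outdir: str | Path,
    gzip_fastq: bool = False,
) -> CohortTruth:
    """Write per-sample FASTQ files plus a truth table TSV.

    Returns the cohort truth with the written file paths.  Deterministic
    under the master seed: rerunning with the same spec yields byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_templates = {
        donor.accession: donor.sequence,
        acceptor.accession: acceptor.sequence,
    }
    fusion_templates = [
        make_fusion_transcript(donor, f.donor_exon, acceptor, f.acceptor_exon)
        for f in forms
    ]
    truth = plan_cohort(spec, n_forms=len(forms))
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = []
    for sample, seed in zip(truth.samples, truth.seeds):
        params = replace(spec.params, seed=int(seed))
        reads = simulate_sample(sample, params, base_templates, forms, fusion_templates)
        path = outdir / f"{sample.sample_id}{suffix}"
        write_fastq(reads, path)
        paths.append(str(path))
    truth = CohortTruth(samples=truth.samples, seeds=truth.seeds, fastq_paths=tuple(paths))
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth
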
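# Methods

## The screening model

The package screens for one pre-specified fusion transcript, defined at the
transcript (not genome) level: a donor transcript contributes everything
through the end of a named exon, an acceptor transcript everything from the
start of a named exon. For anchor length *k* the junction sequence is the
last *k* donor bases joined to the first *k* acceptor bases; a read reports
the fusion only if it contains this 2*k*-mer, i.e. covers the breakpoint
with at least *k* bases on each side. Anchors (the two *k*-mers separately)
measure locus coverage without asserting the fusion; a read carrying both a
donor and an acceptor anchor is a chimera candidate and is what the
junction criterion formalises.

Assumptions: single-breakpoint fusion; within-read evidence only (paired
mates are scanned independently — no discordant-pair rescue); one isoform
per gene; no splicing beyond the exon join itself.

## Matching

Matching is exact by default. The choice reflects how such screens are run
on raw FASTQ data: a fixed 20-mer is specific enough that substitution
tolerance mainly adds noise. Tolerance is still exposed
(`max_mismatch`, constrained to < *k*/2) and implemented as windowed
Hamming comparison, vectorised with numpy; `N` never matches any base, on
either side, so ambiguous bases cannot fabricate anchors. Reverse-complement
search is on by default (unstranded libraries). Each read counts at most
once per pattern regardless of match multiplicity. Tests hold the
production matcher equal to a naive per-position scan for mismatch 0–2 on
both strands.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| anchor length *k* | 20 | bp | standard anchor size for targeted junction screens; 20-mer chance collision in a 20,000-read × 100 bp sample is ~2 × 10⁻⁶ |
| max_mismatch | 0 | subst. | raw-sequence extraction; configurable |
| min_junction_reads | 1 | reads | a single junction-spanning read is the implicit positive criterion of a targeted screen |
| read length R | 100 | bp | typical short-read length; configurable |
| n_reads per sample | 20,000 | reads | desk-scale stand-in for the tens of millions of reads of a production run; chosen so a full 163-sample cohort generates and screens in minutes on one CPU |
| error rate | 0.001 | per base | order of Illumina substitution error |
| donor/acceptor expression | 0.9/0.1 | weight | emulates the strong donor-over-acceptor asymmetry seen in real anchor counts (thousands vs tens) |
| fusion_weight (positives) | 0.2 | weight | fusion driven by the donor promoter competes with wild-type expression; 0.2 of a 20,000-read sample gives analytic detection power > 0.999 |

## Synthetic data: what it emulates, what it does not

`simulate` draws fixed-length reads from weighted transcript templates:
template by expression weight, start uniform over valid positions,
independent per-base substitutions, orientation flipped with probability
0.5. It reproduces the features the screen's statistics depend on —
expression asymmetry, junction-span geometry, cohort prevalence (positives
= round(prevalence × n), assigned deterministically from the master seed) —
and is byte-identical under a fixed seed, with per-sample seeds drawn below
2³¹ from the master stream.

It does **not** model indels, quality-dependent errors, GC or positional
bias, PCR duplicates, strand-specific protocols, or intergenic/genomic
background reads. Passing tests therefore show the pipeline's logic and
calibration are correct under idealised read generation; they do not show
robustness to alignment-scale artefacts of real libraries, which this
within-read exact screen deliberately avoids by never aligning.

The shipped default gene models are synthetic fixtures (random sequence,
documented arbitrary exon spans) because the real transcripts' exon
boundaries are not part of the package's inputs; the four published primer
sequences are written into the fixtures at their printed transcript
coordinates (240–261 and 290–312 on the donor; 597–622 and 681–698,
reverse-complemented, on the acceptor), so primer-span arithmetic and the
nested-PCR geometry hold verbatim. Exon spans were chosen so both forward
primers fall in donor exon 2 and both reverse sites in acceptor exon 5,
making all three fusion forms amplifiable, as in the real design. Real
transcript models can be supplied as FASTA + exon TSV.

## Statistics

* Frequency: x/n with percent rounded to nearest integer.
* Upper bound: one-sided exact Clopper–Pearson. The x = 0 case uses the
  closed form 1 − α^(1/n), which satisfies (1 − p)ⁿ = α to machine
  precision; x > 0 uses the beta quantile. For n = 163, α = 0.05 the bound
  is 0.0182. (The rule-of-thumb −ln α/n overshoots this by ~1.5% at
  n ≈ 100, falling below 1% only near n ≈ 160; tests assert the asymptotic
  agreement from n = 200 up.)
* Two-cohort comparison: two-sided Fisher exact on the 2×2 table, exact
  rather than approximate because event counts are small; degenerate
  margins return p = 1 with a flag. Verified against full hypergeometric
  enumeration for margins ≤ 30.
* Junction-span probability q = max(0, R − 2m + 1)/(L − R + 1) counts
  qualifying read starts on the fusion transcript (uniform-start model,
  m = k on each side). Detection power is the binomial tail
  P(Bin(n, q) ≥ threshold); the simulator is held to both formulas within
  3σ in tests.
* Dominance diagnostic: under the fusion hypothesis each acceptor anchor
  should be covered at roughly donor level, so the ratio r =
  acceptor/donor is reported per exon with verdict "inconsistent with
  fusion" when all r < 0.1 and donor coverage ≥ 100 reads. The equal-level
  expectation is a deliberate simplification (equal window sizes, shared
  promoter); both thresholds are configurable, and low donor coverage or a
  zero donor count degrades the verdict rather than over-claiming.

## In-silico PCR

PCR is site matching plus product enumeration: no melting temperature,
cycling or yield. A primer primes where it matches the template
(sense) or where its reverse complement occurs (antisense), subject to
`max_mismatch` and to exact identity of its 3'-terminal bases
(`three_prime_exact`, default 3) — the minimal specificity proxy for
polymerase extension. Products pair an upstream sense forward site with a
downstream antisense reverse site within [min, max] product length
(defaults: primer-length sum, 5,000 bp). Nested PCR applies the inner pair
to each first-round product string, reporting coordinates relative to both
the outer amplicon and the original template; every nested product is by
construction a substring of its parent. The plasmid positive control is
modelled as donor exon 2 + acceptor exon 5 with configurable random
backbone padding. Copy numbers from mass use 650 g·mol⁻¹·bp⁻¹ and
Avogadro's number.

## Rearrangement feasibility

Loci are modelled on the centromere→telomere axis (position = distance from
centromere, orientation = transcription direction along the axis), not
genome-build strand, so no build details are imported. Under a single-event
model the feasible class is determined by configuration: different
chromosomes → translocation; opposite orientations → inversion; same
orientation with the 5' partner transcriptionally upstream → deletion,
downstream → tandem duplication. The duplication case requires one
breakpoint per gene (donor intron after its contributed exon, acceptor
intron before its first retained exon), which the toy-chromosome oracle
encodes by cutting at segment boundaries. Multi-event paths, which can
produce any fusion, are intentionally outside the model. The classifier is
proven equivalent to exhaustive breakpoint enumeration over all eight
two-gene configurations of a six-segment toy chromosome.

## Numerical and degenerate-input choices

* Determinism: every stochastic routine takes an explicit seed; cohort
  planning, per-sample seeds and read draws all come from
  `numpy.random.default_rng` streams of the master seed.
* Cohort positives use arithmetic (half-up) rounding of prevalence × n so
  0.1493 × 67 → 10.
* Substitution errors replace a base by one of the three others, never
  silently resampling the same base.
* Empty cohorts report 0/0 with an explicit empty flag; unreadable samples
  are recorded as failures without aborting the run; donor coverage of 0
  makes the dominance verdict "uninformative".
* Screen invariants maintained by construction and asserted in tests:
  junction reads ⊆ chimera reads ⊆ anchor read sets (at mismatch 0), and
  counts are non-decreasing in mismatch tolerance.

## Known limitations

Within-read evidence only (no discordant-pair or split-alignment recovery),
one isoform per gene, substitution-only error model, no genomic background
in simulations, and a PCR model that predicts presence/absence of products
rather than yields. The screen tests exactly one pre-specified fusion;
it is not a discovery tool.
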
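"""Anchor/junction counting against a naive oracle, cross-checks, and calls."""

import numpy as np
import pytest

from fusionscreen.gene_models import reverse_complement
from fusionscreen.matching import match_positions
from fusionscreen.screen import (
    NEGATIVE,
    POSITIVE,
    CohortReport,
    ScreenParams,
    ScreenResult,
    classify_sample,
    count_anchor_reads,
    cross_check,
    find_junction_reads,
    screen_cohort,
    screen_sample,
)
from fusionscreen.simulate import SimParams, make_fusion_transcript, simulate_reads


# --- independent naive oracle ------------------------------------------------

def naive_positions(seq: str, pattern: str, max_mm: int) -> list[int]:
    """O(len(seq) * len(pattern)) per-position scan; N never matches."""
    out = []
    for i in range(len(seq) - len(pattern) + 1):
        mm = 0
        for a, b in zip(seq[i : i + len(pattern)], pattern):
            if a != b or a == "N" or b == "N":
                mm += 1
        if mm <= max_mm:
            out.append(i)
    return out


def naive_read_hits(reads, pattern, max_mm, revcomp):
    pats = [pattern] + ([reverse_complement(pattern)] if revcomp else [])
    hits = set()
    for rid, seq in reads:
        if any(naive_positions(seq, p, max_mm) for p in pats):
            hits.add(rid)
    return hits


def random_reads(rng, n, length=100):
    bases = np.array(list("ACGT"))
    return [
        (f"r{i}", "".join(bases[rng.integers(0, 4, size=length)])) for i in range(n)
    ]


class TestMatcherOracleEquivalence:
    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_production_matcher_equals_naive_scan(self, max_mm):
        rng = np.random.default_rng(42 + max_mm)
        for _ in range(20):
            n = int(rng.integers(50, 400))
            seq = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, size=n)])
            m = int(rng.integers(4, 25))
            pattern = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=m)])
            assert match_positions(seq, pattern, max_mm) == naive_positions(
                seq, pattern, max_mm
            )

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    @pytest.mark.parametrize("revcomp", [False, True])
    def test_anchor_counts_equal_naive_oracle_on_read_sets(self, forms, max_mm, revcomp):
        """Production counting agrees with the naive sliding-window oracle on
        1,000-read instances, with planted exact and near-miss hits."""
        rng = np.random.default_rng(7 * (max_mm + 1) + int(revcomp))
        anchor = forms[0].donor_anchor
        reads = random_reads(rng, 1000)
        planted = []
        for i, (rid, seq) in enumerate(reads):
            roll = rng.random()
            if roll < 0.05:  # plant the anchor, sometimes mutated
                a = list(anchor)
                for _ in range(int(rng.integers(0, 3))):
                    a[int(rng.integers(0, len(a)))] = "ACGT"[int(rng.integers(0, 4))]
                ins = "".join(a)
                if rng.random() < 0.5:
                    ins = reverse_complement(ins)
                pos = int(rng.integers(0, len(seq) - len(ins)))
                planted.append((rid, seq[:pos] + ins + seq[pos + len(ins) :]))
            else:
                planted.append((rid, seq))
        params = ScreenParams(max_mismatch=max_mm, search_revcomp=revcomp)
        count, ids = count_anchor_reads(planted, anchor, params)
        oracle = naive_read_hits(planted, anchor, max_mm, revcomp)
        assert ids == oracle
        assert count == len(oracle)

    def test_counts_monotone_in_mismatch_tolerance(self, forms):
        rng = np.random.default_rng(3)
        anchor = forms[0].donor_anchor
        reads = random_reads(rng, 300, length=60)
        reads += [(f"p{i}", s[:20] + anchor + s[40:]) for i, (_, s) in enumerate(reads[:30])]
        prev = -1
        for mm in (0, 1, 2, 3):
            count, _ = count_anchor_reads(reads, anchor, ScreenParams(max_mismatch=mm))
            assert count >= prev
            prev = count


class TestAnchorCounting:
    def test_constructed_fixture_counts_exactly_the_planted_reads(self, forms):
        anchor = forms[0].donor_anchor
        filler = ("ACGT" * 30)[: 100 - 20]
        reads = [
            ("r0", "A" * 100),
            ("r1", anchor + filler[:80]),
            ("r2", "C" * 100),
            ("r3", filler[:40] + anchor + filler[:40]),
            ("r4", "G" * 100),
        ]
        count, ids = count_anchor_reads(reads, anchor, ScreenParams())
        assert (count, ids) == (2, {"r1", "r3"})

    def test_empty_read_set(self, forms):
        assert count_anchor_reads([], forms[0].donor_anchor, ScreenParams()) == (0, set())

    def test_reverse_complement_only_counted_when_enabled(self, forms):
        anchor = forms[0].donor_anchor
        reads = [("r0", "T" * 40 + reverse_complement(anchor) + "T" * 40)]
        on, _ = count_anchor_reads(reads, anchor, ScreenParams(search_revcomp=True))
        off, _ = count_anchor_reads(reads, anchor, ScreenParams(search_revcomp=False))
        assert (on, off) == (1, 0)

    def test_read_counted_once_despite_multiple_occurrences(self, forms):
        anchor = forms[0].donor_anchor
        reads = [("r0", anchor + "AC" + anchor)]
        assert count_anchor_reads(reads, anchor, ScreenParams())[0] == 1

    def test_non_dna_anchor_rejected(self):
        with pytest.raises(ValueError):
            count_anchor_reads([("r0", "ACGT")], "ACGU", ScreenParams())


class TestJunctionReads:
    def test_spanning_read_detected_and_half_reads_not(self, donor, acceptor, forms):
        form = forms[2]
        fusion = make_fusion_transcript(donor, 2, acceptor, form.acceptor_exon)
        j = fusion.find(form.junction_sequence)
        spanning = fusion[j - 30 : j - 30 + 100]
        donor_only = fusion[j - 80 : j + 19]  # covers the break with <k on the right
        assert find_junction_reads(
            [("s", spanning), ("d", donor_only)], form, ScreenParams()
        ) == ["s"]

    def test_revcomp_spanning_read_respects_search_flag(self, donor, acceptor, forms):
        form = forms[2]
        fusion = make_fusion_transcript(donor, 2, acceptor, form.acceptor_exon)
        j = fusion.find(form.junction_sequence)
        rc = reverse_complement(fusion[j - 30 : j - 30 + 100])
        assert find_junction_reads([("r", rc)], form, ScreenParams(search_revcomp=True)) == ["r"]
        assert find_junction_reads([("r", rc)], form, ScreenParams(search_revcomp=False)) == []

    def test_junction_hit_implies_both_anchor_hits_exact(self, donor, acceptor, forms):
        form = forms[2]
        fusion = make_fusion_transcript(donor, 2, acceptor, form.acceptor_exon)
        j = fusion.find(form.junction_sequence)
        reads = [(f"r{s}", fusion[s : s + 100]) for s in range(j - 120, j + 20, 7) if s >= 0]
        params = ScreenParams()
        jr = set(find_junction_reads(reads, form, params))
        _, donor_ids = count_anchor_reads(reads, form.donor_anchor, params)
        _, acc_ids = count_anchor_reads(reads, form.acceptor_anchor, params)
        assert jr <= donor_ids and jr <= acc_ids


class TestCrossCheckAndCalls:
    def test_disjoint_sets_have_no_chimeras(self):
        assert cross_check({"a", "b"}, {3: {"c"}, 4: {"d"}}) == 0

    def test_chimera_count_equals_spiked_junction_reads(self, donor, acceptor, forms):
        """error-free sample spiked with j junction-spanning reads ->
        chimera count exactly j (emission-tracking oracle)."""
        form = forms[2]
        fusion = make_fusion_transcript(donor, 2, acceptor, form.acceptor_exon)
        jpos = fusion.find(form.junction_sequence)
        p = SimParams(seed=9, n_reads=2000, read_len=100, error_rate=0.0,
                      orient_prob=0.5,
                      expression_weights={donor.accession: 0.95,
                                          acceptor.accession: 0.05})
        reads = simulate_reads(
            {donor.accession: donor.sequence, acceptor.accession: acceptor.sequence}, p
        )
        spikes = [
            (f"spike{i}", fusion[jpos - 40 + i : jpos - 40 + i + 100]) for i in range(7)
        ]
        res = screen_sample([(r.id, r.sequence) for r in reads] + spikes, [form])
        assert res.chimera_crosscheck == 7
        assert res.junction_reads[form.name] == [s[0] for s in spikes]

    def test_fusion_negative_sample_has_no_chimeras_across_seeds(
        self, donor, acceptor, forms
    ):
        templates = {donor.accession: donor.sequence, acceptor.accession: acceptor.sequence}
        for seed in range(20):
            p = SimParams(seed=seed, n_reads=1000, read_len=100, error_rate=0.001,
                          expression_weights={donor.accession: 0.9,
                                              acceptor.accession: 0.1})
            res = screen_sample(simulate_reads(templates, p), forms)
            assert res.chimera_crosscheck == 0
            assert res.call == NEGATIVE

    @pytest.mark.parametrize(
        "n_junction,threshold,expected",
        [(0, 1, NEGATIVE), (1, 1, POSITIVE), (1, 2, NEGATIVE), (3, 2, POSITIVE)],
    )
    def test_call_threshold_semantics(self, n_junction, threshold, expected):
        res = ScreenResult(
            sample_id="s", donor_anchor_reads=10, acceptor_anchor_reads={3: 1},
            junction_reads={"f": [f"r{i}" for i in range(n_junction)]},
            chimera_crosscheck=0, call=NEGATIVE,
        )
        assert classify_sample(res, ScreenParams(min_junction_reads=threshold)) == expected


class TestScreenCohort:
    def test_anchorless_templates_yield_zero_counts(self, forms):
        """Reads drawn from templates unrelated to the fusion genes never hit
        a 20-mer anchor (chance collision probability ~ 2e-6 per cohort)."""
        from fusionscreen.simulate import make_transcript

        other = make_transcript(999, 2000, [2000], gene_symbol="OTHER")
        for seed in range(3):
            p = SimParams(seed=seed, n_reads=20000, read_len=100,
                          expression_weights={other.accession: 1.0})
            reads = simulate_reads({other.accession: other.sequence}, p)
            res = screen_sample(reads, forms)
            assert res.donor_anchor_reads == 0
            assert all(v == 0 for v in res.acceptor_anchor_reads.values())

    def test_negative_cohort_screens_negative(self, donor, acceptor, forms):
        templates = {donor.accession: donor.sequence, acceptor.accession: acceptor.sequence}
        samples = []
        for i in range(10):
            p = SimParams(seed=100 + i, n_reads=2000, read_len=100, error_rate=0.001,
                          expression_weights={donor.accession: 0.9,
                                              acceptor.accession: 0.1})
            samples.append((f"S{i}", [(r.id, r.sequence) for r in simulate_reads(templates, p)]))
        report = screen_cohort(samples, forms)
        assert (report.n_positive, report.n_samples) == (0, 10)

    def test_high_weight_spike_in_cohort_all_positive(self, donor, acceptor, forms):
        """At fusion weight 0.2 and 20,000 reads the analytic detection power
        exceeds 0.999, so all 10 seeded positive samples are called."""
        from fusionscreen.simulate import CohortSpec, make_cohort
        import tempfile

        spec = CohortSpec(
            n_samples=10, prevalence=1.0, master_seed=3, fusion_weight=0.2,
            params=SimParams(seed=0, n_reads=20000, read_len=100, error_rate=0.001,
                             expression_weights={donor.accession: 0.9,
                                                 acceptor.accession: 0.1}),
        )
        with tempfile.TemporaryDirectory() as d:
            truth = make_cohort(spec, forms, donor, acceptor, d)
            report = screen_cohort(
                [(s.sample_id, p) for s, p in zip(truth.samples, truth.fastq_paths)],
                forms,
            )
        assert (report.n_positive, report.n_samples) == (10, 10)

    def test_empty_cohort_reports_explicit_empty_flag(self, forms):
        report = screen_cohort([], forms)
        assert (report.n_positive, report.n_samples) == (0, 0)
        assert report.empty

    def test_unreadable_sample_recorded_and_run_continues(self, forms, tmp_path):
        good = [("ok", [("r0", "A" * 100)])]
        bad = [("broken", tmp_path / "missing.fastq")]
        report = screen_cohort(bad + good, forms)
        assert report.n_samples == 2
        assert "broken" in report.failures
        assert len(report.results) == 1

    def test_spike_in_recovery_within_factor_of_expectation(self, donor, acceptor, forms):
        """Detected junction reads / analytic expectation stays in [0.5, 1.5]
        pooled over 20 seeds at expectation >= 10."""
        from fusionscreen.stats import junction_span_probability

        form = forms[2]
        fusion = make_fusion_transcript(donor, 2, acceptor, form.acceptor_exon)
        w, n, R = 0.1, 4000, 100
        q = junction_span_probability(R, form.anchor_len, len(fusion))
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            p = SimParams(seed=seed, n_reads=n, read_len=R, error_rate=0.0,
                          orient_prob=0.5,
                          expression_weights={donor.accession: 1 - w, "fusion": w})
            reads = simulate_reads(
                {donor.accession: donor.sequence, "fusion": fusion}, p
            )
            detected += len(find_junction_reads(reads, form, ScreenParams()))
        expected = n_seeds * n * w * q
        assert expected >= 10
        assert 0.5 <= detected / expected <= 1.5
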
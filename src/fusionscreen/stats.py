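"""Statistics for a negative screening result.

Covers the quantities a negative targeted screen should report: the observed
detection frequency, an exact (Clopper–Pearson) upper bound on the true
frequency when nothing is found, an exact two-cohort comparison (Fisher),
the per-read probability that a uniformly placed read spans the fusion
junction with enough flanking sequence on each side, the implied detection
power, and an expression-dominance diagnostic: if the fusion were present
and driven by the donor promoter, acceptor-exon anchor counts should be
comparable to the donor's, not orders of magnitude below it.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps


@dataclass(frozen=True)
class FrequencyComparison:
    """Detection counts in two cohorts with an exact test p-value."""

    x1: int
    n1: int
    x2: int
    n2: int
    p_value: float
    method: str = "Fisher exact (two-sided)"
    degenerate: bool = False

    def __post_init__(self) -> None:
        for x, n in ((self.x1, self.n1), (self.x2, self.n2)):
            if not (0 <= x <= n):
                raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")


@dataclass(frozen=True)
class PowerModel:
    """Detectability of a junction within single reads.

    R: read length; m: minimum overlap required on each side of the junction
    (the anchor length k); L: fusion transcript length; n_fusion_reads:
    expected number of reads drawn from the fusion transcript; q: per-read
    probability of spanning the junction with >= m bases on both sides.
    """

    R: int
    m: int
    L: int
    n_fusion_reads: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must lie in [0, 1]")
        if self.R < 2 * self.m and self.q != 0.0:
            raise ValueError("q must be 0 when R < 2m")


def observed_frequency(x: int, n: int) -> tuple[float, int]:
    """Observed proportion x/n and its percent rounded to the nearest integer."""
    if n < 1:
        raise ValueError("cohort size n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    p = x / n
    return p, int(round(p * 100))


def binomial_upper_limit(x: int, n: int, confidence: float = 0.95) -> float:
    """One-sided exact (Clopper–Pearson) upper confidence limit on a proportion.

    For x = 0 this solves (1 - p)^n = 1 - confidence in closed form; for
    x > 0 it is the standard beta-quantile bound.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    if n < 1 or not (0 <= x <= n):
        raise ValueError(f"need n >= 1 and 0 <= x <= n, got x={x}, n={n}")
    alpha = 1.0 - confidence
    if x == n:
        return 1.0
    if x == 0:
        return 1.0 - alpha ** (1.0 / n)
    return float(sps.beta.ppf(confidence, x + 1, n - x))


def exact_two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> FrequencyComparison:
    """Two-sided Fisher exact test comparing detection counts in two cohorts.

    Degenerate margins (no positives and no negatives to compare, e.g. all
    counts zero) yield p = 1 with the degenerate flag set.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if not (0 <= x <= n):
            raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    total_pos = x1 + x2
    total_neg = (n1 - x1) + (n2 - x2)
    if total_pos == 0 or total_neg == 0 or n1 == 0 or n2 == 0:
        return FrequencyComparison(x1, n1, x2, n2, p_value=1.0, degenerate=True)
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return FrequencyComparison(x1, n1, x2, n2, p_value=min(p, 1.0))


def junction_span_probability(R: int, m: int, L: int) -> float:
    """Fraction of uniform read starts covering the junction with >= m bases
    on each side: q = max(0, R - 2m + 1) / (L - R + 1).

    The junction of a fusion transcript of length L built from a donor
    prefix and acceptor suffix is a fixed internal position; a read of
    length R detects it only if it overlaps both sides by >= m.
    """
    if R < 1 or m < 1:
        raise ValueError("R and m must be >= 1")
    if L < R:
        raise ValueError(f"fusion transcript length L={L} shorter than read length R={R}")
    return max(0, R - 2 * m + 1) / (L - R + 1)


def detection_power(q: float, n_fusion_reads: int, min_junction_reads: int = 1) -> float:
    """P(Binomial(n, q) >= threshold): chance the screen calls the sample positive."""
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if n_fusion_reads < 0:
        raise ValueError("n_fusion_reads must be >= 0")
    if min_junction_reads < 1:
        raise ValueError("min_junction_reads must be >= 1")
    if n_fusion_reads == 0:
        return 0.0
    if min_junction_reads == 1:
        return 1.0 - (1.0 - q) ** n_fusion_reads
    return float(sps.binom.sf(min_junction_reads - 1, n_fusion_reads, q))


@dataclass(frozen=True)
class DominanceVerdict:
    """Observed/expected acceptor-anchor ratios under the fusion hypothesis."""

    donor_count: int
    ratios: dict[int, float]
    verdict: str  # "inconsistent with fusion" | "consistent" | "uninformative"
    threshold: float
    min_donor_count: int


def dominance_diagnostic(
    donor_anchor_count: int,
    acceptor_anchor_counts: dict[int, int],
    threshold: float = 0.1,
    min_donor_count: int = 100,
) -> DominanceVerdict:
    """Test whether acceptor-anchor counts are consistent with a fusion
    expressed at the donor's level.

    Under the fusion hypothesis the acceptor anchors sit on the fusion
    transcript, which shares the donor promoter, so each acceptor-anchor
    count is expected to be of the donor's order; the ratio
    r = observed / donor far below 1 argues against the fusion.  The verdict
    is "inconsistent with fusion" when every ratio is below ``threshold``
    and the donor count is at least ``min_donor_count``; a donor count of 0
    is uninformative.
    """
    if donor_anchor_count < 0 or any(v < 0 for v in acceptor_anchor_counts.values()):
        raise ValueError("counts must be >= 0")
    if donor_anchor_count == 0:
        return DominanceVerdict(0, {}, "uninformative", threshold, min_donor_count)
    ratios = {
        exon: count / donor_anchor_count
        for exon, count in acceptor_anchor_counts.items()
    }
    if (
        donor_anchor_count >= min_donor_count
        and ratios
        and all(r < threshold for r in ratios.values())
    ):
        verdict = "inconsistent with fusion"
    else:
        verdict = "consistent"
    return DominanceVerdict(
        donor_anchor_count, ratios, verdict, threshold, min_donor_count
    )
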
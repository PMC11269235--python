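"""Gene-set algebra and overlap statistics.

The quantities here are the ones a transcriptome-comparison report prints:
overlap counts and query-percentages, Jaccard similarity between expressed
transcriptomes, one-sided hypergeometric enrichment p-values computed in
log space (printed p-values in this domain reach 1e-1000 and below, far
beyond double-precision underflow), fold over/under-enrichment, and the
condition-dependence partition of differentially expressed (DE) gene sets
between a wild-type and a mutant genotype.

Percentages are rounded half-away-from-zero at the requested number of
decimals, computed in exact rational arithmetic so printed figures are
reproduced bit-for-bit from printed counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

LOG10_2 = math.log10(2.0)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self):
        return len(self.members)


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Plain-text gene list: one id per line, '#' comments allowed."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return GeneSet(name or str(path), frozenset(ids))


def write_gene_list(gs: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gs.members):
            fh.write(gid + "\n")


def overlap(a: GeneSet, b: GeneSet) -> tuple:
    """(shared, only-in-a, only-in-b) member counts."""
    k = len(a.members & b.members)
    return k, len(a) - k, len(b) - k


def _round_half_away(frac: Fraction, decimals: int) -> float:
    scaled = frac * 10**decimals
    q = math.floor(scaled + Fraction(1, 2)) if scaled >= 0 else -math.floor(-scaled + Fraction(1, 2))
    return q / 10**decimals


def percent_of_query(k: int, n_query: int, decimals: int = 0) -> float:
    """100*k/n_query, rounded half-away-from-zero at ``decimals``."""
    if n_query <= 0:
        raise ValueError("n_query must be positive")
    if not 0 <= k <= n_query:
        raise ValueError(f"k={k} outside [0, {n_query}]")
    return _round_half_away(Fraction(100 * k, n_query), decimals)


def jaccard_percent(size_a: int, size_b: int, k: int, decimals: int = 1) -> float:
    """Jaccard similarity 100*|A∩B|/|A∪B| from set sizes and overlap."""
    if k > min(size_a, size_b):
        raise ValueError("overlap exceeds a set size")
    union = size_a + size_b - k
    if union <= 0:
        raise ValueError("degenerate zero union")
    return _round_half_away(Fraction(100 * k, union), decimals)


annotate_fraction = percent_of_query
"""Alias used when labeling within-set functional breakdowns."""


# -- hypergeometric tail in log space ----------------------------------------

def _check_hg(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"need 0 <= n,K <= N, got n={n} K={K} N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n,K)={min(n, K)}]")


def _log10_ratio(num: int, den: int) -> float:
    """log10(num/den) for positive integers, accurate to ~1 ulp even when
    the ratio is far outside double range."""
    shift = den.bit_length() - num.bit_length() + 64
    if shift >= 0:
        q = (num << shift) // den
    else:
        q = num // (den << -shift)
    return math.log10(q) - shift * LOG10_2


def _log_pmf_terms(n: int, K: int, N: int, lo: int, hi: int) -> list:
    """log10 hypergeometric pmf at k = lo..hi (inclusive), from exact
    integer binomial coefficients so that every term is correctly rounded
    regardless of tail depth."""
    den = math.comb(N, n)
    a = math.comb(K, lo)          # C(K, k)
    b = math.comb(N - K, n - lo)  # C(N-K, n-k)
    out = []
    for k in range(lo, hi + 1):
        out.append(_log10_ratio(a * b, den))
        # advance k -> k+1
        a = a * (K - k) // (k + 1)
        if n - k >= 1:
            b = b * (n - k) // (N - K - n + k + 1)
    return out


def _log10_sum(terms: list) -> float:
    m = max(terms)
    return m + math.log10(math.fsum(10.0 ** (t - m) for t in terms))


def log_hypergeom_sf(k: int, n: int, K: int, N: int) -> float:
    """log10 of the upper tail P[X >= k] for X ~ Hypergeom(N, K, n).

    Tail terms come from exact integer binomials and are summed in log10
    space, so magnitudes far below double-precision underflow (log10 p of
    -1200 and beyond) stay finite and accurate.  P[X >= 0] is exactly 1
    (log10 = 0).
    """
    _check_hg(k, n, K, N)
    if k == 0:
        return 0.0
    kmax = min(n, K)
    kmin_support = max(0, n + K - N)
    if k <= kmin_support:
        return 0.0
    return min(0.0, _log10_sum(_log_pmf_terms(n, K, N, k, kmax)))


def log_hypergeom_cdf(k: int, n: int, K: int, N: int) -> float:
    """log10 of the lower tail P[X <= k]."""
    _check_hg(k, n, K, N)
    kmin_support = max(0, n + K - N)
    if k >= min(n, K):
        return 0.0
    return min(0.0, _log10_sum(_log_pmf_terms(n, K, N, kmin_support, k)))


def p_display(log10_p: float, sig: int = 3) -> str:
    """Render a log10 p-value as m.mme-XXX scientific notation without
    ever exponentiating the full magnitude."""
    if log10_p >= 0.0:
        return "1"
    exp = math.floor(log10_p)
    mant = 10 ** (log10_p - exp)
    # mantissa rounding can carry to 10.0
    mant_r = round(mant, sig - 1)
    if mant_r >= 10.0:
        mant_r /= 10.0
        exp += 1
    return f"{mant_r:.{sig - 1}f}e{exp:+04d}"


@dataclass(frozen=True)
class EnrichmentResult:
    query_name: str
    reference_name: str
    k: int
    n: int
    K: int
    N: int
    log10_p: float
    fold: float
    direction: str  # 'enriched' | 'depleted'

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N

    @property
    def p_display(self) -> str:
        return p_display(self.log10_p)


def enrichment_test(query: GeneSet, reference: GeneSet,
                    population: GeneSet) -> EnrichmentResult:
    """One-sided hypergeometric test of the query/reference overlap.

    Enriched overlaps (k >= expected) report the upper tail P[X >= k] and
    fold = observed/expected; depleted overlaps report the lower tail
    P[X <= k] and fold = expected/observed (the "x-fold under enriched"
    convention).
    """
    bad_q = query.members - population.members
    bad_r = reference.members - population.members
    if bad_q or bad_r:
        offenders = sorted(bad_q | bad_r)[:10]
        raise ValueError(f"sets not contained in population; e.g. {offenders}")
    n, K, N = len(query), len(reference), len(population)
    k = len(query.members & reference.members)
    expected = n * K / N
    if k >= expected:
        direction = "enriched"
        lp = log_hypergeom_sf(k, n, K, N)
        fold = k / expected if expected > 0 else math.inf
    else:
        direction = "depleted"
        lp = log_hypergeom_cdf(k, n, K, N)
        fold = expected / k if k > 0 else math.inf
    return EnrichmentResult(query.name, reference.name, k, n, K, N, lp, fold, direction)


# -- condition-dependence partition ------------------------------------------

@dataclass(frozen=True)
class DependencePartition:
    """Partition of wild-type DE genes by whether their differential
    expression survives in a mutant genotype.

    A wild-type DE gene absent from the mutant's same-direction DE list is
    "dependent" on the mutated factor.
    """

    wt_up: GeneSet
    wt_down: GeneSet
    mut_up: GeneSet
    mut_down: GeneSet
    shared_up: int
    shared_down: int
    dependent_up: GeneSet
    dependent_down: GeneSet

    @property
    def percent_dependent(self) -> float:
        total = len(self.wt_up) + len(self.wt_down)
        if total == 0:
            raise ValueError("no wild-type DE genes")
        return percent_of_query(len(self.dependent_up) + len(self.dependent_down),
                                total, decimals=0)


def dependence_partition(wt_up: GeneSet, wt_down: GeneSet,
                         mut_up: GeneSet, mut_down: GeneSet) -> DependencePartition:
    for name, up, down in (("wild-type", wt_up, wt_down), ("mutant", mut_up, mut_down)):
        both = up.members & down.members
        if both:
            raise ValueError(f"{name} up/down sets overlap: {sorted(both)[:5]}")
    dep_up = GeneSet(f"{wt_up.name}_dependent", wt_up.members - mut_up.members)
    dep_down = GeneSet(f"{wt_down.name}_dependent", wt_down.members - mut_down.members)
    return DependencePartition(
        wt_up, wt_down, mut_up, mut_down,
        shared_up=len(wt_up.members & mut_up.members),
        shared_down=len(wt_down.members & mut_down.members),
        dependent_up=dep_up, dependent_down=dep_down,
    )


def enrichment_table(results) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([{
        "query": r.query_name, "reference": r.reference_name,
        "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "expected": r.expected, "fold": r.fold, "direction": r.direction,
        "log10_p": r.log10_p, "p_display": r.p_display,
    } for r in results])
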
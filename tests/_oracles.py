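"""Independent brute-force oracles used only by the tests.

Deliberately naive: the motif matcher enumerates every spacer-length
assignment with itertools.product and checks fixed positions one by one,
sharing no code with the scanning engine it checks.
"""

import itertools
from fractions import Fraction
from math import comb

from postdauer.motifs import Choice, Gap, Literal

ACGT = set("ACGT")


def _expand_fixed(blocks, gap_lengths):
    """Lay out the pattern with concrete gap lengths as a list of
    per-position constraints: a set of allowed bases, or None for a
    spacer position (any single ACGT base)."""
    out = []
    gi = 0
    for b in blocks:
        if isinstance(b, Literal):
            out.extend({c} for c in b.seq)
        elif isinstance(b, Choice):
            out.append(set(b.bases))
        else:
            out.extend([None] * gap_lengths[gi])
            gi += 1
    return out


def brute_force_match(pattern, seq, pos):
    """All (gap_lengths, length) assignments matching at ``pos``, in
    lexicographic gap order."""
    bounds = [(b.min, b.max) for b in pattern.blocks if isinstance(b, Gap)]
    results = []
    for gaps in itertools.product(*[range(lo, hi + 1) for lo, hi in bounds]):
        layout = _expand_fixed(pattern.blocks, gaps)
        end = pos + len(layout)
        if end > len(seq):
            continue
        ok = True
        for off, allowed in enumerate(layout):
            c = seq[pos + off]
            if allowed is None:
                if c not in ACGT:
                    ok = False
                    break
            elif c not in allowed:
                ok = False
                break
        if ok:
            results.append((gaps, len(layout)))
    return results


def brute_force_scan(pattern, seq):
    """Start positions admitting a match, with the leftmost-shortest
    assignment at each."""
    hits = []
    for pos in range(len(seq) + 1):
        m = brute_force_match(pattern, seq, pos)
        if m:
            hits.append((pos,) + m[0])
    return hits


def exact_hypergeom_sf(k, n, K, N):
    """P[X >= k] as an exact Fraction via binomial enumeration."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def exact_hypergeom_cdf(k, n, K, N):
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(max(0, n + K - N), k + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc
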
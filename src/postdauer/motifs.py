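"""Degenerate gapped DNA motif grammar, compiler and scanner.

The motifs of interest in post-dauer ADL neuron regulation are written in a
small pattern notation: runs of literal bases, bracketed single-position
choice sets (``[AT]`` or ``[A/T]``), bounded variable-length spacers
(``N(0,3)`` or ``N_0-3``) and the common IUPAC one-letter degeneracy codes
S/W/Y/R.  The canonical instances are

* the DAF-3/SMAD binding site ``GTCTA``,
* the ~30 bp conserved "MSP motif"
  ``CT[AT]TAA[AT]TTN(0,3)[AC]AN(0,2)TTTTG[CT]CATAA[TA]C[TC]``,
* the ADL E-box ``CASCTG`` and the modified E-box ``CACGTG``.

A gene whose upstream region carries both the DAF-3 site and the MSP motif
(anywhere, in any order) carries the full "PD motif".

Matching semantics: a pattern matches at a position iff some assignment of
spacer lengths (each within its bounds) aligns every fixed position to an
equal base.  When several assignments match, the lexicographically smallest
(leftmost-shortest) one is reported, so hit counts are deterministic.
Ambiguous genome bases (anything outside ACGT, normalised to N) match no
pattern position — not even a spacer — so assembly gaps can never fabricate
a motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import UpstreamRegion, revcomp

_ACGT = frozenset("ACGT")

IUPAC_CODES: Mapping[str, frozenset] = {
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "Y": frozenset("CT"),
    "R": frozenset("AG"),
}


class PatternError(ValueError):
    """Raised for a malformed motif pattern string."""


@dataclass(frozen=True)
class Literal:
    seq: str


@dataclass(frozen=True)
class Choice:
    bases: frozenset


@dataclass(frozen=True)
class Gap:
    min: int
    max: int


Block = Literal | Choice | Gap


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif: ordered blocks plus derived length bounds."""

    name: str
    blocks: tuple
    min_len: int = field(init=False)
    max_len: int = field(init=False)

    def __post_init__(self):
        if not self.blocks:
            raise PatternError("pattern has no blocks")
        if isinstance(self.blocks[0], Gap) or isinstance(self.blocks[-1], Gap):
            raise PatternError("pattern may not start or end with a spacer")
        lo = hi = 0
        for b in self.blocks:
            if isinstance(b, Literal):
                lo += len(b.seq)
                hi += len(b.seq)
            elif isinstance(b, Choice):
                lo += 1
                hi += 1
            else:
                lo += b.min
                hi += b.max
        object.__setattr__(self, "min_len", lo)
        object.__setattr__(self, "max_len", hi)

    @property
    def gap_bounds(self) -> tuple:
        return tuple((b.min, b.max) for b in self.blocks if isinstance(b, Gap))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    pattern_name: str
    offset: int
    length: int
    gap_lengths: tuple
    scanned_strand: str = "forward"  # or "revcomp"


@dataclass(frozen=True)
class PdStatus:
    gene_id: str
    has_daf3: bool
    has_conserved: bool

    @property
    def has_full_pd(self) -> bool:
        return self.has_daf3 and self.has_conserved


def compile_pattern(spec: str, name: str | None = None) -> MotifPattern:
    """Compile a pattern string into a :class:`MotifPattern`.

    Accepts literal ACGT, IUPAC S/W/Y/R, ``[XY]``/``[X/Y]`` choices, and
    spacers spelled ``N(min,max)`` or ``N_min-max``; a bare ``N`` is a
    spacer of exactly one (any) base.  Raises :class:`PatternError` naming
    the offending token and its position.
    """
    spec = spec.strip()
    blocks: list = []
    lit: list = []

    def flush():
        if lit:
            blocks.append(Literal("".join(lit)))
            lit.clear()

    i = 0
    while i < len(spec):
        c = spec[i]
        if c in _ACGT:
            lit.append(c)
            i += 1
        elif c in IUPAC_CODES:
            flush()
            blocks.append(Choice(IUPAC_CODES[c]))
            i += 1
        elif c == "[":
            j = spec.find("]", i)
            if j < 0:
                raise PatternError(f"unbalanced bracket at position {i}: {spec[i:]!r}")
            inner = spec[i + 1 : j].replace("/", "")
            if not inner or not set(inner) <= _ACGT:
                raise PatternError(f"invalid choice token at position {i}: {spec[i:j+1]!r}")
            flush()
            blocks.append(Choice(frozenset(inner)))
            i = j + 1
        elif c == "N":
            flush()
            gap, i = _parse_gap(spec, i)
            blocks.append(gap)
        else:
            raise PatternError(f"unexpected character at position {i}: {c!r}")
    flush()
    # coalesce adjacent gaps (e.g. "NN" -> Gap(2,2))
    merged: list = []
    for b in blocks:
        if merged and isinstance(b, Gap) and isinstance(merged[-1], Gap):
            prev = merged.pop()
            b = Gap(prev.min + b.min, prev.max + b.max)
        merged.append(b)
    return MotifPattern(name if name is not None else spec, tuple(merged))


def _parse_gap(spec: str, i: int):
    # spec[i] == 'N'; returns (Gap, next index)
    if spec.startswith("N(", i):
        j = spec.find(")", i)
        if j < 0:
            raise PatternError(f"unbalanced parenthesis at position {i}: {spec[i:]!r}")
        body = spec[i + 2 : j]
        parts = body.split(",")
        if len(parts) != 2:
            raise PatternError(f"malformed spacer at position {i}: {spec[i:j+1]!r}")
        lo, hi = _gap_bounds(parts[0], parts[1], spec[i : j + 1], i)
        return Gap(lo, hi), j + 1
    if spec.startswith("N_", i):
        j = i + 2
        k = j
        while k < len(spec) and (spec[k].isdigit() or spec[k] == "-"):
            k += 1
        body = spec[j:k]
        parts = body.split("-")
        if len(parts) != 2:
            raise PatternError(f"malformed spacer at position {i}: {spec[i:k]!r}")
        lo, hi = _gap_bounds(parts[0], parts[1], spec[i:k], i)
        return Gap(lo, hi), k
    return Gap(1, 1), i + 1


def _gap_bounds(lo_s: str, hi_s: str, token: str, pos: int):
    try:
        lo, hi = int(lo_s), int(hi_s)
    except ValueError:
        raise PatternError(f"non-integer spacer bound at position {pos}: {token!r}") from None
    if lo < 0 or hi < lo:
        raise PatternError(f"invalid spacer bounds at position {pos}: {token!r}")
    return lo, hi


# -- canonical motifs ---------------------------------------------------------

DAF3_SITE = "GTCTA"
MSP_MOTIF = "CT[AT]TAA[AT]TTN(0,3)[AC]AN(0,2)TTTTG[CT]CATAA[TA]C[TC]"
EBOX_ADL = "CASCTG"
EBOX_CACGTG = "CACGTG"


def daf3_pattern() -> MotifPattern:
    return compile_pattern(DAF3_SITE, name="daf3")


def msp_pattern() -> MotifPattern:
    return compile_pattern(MSP_MOTIF, name="msp")


# -- matching -----------------------------------------------------------------

def match_at(pattern: MotifPattern, seq: str, pos: int) -> MotifHit | None:
    """Try to match ``pattern`` anchored at ``pos``; return the
    leftmost-shortest hit or None.

    Spacer lengths are explored in increasing order, earlier spacers first,
    so the returned ``gap_lengths`` tuple is the lexicographically smallest
    assignment that matches.
    """
    if not 0 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    gaps = _match_blocks(pattern.blocks, seq, pos, ())
    if gaps is None:
        return None
    length = pattern.min_len + sum(gaps) - sum(lo for lo, _ in pattern.gap_bounds)
    return MotifHit("", pattern.name, pos, length, gaps)


def _match_blocks(blocks, seq, pos, gaps):
    if not blocks:
        return gaps
    b, rest = blocks[0], blocks[1:]
    if isinstance(b, Literal):
        end = pos + len(b.seq)
        if end > len(seq) or seq[pos:end] != b.seq:
            return None
        return _match_blocks(rest, seq, end, gaps)
    if isinstance(b, Choice):
        if pos >= len(seq) or seq[pos] not in b.bases:
            return None
        return _match_blocks(rest, seq, pos + 1, gaps)
    # Gap: any ACGT base, length chosen smallest-first
    for g in range(b.min, b.max + 1):
        end = pos + g
        if end > len(seq) or any(c not in _ACGT for c in seq[pos:end]):
            break  # longer gaps only add more failing bases
        res = _match_blocks(rest, seq, end, gaps + (g,))
        if res is not None:
            return res
    return None


def scan_sequence(pattern: MotifPattern, seq: str, gene_id: str = "",
                  scanned_strand: str = "forward") -> list:
    """All hits of ``pattern`` in ``seq``: at most one per start position
    (the leftmost-shortest assignment), overlapping starts all reported,
    ordered by offset."""
    hits = []
    for pos in range(0, len(seq) - pattern.min_len + 1):
        h = match_at(pattern, seq, pos)
        if h is not None:
            hits.append(MotifHit(gene_id, pattern.name, pos, h.length,
                                 h.gap_lengths, scanned_strand))
    return hits


def scan_region(pattern: MotifPattern, region: UpstreamRegion,
                both_strands: bool = False) -> list:
    """Scan one upstream region; optionally also its reverse complement.

    Reverse-complement hits carry offsets in reverse-complement coordinates
    and ``scanned_strand="revcomp"``.  For palindromic patterns a forward
    and a revcomp hit can describe the same genomic locus; deduplication is
    left to the caller.
    """
    hits = scan_sequence(pattern, region.seq, region.gene_id)
    if both_strands:
        hits += scan_sequence(pattern, revcomp(region.seq), region.gene_id,
                              scanned_strand="revcomp")
    return hits


def classify_pd_status(regions: Sequence[UpstreamRegion],
                       daf3: MotifPattern | None = None,
                       conserved: MotifPattern | None = None) -> list:
    """Flag each gene for DAF-3 site / MSP motif / full-PD-motif content.

    Presence means >= 1 hit anywhere in the region; the full PD motif is the
    conjunction of the two flags with no spacing or ordering constraint.
    """
    daf3 = daf3 if daf3 is not None else daf3_pattern()
    conserved = conserved if conserved is not None else msp_pattern()
    seen = set()
    out = []
    for r in regions:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id among regions: {r.gene_id}")
        seen.add(r.gene_id)
        out.append(PdStatus(
            r.gene_id,
            has_daf3=bool(scan_sequence(daf3, r.seq)),
            has_conserved=bool(scan_sequence(conserved, r.seq)),
        ))
    return out


def scan_geneset(patterns: Iterable[MotifPattern],
                 regions: Sequence[UpstreamRegion],
                 both_strands: bool = False):
    """Scan many patterns over many regions.

    Returns ``(hit_table, gene_sets)``: a DataFrame with one row per
    (gene, pattern) having >=1 hit — columns gene_id, pattern_name, n_hits,
    offsets — and a dict mapping pattern name to the set of motif-bearing
    gene ids (genes with zero hits are absent from both).
    """
    rows = []
    gene_sets: dict = {p.name: set() for p in patterns}
    for p in patterns:
        for r in regions:
            hits = scan_region(p, r, both_strands=both_strands)
            if hits:
                rows.append({
                    "gene_id": r.gene_id,
                    "pattern_name": p.name,
                    "n_hits": len(hits),
                    "offsets": ",".join(str(h.offset) for h in hits),
                })
                gene_sets[p.name].add(r.gene_id)
    table = pd.DataFrame(rows, columns=["gene_id", "pattern_name", "n_hits", "offsets"])
    return table, gene_sets


def read_motif_file(path) -> list:
    """Read motif definitions: one ``name<TAB or space>pattern`` per line,
    '#' comments and blank lines ignored."""
    pats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise PatternError(f"motif line needs 'name pattern': {line!r}")
            name, spec = parts
            pats.append(compile_pattern(spec.strip(), name=name.strip()))
    return pats


def write_hit_table(hits: Iterable[MotifHit], path) -> None:
    df = pd.DataFrame(
        [(h.gene_id, h.pattern_name, h.offset, h.length,
          ",".join(map(str, h.gap_lengths)), h.scanned_strand) for h in hits],
        columns=["gene_id", "pattern_name", "offset", "length",
                 "gap_lengths", "scanned_strand"],
    )
    df.to_csv(path, sep="\t", index=False)
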
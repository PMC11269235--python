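"""Behavioral assay indices for nematode chemosensation.

Three plate-assay readouts, all per trial:

* six-sector octanol avoidance: the plate is split into sectors A-F with
  the stimulus at A and the solvent control at F; the avoidance index is
  ((A+B) - (E+F)) / N over all six sectors, so negative values mean the
  animals moved away from the stimulus;
* two-spot chemotaxis: (worms at attractant - worms at control) / total,
  +1 perfect attraction, -1 perfect repulsion;
* drop-test reversal: the fraction of tested animals showing a backward
  escape response.

Cross-trial aggregation is mean +/- SD with the trial as the unit;
hypothesis testing on the indices is left to standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class SectorCounts:
    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d, self.e, self.f) < 0:
            raise ValueError("sector counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d + self.e + self.f


@dataclass(frozen=True)
class SpotCounts:
    n_attractant: int
    n_control: int
    n_total: int

    def __post_init__(self):
        if min(self.n_attractant, self.n_control) < 0:
            raise ValueError("spot counts must be non-negative")
        if self.n_total < self.n_attractant + self.n_control:
            raise ValueError("n_total smaller than counted worms")


@dataclass(frozen=True)
class ReversalRecord:
    n_reversed: int
    n_tested: int

    def __post_init__(self):
        if not 0 <= self.n_reversed <= self.n_tested:
            raise ValueError("need 0 <= n_reversed <= n_tested")


def avoidance_index(s: SectorCounts) -> float:
    """((A+B) - (E+F)) / N; negative = avoidance of the sector-A stimulus."""
    if s.total == 0:
        raise ValueError("no worms on plate")
    return ((s.a + s.b) - (s.e + s.f)) / s.total


def chemotaxis_index(s: SpotCounts) -> float:
    """(attractant - control) / total; +1 perfect attraction."""
    if s.n_total == 0:
        raise ValueError("no worms on plate")
    return (s.n_attractant - s.n_control) / s.n_total


def reversal_fraction(r: ReversalRecord) -> float:
    if r.n_tested == 0:
        raise ValueError("no animals tested")
    return r.n_reversed / r.n_tested


def read_assay_tsv(path) -> pd.DataFrame:
    """Assay TSV: one row per trial with columns strain, assay
    ('avoidance'|'chemotaxis'|'reversal') and the raw counts for that assay
    type (sector_a..sector_f / n_attractant,n_control,n_total /
    n_reversed,n_tested)."""
    return pd.read_csv(path, sep="\t")


def trial_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial index column appended to an assay table."""
    vals = []
    for _, row in df.iterrows():
        kind = row["assay"]
        if kind == "avoidance":
            v = avoidance_index(SectorCounts(*[int(row[f"sector_{c}"])
                                               for c in "abcdef"]))
        elif kind == "chemotaxis":
            v = chemotaxis_index(SpotCounts(int(row["n_attractant"]),
                                            int(row["n_control"]),
                                            int(row["n_total"])))
        elif kind == "reversal":
            v = reversal_fraction(ReversalRecord(int(row["n_reversed"]),
                                                 int(row["n_tested"])))
        else:
            raise ValueError(f"unknown assay type {kind!r}")
        vals.append(v)
    out = df.copy()
    out["index"] = vals
    return out


def strain_summary(df_with_index: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of the per-trial index, grouped by strain and assay."""
    g = df_with_index.groupby(["strain", "assay"])["index"]
    return g.agg(n_trials="count", mean="mean", sd="std").reset_index()
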
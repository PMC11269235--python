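"""RPKM normalisation, expressed-gene calling and DE-table ingestion.

RPKM (reads per kilobase of transcript per million mapped reads) is
RPKM[g,s] = counts[g,s] * 1e9 / (length_nt[g] * total_reads[s]).  A gene is
called expressed in a condition when the mean RPKM over that condition's
replicates meets the threshold (default >= 10 RPKM, the conventional
cutoff for neuron-sorted RNA-Seq).  Differential-expression testing itself
is upstream of this package: DE tables (gene_id, direction, fdr) are
consumed and filtered at a strict FDR < cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts with per-gene transcript lengths.

    ``sample_labels`` maps each counts column to a (genotype, condition,
    replicate) triple.
    """

    counts: pd.DataFrame  # index = gene ids, columns = sample names
    lengths_nt: pd.Series  # same index
    sample_labels: dict  # sample name -> (genotype, condition, replicate)

    def __post_init__(self):
        if not self.counts.index.equals(self.lengths_nt.index):
            raise ValueError("counts and lengths indexed by different genes")
        if (self.lengths_nt <= 0).any():
            bad = self.lengths_nt[self.lengths_nt <= 0].index[:5].tolist()
            raise ValueError(f"non-positive transcript lengths, e.g. {bad}")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")

    def samples_for(self, genotype=None, condition=None) -> list:
        return [s for s, (g, c, _r) in self.sample_labels.items()
                if (genotype is None or g == genotype)
                and (condition is None or c == condition)]


def read_counts_tsv(path) -> ExpressionMatrix:
    """Counts TSV: columns gene_id, length_nt, then one column per sample
    named genotype.condition.replicate."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("gene_id")
    lengths = df.pop("length_nt")
    labels = {}
    for col in df.columns:
        parts = col.split(".")
        if len(parts) != 3:
            raise ValueError(f"sample column {col!r} is not genotype.condition.replicate")
        labels[col] = (parts[0], parts[1], parts[2])
    return ExpressionMatrix(df.astype(np.int64), lengths.astype(np.int64), labels)


def rpkm(counts: pd.DataFrame, lengths_nt: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample RPKM.  ``totals`` defaults to the column sums."""
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero total reads in sample(s) {bad}")
    return counts * 1e9 / np.outer(lengths_nt.to_numpy(), totals.to_numpy())


@dataclass(frozen=True)
class ExpressedSet:
    condition: str
    threshold: float
    rule: str  # '>=' or '>'
    members: GeneSet


def call_expressed(rpkm_df: pd.DataFrame, samples: Sequence[str],
                   threshold: float = 10.0, rule: str = ">=",
                   condition: str = "condition") -> ExpressedSet:
    """Expressed-gene call: mean RPKM over the condition's replicates
    compared with the threshold."""
    if not samples:
        raise ValueError("empty sample subset")
    if rule not in (">=", ">"):
        raise ValueError(f"rule must be '>=' or '>', got {rule!r}")
    summary = rpkm_df[list(samples)].mean(axis=1)
    mask = summary >= threshold if rule == ">=" else summary > threshold
    members = GeneSet(condition, frozenset(summary.index[mask]))
    return ExpressedSet(condition, threshold, rule, members)


def read_de_table(path) -> pd.DataFrame:
    """DE table TSV with columns gene_id, direction ('up'/'down'), fdr."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "direction", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in DE table: {dup}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    return df


def de_sets(table: pd.DataFrame, fdr_cutoff: float = 0.05,
            name_prefix: str = "de") -> tuple:
    """Split a DE table into (up, down) GeneSets at strict FDR < cutoff."""
    bad = set(table["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown direction token(s): {sorted(bad)}")
    sig = table[table["fdr"] < fdr_cutoff]
    up = GeneSet(f"{name_prefix}_up",
                 frozenset(sig.loc[sig["direction"] == "up", "gene_id"]))
    down = GeneSet(f"{name_prefix}_down",
                   frozenset(sig.loc[sig["direction"] == "down", "gene_id"]))
    return up, down
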
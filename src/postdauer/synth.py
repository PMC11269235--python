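"""Synthetic data generators mirroring the study's input structure.

Every pipeline stage can be exercised without downloading sequencing data:
the generators emit exactly the dialects the other modules read (genome
FASTA + gene table, counts TSV, DE tables, assay records) together with a
machine-readable truth record, and are deterministic given a seed.

What is emulated, and how:

* ``gen_genome`` — synthetic contigs with genes on both strands whose
  upstream windows are rejection-sampled to be free of all configured
  motifs before instances are planted, so scanner hit counts equal
  planting counts exactly.  Background base composition defaults to
  uniform 25% each; an AT-rich option mimics the C. elegans genome for
  stress-testing pattern specificity.
* ``gen_counts`` — per-gene read counts with negative-binomial replicate
  noise over a genotypes x conditions x replicates design (default
  2 x 2 x 4), planted up/down-regulated genes, and a truth DE table.
* ``gen_association`` — a DE-down gene set correlated with motif presence
  at a configured odds ratio, for calibrating the enrichment test.
* ``gen_assay`` — multinomial worm placement whose expected index equals
  a strain's attraction parameter theta in [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import SectorCounts, SpotCounts
from .expression import ExpressionMatrix
from .genesets import GeneSet
from .motifs import Choice, Gap, Literal, MotifPattern, scan_sequence
from .regions import GeneModel, revcomp

BASES = "ACGT"
UNIFORM = (0.25, 0.25, 0.25, 0.25)
# C. elegans-like AT-rich composition (~65% AT)
AT_RICH = (0.325, 0.175, 0.175, 0.325)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_motif_positions: dict = field(default_factory=dict)
    de_labels: dict = field(default_factory=dict)
    association_table: dict = field(default_factory=dict)
    assay_params: dict = field(default_factory=dict)

    def gene_set(self, pattern_name: str) -> set:
        """Genes carrying >= 1 planted instance of the named pattern."""
        return {g for g, hits in self.planted_motif_positions.items()
                if any(p == pattern_name for p, _, _ in hits)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "seed": self.seed,
                "params": self.params,
                "planted_motif_positions": self.planted_motif_positions,
                "de_labels": self.de_labels,
                "association_table": self.association_table,
                "assay_params": self.assay_params,
            }, fh, indent=1, sort_keys=True)


def _random_seq(rng, length, probs=UNIFORM) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def sample_motif_instance(pattern: MotifPattern, rng) -> str:
    """Draw a uniform member of the pattern's language: Choice positions
    and spacer lengths/bases uniform."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    parts = []
    for b in pattern.blocks:
        if isinstance(b, Literal):
            parts.append(b.seq)
        elif isinstance(b, Choice):
            parts.append(rng.choice(sorted(b.bases)))
        elif isinstance(b, Gap):
            g = int(rng.integers(b.min, b.max + 1))
            parts.append(_random_seq(rng, g))
    return "".join(parts)


# -- genome with planted motifs ----------------------------------------------

def _motif_free_background(rng, length, patterns, probs, max_tries=1000) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length, probs)
        if all(not scan_sequence(p, seq) for p in patterns):
            return seq
    raise RuntimeError(
        "could not sample a motif-free background in "
        f"{max_tries} tries; patterns too permissive for this background — "
        "use a more skewed base composition or shorter windows")


def gen_genome(n_genes: int,
               patterns: Sequence[MotifPattern] = (),
               plan: Mapping | None = None,
               window: int = 500,
               body_len: int = 60,
               spacer_len: int = 20,
               base_probs=UNIFORM,
               genes_per_contig: int = 100,
               seed: int = 0):
    """Generate (genome dict, gene models, SyntheticTruth).

    ``plan`` maps a pattern name — or a tuple of names for co-planting,
    e.g. the DAF-3 site plus the MSP motif in the same window for a full
    PD motif — to either a fraction of genes or an absolute gene count.
    The chosen gene subsets are disjoint across plan entries, so truth
    labels are exact.  Backgrounds are rejection-sampled until free of
    every configured pattern (cap 1000 tries per region).
    """
    rng = np.random.default_rng(seed)
    plan = dict(plan or {})
    by_name = {p.name: p for p in patterns}
    if window < max((p.max_len for p in patterns), default=1):
        raise ValueError("window shorter than the longest pattern")

    # resolve plan into disjoint gene-index subsets
    assignments: dict = {}  # gene index -> tuple of pattern names
    pool = list(range(n_genes))
    rng.shuffle(pool)
    cursor = 0
    for key, amount in plan.items():
        names = (key,) if isinstance(key, str) else tuple(key)
        for nm in names:
            if nm not in by_name:
                raise ValueError(f"plan names unknown pattern {nm!r}")
        count = int(round(amount * n_genes)) if isinstance(amount, float) else int(amount)
        if cursor + count > n_genes:
            raise ValueError("plan assigns more genes than exist")
        for gi in pool[cursor:cursor + count]:
            assignments[gi] = names
        cursor += count

    truth = SyntheticTruth(seed=seed, params={
        "n_genes": n_genes, "window": window,
        "plan": {("+".join(k) if isinstance(k, tuple) else k): v
                 for k, v in plan.items()},
    })
    genome: dict = {}
    genes: list = []
    contig_parts: list = []
    cursor_pos = 0
    contig_idx = 0

    def contig_name():
        return f"chrS{contig_idx + 1}"

    for gi in range(n_genes):
        gene_id = f"g{gi + 1:05d}"
        strand = "+" if rng.integers(2) == 0 else "-"
        background = _motif_free_background(rng, window, patterns, base_probs)
        to_plant = [by_name[nm] for nm in assignments.get(gi, ())]
        if to_plant:
            region_seq, spans = _plant_verified(rng, background, to_plant, patterns)
            truth.planted_motif_positions[gene_id] = [
                (nm, s, inst) for s, _e, nm, inst in spans]
        else:
            region_seq = background
        body = "ATG" + _random_seq(rng, body_len - 3, base_probs)
        spacer = _random_seq(rng, spacer_len, base_probs)
        if strand == "+":
            segment = spacer + region_seq + body
            atg = cursor_pos + len(spacer) + window
        else:
            segment = spacer + revcomp(body) + revcomp(region_seq)
            atg = cursor_pos + len(spacer) + len(body) - 1
        contig_parts.append(segment)
        cursor_pos += len(segment)
        genes.append(GeneModel(gene_id, contig_name(), strand, atg, body_len))
        if (gi + 1) % genes_per_contig == 0 or gi == n_genes - 1:
            genome[contig_name()] = "".join(contig_parts)
            contig_parts, cursor_pos = [], 0
            contig_idx += 1
    return genome, genes, truth


def _plant_verified(rng, background, to_plant, all_patterns, max_tries=1000):
    """Plant instances then verify the final region scans to exactly the
    planted positions for every configured pattern; retry on junction
    artifacts."""
    L = len(background)
    for _ in range(max_tries):
        spans = []
        region = list(background)
        ok = True
        for p in to_plant:
            inst = sample_motif_instance(p, rng)
            placed = False
            for _ in range(50):
                off = int(rng.integers(0, L - len(inst) + 1))
                if all(off + len(inst) <= s or off >= e for s, e, _n, _i in spans):
                    placed = True
                    break
            if not placed:
                ok = False
                break
            spans.append((off, off + len(inst), p.name, inst))
            region[off:off + len(inst)] = inst
        if not ok:
            continue
        seq = "".join(region)
        expected = {}
        for _s, _e, nm, _inst in spans:
            expected.setdefault(nm, set()).add(_s)
        clean = True
        for p in all_patterns:
            found = {h.offset for h in scan_sequence(p, seq)}
            if found != expected.get(p.name, set()):
                clean = False
                break
        if clean:
            return seq, sorted(spans)
    raise RuntimeError("could not place motif instances without junction artifacts")


def write_genome_fasta(genome: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\tstrand\tatg_pos\tlength_nt\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.atg_pos}\t"
                     f"{g.length_nt if g.length_nt is not None else 0}\n")


# -- RNA-Seq counts -----------------------------------------------------------

def gen_counts(n_genes: int = 6000,
               genotypes: Sequence[str] = ("wt", "mut"),
               conditions: Sequence[str] = ("con", "pd"),
               n_replicates: int = 4,
               n_up: int = 116,
               n_down: int = 595,
               fold_change: float = 4.0,
               dispersion: float = 0.1,
               mean_log_mu: float = 4.0,
               mean_log_sigma: float = 1.5,
               length_range=(500, 3000),
               libsize_range=(0.8, 1.2),
               de_genotype: str = "wt",
               de_condition: str = "pd",
               seed: int = 0):
    """Negative-binomial counts over a genotypes x conditions x replicates
    design with planted differential expression.

    Baseline per-gene means are log-normal; planted genes have their mean
    multiplied (up) or divided (down) by ``fold_change`` in
    ``de_genotype``/``de_condition``; every sample's means are scaled by a
    library-size factor drawn uniformly from ``libsize_range``.  Returns
    (ExpressionMatrix, truth DE table, SyntheticTruth); the truth table's
    FDR values place exactly the planted genes under the conventional 0.05
    cutoff.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if n_up + n_down > n_genes:
        raise ValueError("more DE genes planted than genes exist")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{str(i + 1).zfill(5)}" for i in range(n_genes)]
    lengths = pd.Series(rng.integers(length_range[0], length_range[1] + 1,
                                     size=n_genes), index=gene_ids,
                        name="length_nt")
    base_mu = np.exp(rng.normal(mean_log_mu, mean_log_sigma, size=n_genes))
    perm = rng.permutation(n_genes)
    up_idx, down_idx = perm[:n_up], perm[n_up:n_up + n_down]

    labels, cols = {}, {}
    nb_n = 1.0 / dispersion  # NB: var = mu + dispersion * mu^2
    for gt in genotypes:
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                name = f"{gt}.{cond}.r{rep}"
                labels[name] = (gt, cond, f"r{rep}")
                mu = base_mu.copy()
                if gt == de_genotype and cond == de_condition:
                    mu[up_idx] *= fold_change
                    mu[down_idx] /= fold_change
                mu = mu * rng.uniform(*libsize_range)
                cols[name] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    counts = pd.DataFrame(cols, index=gene_ids)
    matrix = ExpressionMatrix(counts, lengths, labels)

    direction = np.array(["null"] * n_genes, dtype=object)
    direction[up_idx], direction[down_idx] = "up", "down"
    fdr = rng.uniform(0.05, 1.0, size=n_genes)
    de_mask = direction != "null"
    fdr[de_mask] = rng.uniform(0.0, 0.0499, size=de_mask.sum())
    de_table = pd.DataFrame({
        "gene_id": gene_ids,
        "direction": np.where(de_mask, direction, "up"),  # token for nulls, filtered by fdr
        "fdr": fdr,
    })
    truth = SyntheticTruth(seed=seed, params={
        "n_genes": n_genes, "n_up": n_up, "n_down": n_down,
        "fold_change": fold_change, "dispersion": dispersion,
        "design": f"{len(genotypes)}x{len(conditions)}x{n_replicates}",
    })
    truth.de_labels = {gene_ids[i]: "up" for i in up_idx}
    truth.de_labels.update({gene_ids[i]: "down" for i in down_idx})
    return matrix, de_table, truth


# -- motif/DE association ------------------------------------------------------

def solve_joint_probability(m: float, d: float, odds_ratio: float) -> float:
    """P(motif AND down) given marginals (m, d) and an odds ratio.

    Solves OR * (m - p)(d - p) = p (1 - m - d + p) for the root inside the
    Frechet bounds [max(0, m + d - 1), min(m, d)].
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    lo, hi = max(0.0, m + d - 1.0), min(m, d)
    if odds_ratio == 1.0:
        p = m * d
    else:
        a = odds_ratio - 1.0
        b = -(odds_ratio * (m + d) + (1.0 - m - d))
        c = odds_ratio * m * d
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("infeasible marginals/odds ratio")
        r1 = (-b - np.sqrt(disc)) / (2 * a)
        r2 = (-b + np.sqrt(disc)) / (2 * a)
        cands = [r for r in (r1, r2) if lo - 1e-12 <= r <= hi + 1e-12]
        if not cands:
            raise ValueError("infeasible marginals/odds ratio")
        p = min(max(cands[0], lo), hi)
    return float(p)


def gen_association(universe_size: int,
                    motif_fraction: float,
                    down_fraction: float,
                    odds_ratio: float,
                    seed: int = 0):
    """(population, motif GeneSet, DE-down GeneSet, SyntheticTruth) with
    the configured motif/DE-down odds ratio.

    The motif set has exact size round(universe * motif_fraction); down
    membership is Bernoulli at the conditional rates implied by the joint
    probability, and the realised 2x2 table is recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    N = universe_size
    p11 = solve_joint_probability(motif_fraction, down_fraction, odds_ratio)
    ids = np.array([f"g{str(i + 1).zfill(5)}" for i in range(N)])
    n_motif = int(round(N * motif_fraction))
    motif_mask = np.zeros(N, dtype=bool)
    motif_mask[rng.choice(N, size=n_motif, replace=False)] = True
    p_down_motif = p11 / motif_fraction
    p_down_other = (down_fraction - p11) / (1.0 - motif_fraction)
    u = rng.uniform(size=N)
    down_mask = np.where(motif_mask, u < p_down_motif, u < p_down_other)
    truth = SyntheticTruth(seed=seed, params={
        "universe": N, "motif_fraction": motif_fraction,
        "down_fraction": down_fraction, "odds_ratio": odds_ratio,
    })
    truth.association_table = {
        "motif_down": int((motif_mask & down_mask).sum()),
        "motif_only": int((motif_mask & ~down_mask).sum()),
        "down_only": int((~motif_mask & down_mask).sum()),
        "neither": int((~motif_mask & ~down_mask).sum()),
    }
    population = GeneSet("population", frozenset(ids))
    motif_set = GeneSet("motif", frozenset(ids[motif_mask]))
    down_set = GeneSet("de_down", frozenset(ids[down_mask]))
    return population, motif_set, down_set, truth


# -- behavioral assays ---------------------------------------------------------

def gen_assay(theta: float, n_worms: int, assay: str = "avoidance",
              lingering: float = 0.0, seed: int = 0):
    """Simulate one assay trial for a strain with attraction parameter
    theta in [-1, 1]; the expected index is (1 - lingering) * theta.

    Six-sector model: probability mass (1+theta)/2 split evenly over
    sectors A,B and (1-theta)/2 over E,F, with ``lingering`` mass
    redistributed to the central sectors C,D.  Two-spot model: each worm
    reaches the attractant with probability (1+theta)/2.
    """
    if not -1.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [-1, 1]")
    if not 0.0 <= lingering < 1.0:
        raise ValueError("lingering must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if assay == "avoidance":
        stim = (1.0 - lingering) * (1.0 + theta) / 2.0
        ctrl = (1.0 - lingering) * (1.0 - theta) / 2.0
        probs = [stim / 2, stim / 2, lingering / 2, lingering / 2,
                 ctrl / 2, ctrl / 2]
        a, b, c, d, e, f = rng.multinomial(n_worms, probs)
        return SectorCounts(int(a), int(b), int(c), int(d), int(e), int(f))
    if assay == "chemotaxis":
        n_att = int(rng.binomial(n_worms, (1.0 + theta) / 2.0))
        return SpotCounts(n_att, n_worms - n_att, n_worms)
    raise ValueError(f"unknown assay type {assay!r}")
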
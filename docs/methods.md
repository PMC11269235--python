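# Methods

This note documents the models, conventions and numerical choices behind
`postdauer`, and what the synthetic-data generators do and do not emulate.

## Upstream region extraction

A gene's regulatory window is the `window` bases (default 500) immediately
5′ of the A of its ATG start codon, excluding the codon itself. Internally
all coordinates are 0-based half-open; GFF3 is read as 1-based inclusive
(the start-codon position is the 5′-most CDS base for + strand genes, the
3′-most for − strand genes) and BED is written 0-based half-open. For
− strand genes the window covers `[atg_pos+1, atg_pos+1+window)` on the +
strand and the sequence is reverse complemented, so every returned region
reads 5′→3′ toward the ATG. Windows shortened by a contig edge are flagged
`truncated`; a gene with zero upstream bases raises an error distinct from
truncation. Neighboring genes are not masked out of each other's windows,
and annotated 5′UTRs are not consulted — the window length is the only
knob. Bases outside A/C/G/T are normalised to N.

## Motif grammar and matching

Patterns are compiled from a small notation: literal bases; one-position
choice sets `[AT]` or `[A/T]`; IUPAC codes S/W/Y/R; bounded spacers
`N(min,max)` or `N_min-max` (a bare `N` is a spacer of exactly one base).
A pattern may not begin or end with a spacer; adjacent spacers are
coalesced. `min_len`/`max_len` are the sums of fixed block lengths plus
spacer minima/maxima — for the MSP motif, 25 and 30 bp.

A pattern matches at a position iff some spacer-length assignment aligns
every fixed position to an equal base. Design choices:

* **Leftmost-shortest assignment.** When several spacer assignments match
  at one start, the lexicographically smallest is reported, and each start
  position yields at most one hit (overlapping starts all reported). This
  makes copy-number statements ("1 to 3 E-boxes") deterministic without
  double-counting spacer variants.
* **N never matches.** An ambiguous genome base satisfies no pattern
  position, spacers included, so assembly gaps cannot fabricate motifs.
* **Forward-strand default.** Extracted regions are already
  transcription-oriented; `both_strands=True` additionally scans the
  reverse complement and reports those hits in reverse-complement
  coordinates. For palindromic patterns (e.g. `CACGTG`) a forward and a
  reverse hit can denote the same locus; deduplication is the caller's
  choice.
* **Full PD motif = presence of both components** (DAF-3 site and MSP
  motif) anywhere in the window, with no spacing or ordering constraint —
  the classification is a list intersection, not a composite spaced
  pattern.

The scanner is validated against an independent exhaustive matcher that
enumerates every spacer assignment, on 10⁴ random pattern/sequence pairs
plus hypothesis-generated cases.

## Set statistics

Report percentages (`100·k/n`) and Jaccard similarities
(`100·k/(|A|+|B|−k)`) are computed in exact rational arithmetic and
rounded half-away-from-zero at the requested decimals; this reproduces
every published figure checked in the tests (62, 81, 24.6, 43, 77.7,
87.5, 32.7, 14.9, 90) from the corresponding integer counts.

Enrichment uses the one-sided hypergeometric tail. Tail terms are exact
integer binomial ratios whose log10 is computed from a 64-bit-quotient
reduction (`log10(num/den) = log10((num≪s)//den) − s·log10 2`), then summed
in log10 space. This keeps p-values finite and accurate far below double
underflow: with a population of 20 000 genes the implementation reproduces,
to the printed three significant digits, published overlap p-values down to
4.07×10⁻³⁹³⁹, and the pmf it implies sums to 1 within 10⁻¹² up to
N = 10⁴ (checked against exact fractions and 50-digit arithmetic).
Conventions: enriched overlaps (k ≥ n·K/N) report P[X ≥ k] and fold
observed/expected; depleted overlaps report P[X ≤ k] and fold
expected/observed (the "x-fold under enriched" reading). The population is
always an explicit argument — p-values at these magnitudes are extremely
sensitive to it, so there is no silent default. `p_display` renders
mantissa/exponent from the log without exponentiating.

The dependence partition classifies a wild-type DE gene as *dependent* on
the mutated factor when it is absent from the mutant's same-direction DE
list; the headline percentage is (dependent up + dependent down) / all
wild-type DE genes.

## Expression

RPKM is `counts·10⁹/(length_nt·total_reads)` with per-sample totals
defaulting to column sums. A gene is expressed in a condition when the
*mean* RPKM over that condition's replicates meets the threshold
(default ≥ 10; the ≥/> choice is configurable and immaterial for
continuous data, and the mean is the conventional replicate summary).
DE testing is deliberately out of scope: DE tables (gene, direction, FDR)
are consumed and filtered at strict FDR < 0.05.

## Behavioral indices

Avoidance index `((A+B) − (E+F))/N` over all six sectors (central-sector
worms stay in N), chemotaxis index `(attractant − control)/total`,
reversal fraction `reversed/tested`. The avoidance formula is often
typeset ambiguously; this reading is the only one that yields a bounded,
dimensionless index and matches the convention that negative values mean
avoidance of the sector-A stimulus. Trials are the unit of aggregation
(mean ± SD per strain); significance testing is left to standard tools.

## Synthetic data: what it emulates

The generators produce statistically structured stand-ins for the study's
raw inputs, with ground truth emitted alongside and byte-identical
regeneration from a seed.

* **Genomes** (`gen_genome`): genes on both strands, each with an upstream
  window rejection-sampled until free of every configured pattern (cap
  1000 tries), then planted with sampled motif instances at
  non-overlapping offsets and re-verified so scanner hits equal planted
  positions exactly. The plan maps a pattern name (or tuple of names, for
  co-planting a full PD motif) to a gene count or fraction; plan subsets
  are disjoint, so truth labels are exact. Background composition defaults
  to uniform 25%; an AT-rich option (65% AT, like the *C. elegans*
  genome) stress-tests specificity of the AT-heavy MSP pattern. Gene
  bodies are short (60 nt) since only upstream windows are analysed.
* **Counts** (`gen_counts`): negative-binomial counts (variance
  μ + αμ², default dispersion α = 0.1, a typical bulk-RNA-Seq value) over
  a 2 genotypes × 2 conditions × 4 replicates design — four biological
  replicates per strain/condition mirroring the study design — with
  log-normal baseline means, planted fold-changes (default 4) in one
  genotype/condition, uniform library-size factors (0.8–1.2), and default
  planted DE counts 116 up / 595 down of 6000 genes, the study's DE-set
  sizes. The truth DE table's FDR values place exactly the planted genes
  under the 0.05 cutoff.
* **Associations** (`gen_association`): the motif/DE-down joint
  probability solves the 2×2 table for the configured marginals and odds
  ratio (quadratic root inside the Fréchet bounds); the motif set has
  exact size, down membership is Bernoulli at the implied conditional
  rates, and the realised table is recorded.
* **Assays** (`gen_assay`): multinomial placement with sector mass
  (1+θ)/2 on A,B and (1−θ)/2 on E,F so the expected index equals the
  strain's attraction parameter θ; an optional `lingering` parameter moves
  mass to the central sectors to test index robustness.

What this does **not** emulate: read-level sequencing (FASTQ), alignment
and counting, FACS contamination or ambient RNA, real promoter base
composition and motif clustering, or correlated replicate structure.
Passing tests therefore demonstrate correctness of the analysis logic
under the stated statistical assumptions, not performance on real
sequencing artefacts.

## Problem sizes and determinism

The test suite and acceptance script run in seconds: planted-recovery
uses 500 genes × 500 bp windows, scanner/oracle equivalence 10⁴ random
cases (sequences ≤ 60 bp), hypergeometric validation the full N ≤ 25 grid
plus N = 10⁴ normalisation and N = 2×10⁴ deep tails, association
calibration 20 seeds at a 5000-gene universe, and assay recovery 10⁴
worms (binomial SD ≈ 0.01, tolerance 0.03). Stochastic checks derive
their child seeds from one base seed via `numpy.random.SeedSequence`;
every generator is deterministic given its seed.

## Known limitations

* GFF3 ingestion collapses a gene to a single start codon (5′-most/3′-most
  CDS); isoforms with distinct start sites are not resolved.
* Under-enrichment fold (expected/observed) is one convention among
  several; it is recorded in output metadata.
* The rejection-sampling generator errors out, by design, when a pattern
  is so permissive that motif-free backgrounds are improbable; use a more
  skewed composition or a "natural background" workflow in that case.
* The pipeline's default enrichment population (union of observed sets,
  used only when no population list is supplied) is a conservative
  fallback and is logged as such; extreme-tail p-values should always be
  computed against an explicit population.
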
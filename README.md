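# postdauer

Regulatory-genomics and behavioral analysis toolkit for *C. elegans*
post-dauer neuron transcriptomics.

Passage through the stress-induced dauer larval stage leaves lasting marks
on the adult nervous system: in the ADL chemosensory neurons, hundreds of
genes — including, unexpectedly, germline *major sperm protein* (*msp*)
genes — are differentially expressed in post-dauer adults, much of it
dependent on the somatic nuclear RNAi Argonaute NRDE-3, and the
downregulated genes are enriched for a composite upstream element (the
"PD motif": a DAF-3/SMAD site `GTCTA` plus a ~30 bp conserved "MSP
motif"). This package implements the computational side of that kind of
study as a reusable, tested pipeline:

* **`postdauer.regions`** — strand-aware extraction of the window
  (default 500 bp) immediately 5′ of each gene's ATG, from a genome FASTA
  plus a GFF3 or simple gene table; BED6/FASTA output.
* **`postdauer.motifs`** — a compiler and scanner for degenerate gapped
  motif patterns written as literals, choice sets `[AT]`, IUPAC codes and
  bounded spacers `N(0,3)`; e.g. the MSP motif
  `CT[AT]TAA[AT]TTN(0,3)[AC]AN(0,2)TTTTG[CT]CATAA[TA]C[TC]`
  (25–30 bp). Matching is exact (no heuristics), with deterministic
  leftmost-shortest spacer resolution, and genes are classified by
  DAF-3-site / MSP-motif / full-PD-motif content.
* **`postdauer.genesets`** — set overlap counts, query percentages and
  Jaccard similarities with exact-rational rounding; one-sided
  hypergeometric enrichment computed in log10 space from exact integer
  binomials, so p-values of magnitude 10⁻³⁰⁰⁰ remain finite and accurate;
  the wild-type-vs-mutant DE dependence partition.
* **`postdauer.expression`** — RPKM
  (`counts · 10⁹ / (length_nt · total_reads)`), expressed-gene calls at a
  mean-RPKM cutoff (default ≥ 10), and FDR-filtered DE gene sets.
* **`postdauer.behavior`** — six-sector avoidance index
  `((A+B) − (E+F))/N`, two-spot chemotaxis index
  `(attractant − control)/total`, drop-test reversal fractions, and
  per-strain trial summaries.
* **`postdauer.synth`** — seeded generators for every input the pipeline
  reads: genomes with motif instances planted on rejection-sampled
  motif-free backgrounds (scanner counts equal planting counts exactly),
  negative-binomial RNA-Seq counts with planted DE genes, motif/DE
  associations at a configured odds ratio, and multinomial assay trials.
* **`postdauer.pipeline` / the `postdauer` CLI** — the composed analysis
  with YAML config, input-hash manifest and plain-text reports.

## Worked example

```python
>>> from postdauer import jaccard_percent, log_hypergeom_sf, percent_of_query
>>> from postdauer.genesets import p_display
>>> percent_of_query(3652, 5908, 0)   # CeNGEN overlap, % of 5908-gene control list
62.0
>>> jaccard_percent(5908, 6001, 5206, 1)  # wild-type vs nrde-3 control transcriptomes
77.7
>>> p_display(log_hypergeom_sf(4779, 5908, 8436, 20000))
'9.75e-1161'
```

62% of the control ADL transcriptome is shared with the CeNGEN reference,
the wild-type and *nrde-3* control transcriptomes are 77.7% similar
(intersection over union), and the 4779-gene overlap with an 8436-gene
pan-neuronal list in a 20000-gene population is significant at
p ≈ 10⁻¹¹⁶¹ — a magnitude only representable because the tail is summed in
log space.

Motif scanning on a synthetic genome (see `examples/02_motif_scan.py`):

```text
MSP motif spans 25-30 bp (2 variable spacers)
  daf3 : offset   7, length 5, spacers ()
  msp  : offset  18, length 30, spacers (3, 2)
  ebox : offset  51, length 6, spacers ()
full PD motif present: True
```

The `examples/` directory has one short script per capability
(region extraction, motif scanning, set statistics, expression calls,
behavior indices, the full pipeline); each prints the numbers it computes
and a line on what they mean. The same stages are available from the
shell: `postdauer regions|scan|express|enrich|behave|synth|run --help`.

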
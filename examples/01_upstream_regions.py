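"""Extract strand-aware upstream regulatory windows from a genome.

Builds a two-gene toy genome (one gene per strand), extracts the 20 bp
immediately 5' of each ATG, and prints the regions.  Minus-strand windows
come back reverse complemented, i.e. already in the gene's reading
direction, which is what a motif scanner wants.
"""

from postdauer import GeneModel, extract_upstream

plus_upstream = "GATTACAGATTACAGATTAC"
minus_upstream = "CCCGGGTTTAAACCCGGGTT"
genome = {"chrT": plus_upstream + "ATG" + "CAT" +  # minus-strand gene body 'CAT' = revcomp(ATG)
          "".join(reversed([{"A": "T", "C": "G", "G": "C", "T": "A"}[c]
                            for c in minus_upstream]))}

plus = GeneModel("gene_plus", "chrT", "+", atg_pos=20)
minus = GeneModel("gene_minus", "chrT", "-", atg_pos=25)

for gene in (plus, minus):
    r = extract_upstream(gene, genome, window=20)
    print(f"{r.gene_id}: {r.chrom}:{r.start}-{r.end} ({r.strand}) "
          f"truncated={r.truncated}\n  {r.seq}")

# gene_plus returns the 20 bp as written; gene_minus returns the reverse
# complement of the genomic slice 3' of its (minus-strand) start codon —
# both sequences read 5'->3' toward the ATG.
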
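"""RPKM normalisation and expressed/DE gene calling on simulated counts.

Simulates a 2 genotypes x 2 conditions x 4 replicates RNA-Seq design with
planted differential expression, then calls expressed genes at the 10-RPKM
cutoff and splits the truth DE table at FDR < 0.05.
"""

from postdauer import call_expressed, de_sets, rpkm
from postdauer.synth import gen_counts

matrix, de_table, truth = gen_counts(n_genes=2000, n_up=30, n_down=80, seed=4)
r = rpkm(matrix.counts, matrix.lengths_nt)

for genotype in ("wt", "mut"):
    for condition in ("con", "pd"):
        es = call_expressed(r, matrix.samples_for(genotype, condition),
                            threshold=10.0, condition=f"{genotype}.{condition}")
        print(f"{es.condition}: {len(es.members)} genes at mean RPKM >= 10")

up, down = de_sets(de_table, fdr_cutoff=0.05)
print(f"DE sets from truth table: {len(up)} up, {len(down)} down "
      f"(planted: 30 up, 80 down)")
# Expressed-set sizes vary with the simulated library; the DE-set sizes
# equal the planted counts exactly because the truth table's FDR values
# place planted genes (and only those) under the cutoff.
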
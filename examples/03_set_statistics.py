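"""Gene-set overlap statistics: percentages, Jaccard, dependence partition
and log-space hypergeometric p-values.

Uses the published ADL transcriptome set sizes as inputs and shows that
the report functions reproduce the published figures, including p-values
whose magnitudes (1e-514 and below) underflow ordinary doubles.
"""

from postdauer import (GeneSet, dependence_partition, jaccard_percent,
                       log_hypergeom_sf, percent_of_query)
from postdauer.genesets import p_display

# 5908 control-expressed genes, 3652 shared with the 7217-gene CeNGEN ADL list
print("CeNGEN overlap:", percent_of_query(3652, 5908, 0), "% of control list")

# wild-type (5908) vs nrde-3 (6001) control transcriptomes, 5206 shared
print("transcriptome similarity:", jaccard_percent(5908, 6001, 5206, 1), "%")

# hypergeometric significance of the pan-neuronal overlap in a population
# of 20000 protein-coding genes, computed entirely in log10 space
lp = log_hypergeom_sf(4779, 5908, 8436, 20000)
print(f"pan-neuronal overlap: log10 p = {lp:.2f} (p = {p_display(lp)})")

# dependence partition: which wild-type DE genes need the mutated factor
wt_up = GeneSet("wt_up", frozenset(f"u{i}" for i in range(116)))
mut_up = GeneSet("mut_up", frozenset(
    [f"u{i}" for i in range(15)] + [f"mu{i}" for i in range(81)]))
wt_down = GeneSet("wt_down", frozenset(f"d{i}" for i in range(595)))
mut_down = GeneSet("mut_down", frozenset(
    [f"d{i}" for i in range(53)] + [f"md{i}" for i in range(52)]))
part = dependence_partition(wt_up, wt_down, mut_up, mut_down)
print(f"dependent: {len(part.dependent_up)} up + {len(part.dependent_down)} "
      f"down = {part.percent_dependent:.0f}% of all wild-type DE genes")
# 101 + 542 of 711 wild-type DE genes lose their differential expression in
# the mutant, i.e. 90% are dependent on the mutated pathway.
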
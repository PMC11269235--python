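"""Scan upstream sequence for the PD-motif components and E-boxes.

The PD motif is a composite regulatory element: a DAF-3/SMAD binding site
(GTCTA) plus a ~30 bp conserved "MSP motif" with two bounded spacers.  A
gene carries the full PD motif when its upstream region contains both.
"""

from postdauer import compile_pattern, daf3_pattern, msp_pattern, scan_sequence
from postdauer.motifs import classify_pd_status
from postdauer.regions import UpstreamRegion

daf3, msp = daf3_pattern(), msp_pattern()
print(f"MSP motif spans {msp.min_len}-{msp.max_len} bp "
      f"({len(msp.gap_bounds)} variable spacers)")

# an osm-9-like upstream region: DAF-3 site, then an MSP-motif instance
# with spacer lengths (3, 2), then an ADL E-box
seq = ("TTGACCA" + "GTCTA" + "AACCTT"
       + "CTTTAATTTGGGCAGGTTTTGTCATAAACC"
       + "GGA" + "CAGCTG" + "TTACG")

for pat in (daf3, msp, compile_pattern("CASCTG", name="ebox")):
    for hit in scan_sequence(pat, seq):
        print(f"  {pat.name:5s}: offset {hit.offset:3d}, length {hit.length}, "
              f"spacers {hit.gap_lengths}")

region = UpstreamRegion("osm-9-like", "chrT", 0, len(seq), "+", seq, True)
status = classify_pd_status([region], daf3, msp)[0]
print(f"full PD motif present: {status.has_full_pd}")
# Both components are found, so the gene would join the full-PD gene list
# that the downstream enrichment stage compares against DE genes.
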
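"""Strand-aware extraction of upstream regulatory regions.

A gene's regulatory window is the stretch of sequence immediately 5' of the
A of its ATG start codon, by default 500 bp, read in the direction of
transcription (so minus-strand windows are reverse complemented).  The ATG
itself is never included.  Windows truncated by a contig edge are flagged;
a gene with zero available upstream bases is an error, not a truncation.

Coordinates are 0-based half-open internally; GFF3 is read as 1-based
inclusive and BED is written 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase; any base outside ACGT becomes N."""
    seq = seq.upper()
    if set(seq) <= set("ACGT"):
        return seq
    return "".join(c if c in "ACGT" else "N" for c in seq)


@dataclass(frozen=True)
class GeneModel:
    """One gene: where its start codon sits and which strand it reads."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    atg_pos: int  # 0-based genomic coordinate of the first base of ATG
    length_nt: int | None = None  # transcript length, needed for RPKM only

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.atg_pos < 0:
            raise ValueError(f"{self.gene_id}: atg_pos must be >= 0")


@dataclass(frozen=True)
class UpstreamRegion:
    """An extracted upstream window with its genomic provenance.

    ``start``/``end`` delimit the half-open interval on the + strand of
    ``chrom``; ``seq`` is already transcription-oriented (reverse
    complemented for minus-strand genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    truncated: bool

    def __len__(self):
        return len(self.seq)


class AnnotationResult(NamedTuple):
    genes: list
    n_rejected: int


def read_annotation(path, dialect: str = "gene-table") -> AnnotationResult:
    """Read gene models from a GFF3 file or a simple gene table.

    The gene table has 4 or 5 whitespace-separated columns:
    gene_id, chrom, strand, atg_pos (0-based), [length_nt].
    For GFF3, the start-codon position is derived from CDS features:
    the 5'-most CDS base for + strand genes, the 3'-most for - strand.
    Records missing strand or coordinates are dropped with a warning and
    counted in ``n_rejected``; a duplicated gene_id is a hard error.
    """
    if dialect == "gene-table":
        return _read_gene_table(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _check_unique(genes):
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id in annotation: {g.gene_id}")
        seen.add(g.gene_id)


def _read_gene_table(path) -> AnnotationResult:
    genes, rejected = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4 or parts[2] not in ("+", "-"):
                log.warning("rejecting gene-table line %d: %r", lineno, line)
                rejected += 1
                continue
            try:
                atg = int(parts[3])
                length = int(parts[4]) if len(parts) > 4 else None
            except ValueError:
                log.warning("rejecting gene-table line %d: %r", lineno, line)
                rejected += 1
                continue
            genes.append(GeneModel(parts[0], parts[1], parts[2], atg, length))
    _check_unique(genes)
    return AnnotationResult(genes, rejected)


def _read_gff3(path) -> AnnotationResult:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes, rejected = [], 0
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds or gene.strand not in ("+", "-"):
            log.warning("rejecting gene %s: missing CDS or strand", gene.id)
            rejected += 1
            continue
        if gene.strand == "+":
            atg = min(c.start for c in cds) - 1  # 1-based inclusive -> 0-based
        else:
            atg = max(c.end for c in cds) - 1
        length = sum(c.end - c.start + 1 for c in cds)
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, atg, length))
    _check_unique(genes)
    return AnnotationResult(genes, rejected)


def extract_upstream(gene: GeneModel, genome: Mapping[str, str],
                     window: int = 500) -> UpstreamRegion:
    """Extract the upstream window for one gene.

    + strand: covers [max(0, atg_pos - window), atg_pos), as written.
    - strand: covers [atg_pos + 1, min(L, atg_pos + 1 + window)), reverse
    complemented.  Raises KeyError for an unknown contig and ValueError
    when no upstream base exists at all (distinct from mere truncation).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if gene.chrom not in genome:
        raise KeyError(f"{gene.gene_id}: contig {gene.chrom!r} not in genome")
    contig = genome[gene.chrom]
    L = len(contig)
    if not 0 <= gene.atg_pos < L:
        raise ValueError(f"{gene.gene_id}: atg_pos {gene.atg_pos} outside contig "
                         f"{gene.chrom} of length {L}")
    if gene.strand == "+":
        start, end = max(0, gene.atg_pos - window), gene.atg_pos
    else:
        start, end = gene.atg_pos + 1, min(L, gene.atg_pos + 1 + window)
    if end <= start:
        raise ValueError(f"{gene.gene_id}: no upstream sequence available "
                         f"(gene at contig edge)")
    raw = normalize(str(contig[start:end]))
    seq = raw if gene.strand == "+" else revcomp(raw)
    return UpstreamRegion(gene.gene_id, gene.chrom, start, end, gene.strand,
                          seq, truncated=(end - start < window))


def extract_all(genes: Sequence[GeneModel], genome: Mapping[str, str],
                window: int = 500) -> list:
    return [extract_upstream(g, genome, window) for g in genes]


def read_genome(path) -> dict:
    """Load a FASTA into a contig-name -> sequence-string dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_regions(regions: Sequence[UpstreamRegion], fasta_out, bed_out) -> None:
    """Write regions as FASTA (headers = gene_ids) and BED6 (genomic,
    0-based half-open, strand in column 6)."""
    if not regions:
        raise ValueError("no regions to write")
    with open(fasta_out, "w") as fa:
        for r in regions:
            fa.write(f">{r.gene_id}\n{r.seq}\n")
    with open(bed_out, "w") as bed:
        for r in regions:
            bed.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_regions_fasta(path) -> list:
    """Read a regions FASTA back as minimal UpstreamRegion objects (no
    genomic provenance: start/end are 0/len, strand '+')."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize(str(rec.seq))
        out.append(UpstreamRegion(rec.id, rec.id, 0, len(seq), "+", seq,
                                  truncated=len(seq) < 500))
    return out
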
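"""End-to-end orchestration: config validation and the composed analysis.

A run strings the stages together the way the study's results are laid
out: expressed-gene sets per genotype/condition at an RPKM cutoff, DE sets
at an FDR cutoff, overlap/Jaccard tables between transcriptomes, the
NRDE-3-style dependence partition between genotypes, upstream-region
extraction, motif scanning and PD-motif classification, and
hypergeometric enrichment of motif-bearing genes against DE sets.  Every
output is a plain-text table; a manifest records input hashes and the
resolved configuration so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import behavior, expression, genesets, motifs, regions

log = logging.getLogger(__name__)

KNOWN_KEYS = {
    "genome", "annotation", "annotation_dialect", "counts", "de_tables",
    "motif_file", "window", "rpkm_threshold", "rpkm_rule", "fdr_cutoff",
    "population", "both_strands", "seed", "out_dir", "assays",
}
DEFAULTS = {
    "window": 500,
    "rpkm_threshold": 10.0,
    "rpkm_rule": ">=",
    "fdr_cutoff": 0.05,
    "annotation_dialect": "gene-table",
    "both_strands": False,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    out_dir: str
    genome: str | None = None
    annotation: str | None = None
    annotation_dialect: str = "gene-table"
    counts: str | None = None
    de_tables: dict = field(default_factory=dict)  # genotype -> path
    motif_file: str | None = None
    population: str | None = None  # gene list for enrichment population
    assays: str | None = None
    window: int = 500
    rpkm_threshold: float = 10.0
    rpkm_rule: str = ">="
    fdr_cutoff: float = 0.05
    both_strands: bool = False
    seed: int = 0


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML config, collecting all errors before
    raising; unknown keys warn instead of failing."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    for key in set(raw) - KNOWN_KEYS:
        log.warning("unknown config key ignored: %s", key)
        raw.pop(key)
    merged = {**DEFAULTS, **raw}
    if "out_dir" not in merged:
        errors.append("missing required key: out_dir")
    if merged.get("window", 1) < 1:
        errors.append(f"window must be >= 1, got {merged['window']}")
    if not 0 < merged.get("fdr_cutoff", 0.05) <= 1:
        errors.append(f"fdr_cutoff must be in (0, 1], got {merged['fdr_cutoff']}")
    if merged.get("rpkm_rule") not in (">=", ">"):
        errors.append(f"rpkm_rule must be '>=' or '>', got {merged['rpkm_rule']!r}")
    for key in ("genome", "annotation", "counts", "motif_file", "population", "assays"):
        p = merged.get(key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key} path does not exist: {p}")
    for gt, p in (merged.get("de_tables") or {}).items():
        if not Path(p).exists():
            errors.append(f"de_tables[{gt}] path does not exist: {p}")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(**merged)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage the config enables; returns a manifest dict (also
    written to out_dir/manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "inputs": {}, "outputs": [], "stages": []}
    for key in ("genome", "annotation", "counts", "motif_file", "population", "assays"):
        p = getattr(cfg, key)
        if p:
            manifest["inputs"][key] = _sha256(p)
    for gt, p in cfg.de_tables.items():
        manifest["inputs"][f"de_tables.{gt}"] = _sha256(p)

    def emit(name, writer):
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    expressed = {}
    de = {}

    if cfg.counts:
        manifest["stages"].append("expression")
        mat = expression.read_counts_tsv(cfg.counts)
        rp = expression.rpkm(mat.counts, mat.lengths_nt)
        combos = sorted({(g, c) for g, c, _r in mat.sample_labels.values()})
        for gt, cond in combos:
            label = f"{gt}.{cond}"
            es = expression.call_expressed(
                rp, mat.samples_for(gt, cond), cfg.rpkm_threshold,
                cfg.rpkm_rule, condition=label)
            expressed[label] = es.members
            emit(f"expressed.{label}.txt",
                 lambda p, gs=es.members: genesets.write_gene_list(gs, p))
        # pairwise overlap / Jaccard table across expressed sets
        rows = []
        labels = sorted(expressed)
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                k, _, _ = genesets.overlap(expressed[la], expressed[lb])
                rows.append({
                    "set_a": la, "set_b": lb,
                    "size_a": len(expressed[la]), "size_b": len(expressed[lb]),
                    "overlap": k,
                    "pct_of_a": genesets.percent_of_query(k, len(expressed[la]), 1),
                    "jaccard_pct": genesets.jaccard_percent(
                        len(expressed[la]), len(expressed[lb]), k, 1),
                })
        emit("expressed_overlaps.tsv",
             lambda p, r=rows: pd.DataFrame(r).to_csv(p, sep="\t", index=False))

    if cfg.de_tables:
        manifest["stages"].append("de_sets")
        for gt, path in cfg.de_tables.items():
            table = expression.read_de_table(path)
            up, down = expression.de_sets(table, cfg.fdr_cutoff, name_prefix=gt)
            de[gt] = (up, down)
            emit(f"de.{gt}.up.txt", lambda p, gs=up: genesets.write_gene_list(gs, p))
            emit(f"de.{gt}.down.txt", lambda p, gs=down: genesets.write_gene_list(gs, p))
        if len(de) >= 2:
            manifest["stages"].append("dependence_partition")
            gts = sorted(de)
            wt, mut = gts[-1], gts[0]  # prefer 'wt' lexicographically last
            if "wt" in de:
                wt = "wt"
                mut = next(g for g in gts if g != "wt")
            part = genesets.dependence_partition(de[wt][0], de[wt][1],
                                                 de[mut][0], de[mut][1])
            report = {
                "wt_up": len(part.wt_up), "wt_down": len(part.wt_down),
                "mut_up": len(part.mut_up), "mut_down": len(part.mut_down),
                "shared_up": part.shared_up, "shared_down": part.shared_down,
                "dependent_up": len(part.dependent_up),
                "dependent_down": len(part.dependent_down),
                "percent_dependent": part.percent_dependent,
            }
            emit("dependence_partition.json",
                 lambda p, r=report: Path(p).write_text(json.dumps(r, indent=1)))
        else:
            log.info("single DE table: dependence partition skipped")

    motif_sets = {}
    if cfg.genome and cfg.annotation:
        manifest["stages"].append("regions")
        genome = regions.read_genome(cfg.genome)
        genes, n_rej = regions.read_annotation(cfg.annotation, cfg.annotation_dialect)
        if n_rej:
            log.warning("%d annotation records rejected", n_rej)
        regs = regions.extract_all(genes, genome, cfg.window)
        emit("upstream.fa", lambda p, r=regs: regions.write_regions(
            r, p, out / "upstream.bed") or None)
        manifest["outputs"].append("upstream.bed")

        if cfg.motif_file:
            manifest["stages"].append("motif_scan")
            pats = motifs.read_motif_file(cfg.motif_file)
            table, motif_sets_raw = motifs.scan_geneset(pats, regs, cfg.both_strands)
            emit("motif_hits.tsv",
                 lambda p, t=table: t.to_csv(p, sep="\t", index=False))
            motif_sets = {nm: genesets.GeneSet(f"motif_{nm}", frozenset(ids))
                          for nm, ids in motif_sets_raw.items()}
            pat_names = {p.name for p in pats}
            if {"daf3", "msp"} <= pat_names:
                daf3 = next(p for p in pats if p.name == "daf3")
                msp = next(p for p in pats if p.name == "msp")
                status = motifs.classify_pd_status(regs, daf3, msp)
                emit("pd_status.tsv", lambda p, st=status: pd.DataFrame(
                    [(s.gene_id, s.has_daf3, s.has_conserved, s.has_full_pd)
                     for s in st],
                    columns=["gene_id", "has_daf3", "has_conserved",
                             "has_full_pd"]).to_csv(p, sep="\t", index=False))

    if motif_sets and de:
        manifest["stages"].append("enrichment")
        if cfg.population:
            population = genesets.read_gene_list(cfg.population, "population")
        else:
            members = set()
            for up, down in de.values():
                members |= up.members | down.members
            for gs in motif_sets.values():
                members |= gs.members
            population = genesets.GeneSet("population(all observed)", frozenset(members))
            log.warning("no population list given; using union of observed sets "
                        "(%d genes) — p-values depend strongly on this choice",
                        len(population))
        results = []
        for nm, gs in sorted(motif_sets.items()):
            for gt, (up, down) in sorted(de.items()):
                for deset in (up, down):
                    results.append(genesets.enrichment_test(
                        genesets.GeneSet(deset.name, deset.members & population.members),
                        genesets.GeneSet(gs.name, gs.members & population.members),
                        population))
        emit("enrichment.tsv", lambda p, r=results: genesets.enrichment_table(r)
             .to_csv(p, sep="\t", index=False))

    if cfg.assays:
        manifest["stages"].append("behavior")
        df = behavior.trial_indices(behavior.read_assay_tsv(cfg.assays))
        emit("assay_indices.tsv", lambda p, d=df: d.to_csv(p, sep="\t", index=False))
        emit("assay_summary.tsv", lambda p, d=df: behavior.strain_summary(d)
             .to_csv(p, sep="\t", index=False))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
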
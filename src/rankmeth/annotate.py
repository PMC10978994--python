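"""Functional annotation of DMRs against a derived feature set.

From a gene model we derive, per gene: the TSS (first position of the first
exon, strand-aware, stored as a 1-bp interval), the promoter (2 kb
immediately upstream of the TSS on the gene's strand, truncated at contig
bounds), introns (gene span minus exon union), plus the exons, gene span
and optional start/stop codons. A DMR overlapping >= 1 bp of any
gene-linked feature is intragenic, otherwise intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .diffmeth import DMR
from .genome import GeneModelSet

logger = logging.getLogger(__name__)

FEATURE_LABELS = ("promoter", "TSS", "start_codon", "exon", "intron",
                  "stop_codon", "gene")


@dataclass
class Feature:
    label: str
    gene_id: str
    contig: str
    start: int
    end: int


@dataclass
class FeatureSet:
    features: list[Feature]

    def by_contig(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for i, f in enumerate(self.features):
            if f.end > f.start:
                trees.setdefault(f.contig, IntervalTree()).addi(
                    f.start, f.end, i)
        return trees

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.features])

    def write_gff3(self, model: GeneModelSet, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in model.contigs:
                fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
            for f in self.features:
                if f.end <= f.start:
                    continue
                fh.write(f"{f.contig}\trankmeth\t{f.label}\t{f.start + 1}\t"
                         f"{f.end}\t.\t.\t.\tgene_id={f.gene_id}\n")


def derive_features(model: GeneModelSet, promoter_bp: int = 2000,
                    strand_aware_promoters: bool = True) -> FeatureSet:
    """Build the annotation feature set from a gene model.

    Promoters extend upstream of the TSS on the gene's strand (for minus-
    strand genes that is toward higher coordinates); with
    ``strand_aware_promoters=False`` every promoter extends toward lower
    coordinates, mirroring a strand-naive convention.
    """
    lengths = model.contig_lengths
    feats: list[Feature] = []
    for g in model.genes:
        clen = lengths[g.contig]
        feats.append(Feature("gene", g.gene_id, g.contig, g.start, g.end))
        for a, b in g.exons:
            feats.append(Feature("exon", g.gene_id, g.contig, a, b))
        # introns: gene span minus exon union
        pos = g.start
        for a, b in g.exons:
            if a > pos:
                feats.append(Feature("intron", g.gene_id, g.contig, pos, a))
            pos = max(pos, b)
        if pos < g.end:
            feats.append(Feature("intron", g.gene_id, g.contig, pos, g.end))
        tss = g.tss
        feats.append(Feature("TSS", g.gene_id, g.contig, tss, tss + 1))
        upstream = g.strand == "+" or not strand_aware_promoters
        if upstream:
            p_start, p_end = max(0, tss - promoter_bp), tss
        else:
            p_start, p_end = tss + 1, min(clen, tss + 1 + promoter_bp)
        if p_end > p_start:
            feats.append(Feature("promoter", g.gene_id, g.contig,
                                 p_start, p_end))
    return FeatureSet(features=feats)


@dataclass
class AnnotatedDMR:
    dmr: DMR
    overlaps: list[tuple[str, str]] = field(default_factory=list)  # (label, gene)

    @property
    def locality(self) -> str:
        return "intragenic" if self.overlaps else "intergenic"


def annotate_dmrs(dmrs: list[DMR], features: FeatureSet) -> list[AnnotatedDMR]:
    """Record every (feature label, gene id) pair a DMR overlaps by >= 1 bp.

    A DMR on a contig absent from the feature set is marked intergenic with
    a logged warning.
    """
    trees = features.by_contig()
    known_contigs = {f.contig for f in features.features}
    out = []
    for d in dmrs:
        if d.contig not in known_contigs:
            logger.warning("DMR %s on contig absent from annotation; "
                           "marked intergenic", d.name)
            out.append(AnnotatedDMR(dmr=d))
            continue
        hits = trees.get(d.contig, IntervalTree()).overlap(d.start, d.end)
        pairs = sorted({(features.features[h.data].label,
                         features.features[h.data].gene_id) for h in hits})
        out.append(AnnotatedDMR(dmr=d, overlaps=pairs))
    return out


def summarize_overlaps(annotated: list[AnnotatedDMR]) -> dict[str, int]:
    """Per-feature DMR counts (a DMR can count toward several labels) plus
    the intergenic count."""
    summary = {label: 0 for label in FEATURE_LABELS}
    summary["intergenic"] = 0
    for a in annotated:
        labels = {label for label, _ in a.overlaps}
        for label in labels:
            summary[label] += 1
        if not labels:
            summary["intergenic"] += 1
    return summary


def annotated_to_frame(annotated: list[AnnotatedDMR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": a.dmr.name, "contig": a.dmr.contig, "start": a.dmr.start,
        "end": a.dmr.end, "direction": a.dmr.direction,
        "mean_logFC": a.dmr.mean_logfc, "min_q": a.dmr.min_q,
        "locality": a.locality,
        "overlaps": ";".join(f"{l}:{g}" for l, g in a.overlaps),
    } for a in annotated])
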
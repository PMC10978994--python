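"""Gene models and contig bookkeeping.

Coordinates are 0-based half-open everywhere inside the package; GFF3 I/O
converts to and from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils


@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    is_mitochondrial: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.name!r} must have positive length")


@dataclass
class Gene:
    """A single-isoform gene model: a span plus its ordered exons.

    ``exons`` are (start, end) tuples in genome order, 0-based half-open,
    all within ``(start, end)``. Transcription order is derived from
    ``strand``: on '-' the last genomic exon is exon 1.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    name: str | None = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exon list is empty")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if a < self.start or b > self.end or a >= b:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{a},{b}) outside gene span "
                    f"[{self.start},{self.end}) or empty"
                )

    @property
    def tss(self) -> int:
        """5'-most transcribed base (0-based): first position of exon 1."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class GeneModelSet:
    contigs: list[Contig]
    genes: list[Gene]

    def __post_init__(self):
        lengths = {c.name: c.length for c in self.contigs}
        for g in self.genes:
            if g.contig not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > lengths[g.contig]:
                raise ValueError(f"gene {g.gene_id} extends past contig end")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.contigs}

    @property
    def mitochondrial_contigs(self) -> set[str]:
        return {c.name for c in self.contigs if c.is_mitochondrial}

    def is_mitochondrial_gene(self, gene: Gene) -> bool:
        return gene.contig in self.mitochondrial_contigs


def read_gff3(path: str, mito_contigs: set[str] | None = None,
              contig_lengths: dict[str, int] | None = None) -> GeneModelSet:
    """Load gene/exon features from a GFF3 file into a GeneModelSet.

    Contig lengths come from ``##sequence-region`` pragmas unless supplied;
    contigs named in ``mito_contigs`` are flagged mitochondrial.
    """
    mito_contigs = mito_contigs or set()
    lengths: dict[str, int] = dict(contig_lengths or {})
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
        if not exons:
            continue
        gid = g.id
        name = g.attributes.get("Name", [None])[0]
        genes.append(Gene(gene_id=gid, contig=g.seqid, start=g.start - 1,
                          end=g.end, strand=g.strand, exons=exons, name=name))
    contig_names = sorted({g.contig for g in genes} | set(lengths))
    contigs = [Contig(n, lengths.get(n, max((g.end for g in genes if g.contig == n),
                                            default=1)),
                      n in mito_contigs)
               for n in contig_names]
    return GeneModelSet(contigs=contigs, genes=genes)


def write_gff3(model: GeneModelSet, path: str) -> None:
    """Write genes and exons as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in model.contigs:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in model.genes:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(f"{g.contig}\trankmeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write(f"{g.contig}\trankmeth\texon\t{a + 1}\t{b}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}\n")
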
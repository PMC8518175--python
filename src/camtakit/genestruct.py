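"""Gene models, exon-intron statistics, and strand-aware promoter intervals.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
boundary (1-based inclusive) is converted in exactly one reader/writer pair
here.  The transcription start site is taken as the gene feature's 5' end,
which is the only operationalizable choice when the annotation carries no
UTRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils

from .fastaio import revcomp


@dataclass
class GeneModel:
    """One mRNA's gene model: scaffold, strand, ordered exon intervals
    (0-based half-open) and the enclosing gene span."""

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1


@dataclass
class StructureStats:
    n_exons: int
    n_introns: int
    exon_lengths: list[int]
    intron_lengths: list[int]


@dataclass
class PromoterInterval:
    """Forward-coordinate upstream interval, 0-based half-open.  For minus
    strand genes the extracted sequence must be reverse-complemented
    (``needs_revcomp``)."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    needs_revcomp: bool
    clipped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gff3(path, scaffold_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Parse a GFF3 into gene models, one per mRNA.

    gene/mRNA/exon features are linked by ID/Parent.  Multiple mRNAs per gene
    are allowed; their model ids are suffixed ``.1``, ``.2``, ...  Exons
    falling outside their gene span, or exon/mRNA features without a Parent,
    raise with the offending feature.  ``##sequence-region`` pragmas (or an
    explicit ``scaffold_lengths``) bound-check the coordinates.
    """
    if scaffold_lengths is None:
        scaffold_lengths = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, name, _start, end = line.split()
                    scaffold_lengths[name] = int(end)

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.all_features():
        if feat.featuretype in ("mRNA", "exon", "CDS") and "Parent" not in feat.attributes:
            raise ValueError(f"{feat.featuretype} feature without Parent: {feat}")

    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        for k, mrna in enumerate(mrnas, start=1):
            exons = []
            for ex in db.children(mrna, featuretype="exon"):
                if ex.start < gene.start or ex.end > gene.end:
                    raise ValueError(f"exon outside gene span of {gene.id}: {ex}")
                exons.append((ex.start - 1, ex.end))  # 1-based inclusive -> half-open
            scaffold_len = scaffold_lengths.get(gene.seqid)
            if scaffold_len is not None and gene.end > scaffold_len:
                raise ValueError(
                    f"{gene.id}: gene end {gene.end} beyond scaffold "
                    f"{gene.seqid} length {scaffold_len}"
                )
            gid = gene.id if len(mrnas) == 1 else f"{gene.id}.{k}"
            models.append(
                GeneModel(
                    gene_id=gid,
                    scaffold_id=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    cds_span=(gene.start - 1, gene.end),
                )
            )
    return models


def write_gff3(models: list[GeneModel], scaffold_lengths: dict[str, int], path) -> None:
    """Emit gene/mRNA/exon/CDS features (1-based inclusive, ID/Parent links)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(scaffold_lengths):
            fh.write(f"##sequence-region {name} 1 {scaffold_lengths[name]}\n")
        for m in models:
            s, e = m.span
            base = f"{m.scaffold_id}\tcamtakit\t"
            fh.write(
                f"{base}gene\t{s + 1}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.m1"
            fh.write(
                f"{base}mRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(m.exons, start=1):
                fh.write(
                    f"{base}exon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                fh.write(
                    f"{base}CDS\t{xs + 1}\t{xe}\t.\t{m.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def structure_stats(m: GeneModel) -> StructureStats:
    """Exon and intron lengths in bp; intron i is the gap between exons i
    and i+1."""
    exon_lengths = [e - s for s, e in m.exons]
    intron_lengths = [
        m.exons[i + 1][0] - m.exons[i][1] for i in range(len(m.exons) - 1)
    ]
    return StructureStats(
        n_exons=len(exon_lengths),
        n_introns=len(intron_lengths),
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
    )


def upstream_region(
    m: GeneModel, scaffold_len: int, length: int = 1000
) -> PromoterInterval:
    """The promoter interval upstream of the TSS, clipped at scaffold edges.

    Plus strand: [TSS - length, TSS).  Minus strand: the ``length`` bases
    after the gene end in forward coordinates, flagged for
    reverse-complementation.  A zero-length result (gene starting at the
    scaffold edge) warns and returns an empty interval.
    """
    gs, ge = m.span
    if m.strand == "+":
        start, end = max(0, gs - length), gs
    else:
        start, end = ge, min(scaffold_len, ge + length)
    clipped = (end - start) < length
    if end <= start:
        warnings.warn(
            f"{m.gene_id}: empty promoter (gene abuts scaffold edge)", stacklevel=2
        )
        start = end = max(0, start)
    return PromoterInterval(
        scaffold_id=m.scaffold_id,
        start=start,
        end=end,
        strand=m.strand,
        needs_revcomp=(m.strand == "-"),
        clipped=clipped,
    )


def extract_promoters(
    models: list[GeneModel], scaffolds: dict[str, str], length: int = 1000
) -> dict[str, str]:
    """Promoter sequences keyed by gene id, in transcript orientation."""
    promoters = {}
    for m in models:
        iv = upstream_region(m, len(scaffolds[m.scaffold_id]), length)
        seq = scaffolds[m.scaffold_id][iv.start : iv.end]
        promoters[m.gene_id] = revcomp(seq) if iv.needs_revcomp else seq
    return promoters


def promoter_bed(models: list[GeneModel], scaffolds: dict[str, str], length: int = 1000):
    """BED-like promoter interval rows (0-based half-open, strand column)."""
    rows = []
    for m in models:
        iv = upstream_region(m, len(scaffolds[m.scaffold_id]), length)
        rows.append(
            {
                "scaffold": iv.scaffold_id,
                "start": iv.start,
                "end": iv.end,
                "gene": m.gene_id,
                "strand": iv.strand,
                "clipped": iv.clipped,
            }
        )
    return rows
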
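"""Gene-context annotation of significant SNPs.

Finds all genes overlapping a +/- 0.5 Mbp window around each SNP (the radius
is adjustable) and reports, per gene, the base-pair distance to the nearer
gene edge (0 if the SNP lies inside the gene span) and the strand-aware
relation: a SNP lying 5' of the gene — before the start of a plus-strand
gene, or after the end of a minus-strand gene — is "upstream", the opposite
side "downstream", and a SNP inside the span "within".

Gene tables are 5-column TSVs (name, chrom, start, end, strand) with
1-based *inclusive* coordinates.  NOTE: this deliberately deviates from
BED's 0-based half-open convention so that hand-written annotation fixtures
read naturally; convert BED starts by adding 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneModel", "GeneHit", "read_gene_table", "genes_near", "annotate_table"]


@dataclass(frozen=True)
class GeneModel:
    """One gene span: 1-based inclusive [start, end] on chrom, strand + or -."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneHit:
    gene: GeneModel
    distance: int  # bp to nearer edge; 0 iff the SNP is within the span
    relation: str  # within | upstream | downstream


def read_gene_table(path) -> list[GeneModel]:
    """Read a gene-annotation TSV with columns name, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneModel(str(r.name), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def genes_near(
    snp: tuple[str, int], genes: list[GeneModel], window: int = 500_000
) -> list[GeneHit]:
    """All genes overlapping [pos - window, pos + window] around one SNP.

    Results are sorted by distance then gene start, independent of the input
    gene order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    chrom, pos = str(snp[0]), int(snp[1])
    hits: list[GeneHit] = []
    for g in genes:
        if g.chrom != chrom or g.end < pos - window or g.start > pos + window:
            continue
        if g.start <= pos <= g.end:
            hits.append(GeneHit(g, 0, "within"))
            continue
        if pos < g.start:
            dist = g.start - pos
            relation = "upstream" if g.strand == "+" else "downstream"
        else:
            dist = pos - g.end
            relation = "downstream" if g.strand == "+" else "upstream"
        hits.append(GeneHit(g, dist, relation))
    hits.sort(key=lambda h: (h.distance, h.gene.start, h.gene.name))
    return hits


def annotate_table(
    snps: pd.DataFrame, genes: list[GeneModel], window: int = 500_000
) -> pd.DataFrame:
    """Annotate a SNP table (columns rsid, chrom, pos) with nearby genes.

    One output row per (SNP, gene) hit; SNPs with no gene inside the window
    get a single row with empty gene fields.
    """
    rows = []
    for r in snps.itertuples(index=False):
        hits = genes_near((str(r.chrom), int(r.pos)), genes, window=window)
        if not hits:
            rows.append((r.rsid, r.chrom, r.pos, "", pd.NA, ""))
        for h in hits:
            rows.append((r.rsid, r.chrom, r.pos, h.gene.name, h.distance, h.relation))
    return pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "gene", "distance", "relation"]
    )
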
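"""Region-based annotation of SVs against gene models.

Every SV gets exactly one class by the fixed precedence
exonic > intronic > upstream_1kb > downstream_1kb > intergenic:
an SV intersecting any exon is exonic; else intersecting any gene span is
intronic; else within 1 kb of a gene span (strand-aware, upstream meaning
5' of the gene) it is upstream_1kb or downstream_1kb; else intergenic.
All interval intersections are closed-interval (>=1 shared bp).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import GeneModel, RegionClass, SelectionRegion


class GeneIndex:
    """Per-chromosome interval trees over exons, gene spans, and the 1-kb
    upstream/downstream flanks of each gene."""

    #: distance from the gene span within which an SV counts as near-gene
    FLANK = 1_000

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        self.genes = {g.gene_id: g for g in genes}
        self._exons: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        self._upstream: dict[str, IntervalTree] = {}
        self._downstream: dict[str, IntervalTree] = {}
        for g in genes:
            # IntervalTree is half-open; store [start, end] as [start, end+1)
            for lo, hi in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g.gene_id)
            self._spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
            if g.strand == "+":
                up = (g.start - self.FLANK, g.start - 1)
                down = (g.end + 1, g.end + self.FLANK)
            else:
                up = (g.end + 1, g.end + self.FLANK)
                down = (g.start - self.FLANK, g.start - 1)
            for tree, (lo, hi) in (
                (self._upstream, up),
                (self._downstream, down),
            ):
                lo = max(lo, 1)
                if hi >= lo:
                    tree.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g.gene_id)

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, start: int, end: int):
        tree = trees.get(chrom)
        if tree is None:
            return ()
        return tuple(sorted({iv.data for iv in tree.overlap(start, end + 1)}))


def classify_sv(sv, index: GeneIndex) -> RegionClass:
    """Assign the single region class of an SV (total function; precedence
    exonic > intronic > upstream_1kb > downstream_1kb > intergenic)."""
    chrom, start, end = sv.chrom, sv.start, sv.end
    for cls, trees in (
        ("exonic", index._exons),
        ("intronic", index._spans),
        ("upstream_1kb", index._upstream),
        ("downstream_1kb", index._downstream),
    ):
        hits = index._hits(trees, chrom, start, end)
        if hits:
            return RegionClass(cls, hits)
    return RegionClass("intergenic")


def classify_all(svs: Sequence, genes: Sequence[GeneModel]) -> list[RegionClass]:
    index = GeneIndex(genes)
    return [classify_sv(sv, index) for sv in svs]


def class_distribution(svs: Sequence, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Counts and percentages of SVs per region class (comparative summary;
    the denominator is the full input SV set)."""
    classes = [rc.region_class for rc in classify_all(svs, genes)]
    counts = pd.Series(classes).value_counts()
    counts = counts.reindex(RegionClass.CLASSES, fill_value=0)
    df = counts.rename_axis("region_class").to_frame("n").reset_index()
    df["percent"] = 100.0 * df["n"] / max(len(svs), 1)
    return df


def genes_in_regions(
    regions: Sequence[SelectionRegion],
    genes: Sequence[GeneModel],
) -> dict[SelectionRegion, tuple[str, ...]]:
    """Per region, the distinct ids of genes whose spans intersect the
    region interval (closed-interval, >=1 bp)."""
    index = GeneIndex(genes)
    return {
        region: index._hits(index._spans, region.chrom, region.start, region.end)
        for region in regions
    }


def attach_genes(
    regions: Sequence[SelectionRegion],
    genes: Sequence[GeneModel],
) -> list[SelectionRegion]:
    """Return regions with their overlapping gene ids filled in."""
    mapping = genes_in_regions(regions, genes)
    return [
        SelectionRegion(r.chrom, r.start, r.end, r.sites, mapping[r])
        for r in regions
    ]


def count_distinct_genes(region_genes: Mapping[SelectionRegion, tuple[str, ...]]) -> int:
    """Distinct genes covered across all regions."""
    return len({g for ids in region_genes.values() for g in ids})
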
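"""Assign CpG sites to genomic feature categories.

Each site gets exactly one category out of promoter, 5' UTR, 3' UTR,
exon (non-UTR exonic sequence), intron, or intergenic.  Overlaps are
resolved by a fixed precedence (promoter > utr5 > utr3 > exon > intron);
ties between genes within one category break by distance to the nearest
TSS and then lexicographic gene id, so assignment is deterministic and
independent of input gene order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, ValidationError, subtract_intervals

CATEGORIES = ["promoter", "utr5", "utr3", "exon", "intron", "intergenic"]
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES[:-1])}

DEFAULT_PROMOTER_UP = 1000
DEFAULT_PROMOTER_DOWN = 1000


class FeatureIndex:
    """Per-chromosome interval index over gene feature categories."""

    def __init__(self):
        self.trees = {}

    def add(self, chrom, start, end, category, gene_id, tss):
        if end < start:
            return
        # intervaltree is half-open; store 1-based inclusive as [start, end+1)
        self.trees.setdefault(chrom, IntervalTree()).addi(
            start, end + 1, (_PRECEDENCE[category], category, gene_id, tss)
        )

    def query(self, chrom, pos):
        """Best (category, gene_id) at a 1-based position."""
        tree = self.trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return "intergenic", None
        best = min(
            hits,
            key=lambda iv: (iv.data[0], abs(pos - iv.data[3]), iv.data[2]),
        )
        return best.data[1], best.data[2]


def promoter_interval(gene: GeneModel, up: int, down: int):
    """Strand-aware promoter window around the TSS, 1-based inclusive."""
    tss = gene.tss
    if gene.strand == "+":
        return max(1, tss - up), tss + down
    return max(1, tss - down), tss + up


def build_feature_index(
    genes,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> FeatureIndex:
    """Index promoter/UTR/exon/intron intervals for all genes.

    The exon category covers exonic sequence outside annotated UTRs; the
    intron category is the gene span minus merged exons.
    """
    index = FeatureIndex()
    for g in genes:
        ps, pe = promoter_interval(g, promoter_up, promoter_down)
        index.add(g.chrom, ps, pe, "promoter", g.gene_id, g.tss)
        for s, e in g.utr5:
            index.add(g.chrom, s, e, "utr5", g.gene_id, g.tss)
        for s, e in g.utr3:
            index.add(g.chrom, s, e, "utr3", g.gene_id, g.tss)
        for s, e in subtract_intervals(g.exons, list(g.utr5) + list(g.utr3)):
            index.add(g.chrom, s, e, "exon", g.gene_id, g.tss)
        for s, e in g.introns:
            index.add(g.chrom, s, e, "intron", g.gene_id, g.tss)
    return index


def annotate_sites(sites: pd.DataFrame, index: FeatureIndex, chrom_lengths=None):
    """Assign every (chrom, pos) site to one feature category.

    Returns (assignments frame with ``category`` and ``gene_id`` columns,
    category percentage dict over all sites).  Percentages cover every
    category, including zeros, and sum to 100 up to rounding.
    """
    cats, gids = [], []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        if chrom_lengths is not None:
            length = chrom_lengths.get(chrom)
            if length is not None and not (1 <= pos <= length):
                raise ValidationError(f"site {chrom}:{pos} beyond chromosome bounds")
        cat, gid = index.query(chrom, int(pos))
        cats.append(cat)
        gids.append(gid)
    assignments = sites.copy()
    assignments["category"] = cats
    assignments["gene_id"] = gids
    n = len(assignments)
    counts = assignments["category"].value_counts()
    percentages = {
        c: (100.0 * counts.get(c, 0) / n if n else 0.0) for c in CATEGORIES
    }
    return assignments, percentages


def category_counts(assignments: pd.DataFrame) -> dict:
    counts = assignments["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}
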
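"""Duplicated-block detection from all-vs-all transcript hits.

Each gene is represented by its longest transcript; an all-vs-all
nucleotide search of that non-redundant set against itself makes every
sequence's best hit itself, so homologs appear as *second-best* hits.
Two genes whose best non-self hits (e-value <= 1e-10) point at each
other form a reciprocal pair; runs of at least ``min_genes`` (default
10) neighboring reciprocal pairs between two chromosomal regions are
chained into duplicated (syntenic) blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ValidationError

DEFAULT_E_CUTOFF = 1e-10
DEFAULT_MIN_GENES = 10
DEFAULT_MAX_GAP = 2


@dataclass(frozen=True)
class ReciprocalPair:
    gene_a: str
    gene_b: str
    e_value_ab: float
    e_value_ba: float


@dataclass
class SyntenyBlock:
    chrom_a: str
    index_range_a: tuple  # inclusive gene-rank range on chrom_a
    chrom_b: str
    index_range_b: tuple
    pairs: list  # ReciprocalPair, ordered along chrom_a
    orientation: str  # 'same' | 'inverted'

    @property
    def n_genes(self) -> int:
        return len(self.pairs)


def longest_transcript_db(genes) -> dict:
    """Representative (longest summed-exon) transcript per gene.

    Ties break by lexicographically smallest transcript id, so the map is
    deterministic across runs.
    """
    rep = {}
    for g in genes:
        if not g.transcripts:
            continue
        best = min(g.transcripts, key=lambda t: (-t.length, t.transcript_id))
        rep[g.gene_id] = best.transcript_id
    return rep


def second_best_hits(
    hits: pd.DataFrame, tx_to_gene: dict, e_cutoff: float = DEFAULT_E_CUTOFF
) -> dict:
    """Best non-self gene-level hit per gene at the e-value cutoff.

    ``hits`` is a 12-column tabular hit frame with transcript ids;
    ``tx_to_gene`` maps transcript id -> gene id.  Self-hits (same gene
    after mapping) and hits above ``e_cutoff`` are dropped; among the
    rest each gene keeps the minimal e-value, ties broken by higher bit
    score then lexicographic subject gene.  Genes with no surviving hit
    are simply absent from the returned map.
    """
    best = {}
    for row in hits.itertuples(index=False):
        qg = tx_to_gene.get(row.query_id)
        sg = tx_to_gene.get(row.subject_id)
        if qg is None or sg is None or qg == sg:
            continue
        if row.e_value > e_cutoff:
            continue
        key = (row.e_value, -row.bit_score, sg)
        if qg not in best or key < best[qg][0]:
            best[qg] = (key, sg, row.e_value)
    return {g: (sg, e) for g, (_, sg, e) in best.items()}


def reciprocal_pairs(best_map: dict):
    """Mutual best-non-self pairs, each emitted once with gene_a < gene_b."""
    pairs = []
    for a, (b, e_ab) in best_map.items():
        partner = best_map.get(b)
        if partner is None or partner[0] != a:
            continue
        if a < b:
            pairs.append(ReciprocalPair(a, b, e_ab, partner[1]))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def gene_order(genes) -> dict:
    """gene_id -> (chrom, rank of start coordinate within chromosome)."""
    order = {}
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        for rank, g in enumerate(sorted(gs, key=lambda g: (g.start, g.gene_id))):
            order[g.gene_id] = (chrom, rank)
    return order


def chain_blocks(
    pairs,
    order: dict,
    min_genes: int = DEFAULT_MIN_GENES,
    max_gap: int = DEFAULT_MAX_GAP,
    require_collinear: bool = True,
):
    """Chain reciprocal pairs into duplicated blocks.

    Anchors are grouped by the (unordered) chromosome pair and sorted
    along the first chromosome; a chain extends while the gene-rank gap
    (intervening non-anchor genes) is <= ``max_gap`` on side A and, when
    ``require_collinear``, also <= ``max_gap`` on side B in a single
    direction (same or inverted) fixed per block.  Chains with at least
    ``min_genes`` anchors are emitted; longest chains claim their genes
    first, so a gene joins at most one block per chromosome pairing.
    """
    missing = sorted(
        {g for p in pairs for g in (p.gene_a, p.gene_b) if g not in order}
    )
    if missing:
        raise ValidationError(f"pairs reference genes missing from annotation: {missing}")

    grouped = {}
    for p in pairs:
        ca, ia = order[p.gene_a]
        cb, ib = order[p.gene_b]
        # orient the anchor so side A is the lexicographically smaller
        # chromosome (or the smaller rank on a self-pairing)
        if (cb, ib) < (ca, ia):
            anchor = (cb, ib, ca, ia, p)
        else:
            anchor = (ca, ia, cb, ib, p)
        grouped.setdefault((anchor[0], anchor[2]), []).append(anchor)

    candidate_chains = []
    for (ca, cb), anchors in grouped.items():
        anchors.sort(key=lambda a: (a[1], a[3]))
        chain = []
        direction = 0  # +1 same, -1 inverted, 0 undetermined

        def close():
            nonlocal chain, direction
            if len(chain) >= min_genes:
                candidate_chains.append((ca, cb, list(chain), direction))
            chain = []
            direction = 0

        for anchor in anchors:
            if not chain:
                chain.append(anchor)
                continue
            prev = chain[-1]
            gap_a = anchor[1] - prev[1] - 1
            ok = 0 <= gap_a <= max_gap
            if ok and require_collinear:
                delta_b = anchor[3] - prev[3]
                step_dir = 1 if delta_b > 0 else -1 if delta_b < 0 else 0
                gap_b = abs(delta_b) - 1
                if step_dir == 0 or gap_b > max_gap:
                    ok = False
                elif direction == 0:
                    direction = step_dir
                elif step_dir != direction:
                    ok = False
            if ok:
                chain.append(anchor)
            else:
                close()
                chain.append(anchor)
        close()

    blocks = []
    used = set()  # (chrom_pair, gene)
    for ca, cb, chain, direction in sorted(
        candidate_chains, key=lambda c: (-len(c[2]), c[0], c[1], c[2][0][1])
    ):
        key = (ca, cb)
        members = {g for a in chain for g in (a[4].gene_a, a[4].gene_b)}
        if any((key, g) in used for g in members):
            continue
        used.update((key, g) for g in members)
        idx_a = [a[1] for a in chain]
        idx_b = [a[3] for a in chain]
        blocks.append(
            SyntenyBlock(
                chrom_a=ca,
                index_range_a=(min(idx_a), max(idx_a)),
                chrom_b=cb,
                index_range_b=(min(idx_b), max(idx_b)),
                pairs=[a[4] for a in chain],
                orientation="inverted" if direction == -1 else "same",
            )
        )
    blocks.sort(key=lambda b: (b.chrom_a, b.index_range_a, b.chrom_b))
    return blocks


def find_blocks(
    genes,
    hits: pd.DataFrame,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    min_genes: int = DEFAULT_MIN_GENES,
    max_gap: int = DEFAULT_MAX_GAP,
    require_collinear: bool = True,
):
    """End-to-end block detection; returns (blocks, reciprocal pairs)."""
    rep = longest_transcript_db(genes)
    tx_to_gene = {tx: g for g, tx in rep.items()}
    # non-representative transcripts still map to their gene
    for g in genes:
        for t in g.transcripts:
            tx_to_gene.setdefault(t.transcript_id, g.gene_id)
    best = second_best_hits(hits, tx_to_gene, e_cutoff=e_cutoff)
    pairs = reciprocal_pairs(best)
    blocks = chain_blocks(
        pairs,
        gene_order(genes),
        min_genes=min_genes,
        max_gap=max_gap,
        require_collinear=require_collinear,
    )
    return blocks, pairs


def blocks_to_frame(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom_a": b.chrom_a,
                "index_start_a": b.index_range_a[0],
                "index_end_a": b.index_range_a[1],
                "chrom_b": b.chrom_b,
                "index_start_b": b.index_range_b[0],
                "index_end_b": b.index_range_b[1],
                "n_genes": b.n_genes,
                "orientation": b.orientation,
                "pairs": ";".join(f"{p.gene_a}|{p.gene_b}" for p in b.pairs),
            }
            for b in blocks
        ],
        columns=[
            "chrom_a", "index_start_a", "index_end_a",
            "chrom_b", "index_start_b", "index_end_b",
            "n_genes", "orientation", "pairs",
        ],
    )


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "e_value_ab": p.e_value_ab,
                "e_value_ba": p.e_value_ba,
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "e_value_ab", "e_value_ba"],
    )
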
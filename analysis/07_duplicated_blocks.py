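#!/usr/bin/env python
"""Duplicated-block detection and paralog expression concordance.

Reduces each gene to its longest transcript, takes best non-self hits at
e <= 1e-10 from the all-vs-all table, keeps mutual (reciprocal) pairs,
chains >=10 neighboring pairs into blocks, and checks whether duplicated
copies change expression in the same direction.
"""

import argparse
from pathlib import Path

import numpy as np

from stressmeth import integration, synteny
from stressmeth.io_formats import hits_to_frame, read_gtf, read_hits, read_tsv, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--outdir", type=Path, default=Path("results/run"))
args = parser.parse_args()

genes = read_gtf(args.study / "annotation.gtf")
hits = hits_to_frame(read_hits(args.study / "hits.tsv"))
blocks, pairs = synteny.find_blocks(genes, hits)
write_tsv(synteny.blocks_to_frame(blocks), args.outdir / "synteny_blocks.tsv")
write_tsv(synteny.pairs_to_frame(pairs), args.outdir / "synteny_pairs.tsv")
print(f"{len(pairs)} reciprocal pairs -> {len(blocks)} duplicated blocks")
for b in blocks:
    print(f"  {b.chrom_a}[{b.index_range_a[0]}-{b.index_range_a[1]}] ~ "
          f"{b.chrom_b}[{b.index_range_b[0]}-{b.index_range_b[1]}] "
          f"({b.n_genes} genes, {b.orientation})")

pair_list = [(p.gene_a, p.gene_b) for p in pairs]
for de_path in sorted(args.outdir.glob("de_*.tsv")):
    de = read_tsv(de_path).set_index("gene_id")
    frac = integration.paralog_direction_concordance(de, pair_list)
    label = "n/a (no doubly significant pair)" if np.isnan(frac) else f"{frac:.2f}"
    print(f"  direction concordance in {de_path.stem}: {label}")
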
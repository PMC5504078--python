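#!/usr/bin/env python
"""1 Mb window co-localization of DM sites with DE genes, per comparison.

Flags windows holding both significant DM sites and significant DE
genes, ranks them as candidate regulatory regions, and reports the
distance from each DM site to the nearest DE gene in its window.
"""

import argparse
from pathlib import Path

import pandas as pd

from stressmeth import window_scan
from stressmeth.io_formats import read_gtf, read_tsv, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--outdir", type=Path, default=Path("results/run"))
args = parser.parse_args()

genes = read_gtf(args.study / "annotation.gtf")
chrom_lengths = dict(
    zip(*read_tsv(args.study / "chrom_lengths.tsv").to_dict("list").values())
)

all_candidates = []
for dm_path in sorted(args.outdir.glob("dm_*.tsv")):
    group = dm_path.stem.split("_", 1)[1]
    dm = read_tsv(dm_path)
    de = read_tsv(args.outdir / f"de_{group}.tsv").set_index("gene_id")
    windows = window_scan.scan_windows(dm, de, genes, chrom_lengths=chrom_lengths)
    write_tsv(window_scan.windows_to_frame(windows),
              args.outdir / f"windows_{group}.tsv")
    ranked = window_scan.rank_candidate_regulatory_windows(windows, dm, genes)
    n_coloc = sum(w.colocalized for w in windows)
    print(f"{group}: {len(windows)} windows, {n_coloc} co-localized")
    if ranked:
        top = ranked[0]
        dists = top["dm_to_nearest_de_gene_bp"]
        print(f"  top window {top['chrom']}:{top['start']}-{top['end']} "
              f"score={top['score']} "
              f"(DM-to-DE-gene distances up to {max(dists)/1000:.0f} kb)")
    for r in ranked:
        r["comparison"] = group
        r["dm_to_nearest_de_gene_bp"] = ",".join(
            str(d) for d in r["dm_to_nearest_de_gene_bp"]
        )
    all_candidates.extend(ranked)

write_tsv(pd.DataFrame(all_candidates), args.outdir / "candidate_windows.tsv")
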
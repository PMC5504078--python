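#!/usr/bin/env python
"""Feature-category distribution of significant DM sites.

Assigns the union of DM calls to promoter / 5' UTR / 3' UTR / exon /
intron / intergenic with fixed precedence and reports the split.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stressmeth import feature_annotation
from stressmeth.io_formats import read_gtf, read_tsv, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--outdir", type=Path, default=Path("results/run"))
args = parser.parse_args()

genes = read_gtf(args.study / "annotation.gtf")
dm_union = (
    pd.concat(
        [
            read_tsv(p).query("status != 'ns'")[["chrom", "pos"]]
            for p in sorted(args.outdir.glob("dm_*.tsv"))
        ],
        ignore_index=True,
    )
    .drop_duplicates()
    .sort_values(["chrom", "pos"])
    .reset_index(drop=True)
)
index = feature_annotation.build_feature_index(genes)
assignments, pct = feature_annotation.annotate_sites(dm_union, index)
write_tsv(assignments, args.outdir / "feature_assignments.tsv")
(args.outdir / "feature_summary.json").write_text(
    json.dumps(pct, indent=2, sort_keys=True) + "\n"
)
print(f"{len(dm_union)} distinct DM sites annotated:")
for cat in feature_annotation.CATEGORIES:
    print(f"  {cat:10s} {pct[cat]:5.1f}%")
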
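#!/usr/bin/env python
"""Expression normalization and DE classification per stressed group.

Median-of-ratios size factors, Welch t on log2(normalized + 1), BH
adjustment; up/down at >=1.5-fold and adjusted p < 0.05.  Also selects
the genes with a consistent >=1.5-fold change in all three comparisons.
"""

import argparse
from pathlib import Path

from stressmeth import diffexpr
from stressmeth.io_formats import read_counts, read_design, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--outdir", type=Path, default=Path("results/run"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

design = read_design(args.study / "design.tsv")
counts = read_counts(args.study / "counts.tsv")
size_factors, normalized = diffexpr.median_of_ratios_norm(counts)
print("size factors:",
      ", ".join(f"{s}={v:.3f}" for s, v in size_factors.head(4).items()), "...")

de_by_group = {}
for group in [g for g in design.groups if g != "CO"]:
    de = diffexpr.de_test(normalized, design, group)
    de_by_group[group] = de
    write_tsv(de.rename_axis("gene_id").reset_index(),
              args.outdir / f"de_{group}.tsv")
    print(f"{group} vs CO: {(de['status'] == 'up').sum()} up, "
          f"{(de['status'] == 'down').sum()} down of {len(de)} genes")

consistent = diffexpr.consistent_de(de_by_group)
write_tsv(consistent.rename_axis("gene_id").reset_index(),
          args.outdir / "consistent_de.tsv")
print(f"consistent >=1.5-fold genes across all stressed groups: "
      f"{len(consistent)} ({(consistent['direction'] == 'up').sum()} up)")
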
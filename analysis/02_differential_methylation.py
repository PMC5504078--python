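#!/usr/bin/env python
"""Per-CpG differential methylation, each stressed group vs control.

Coverage-filtered (>=10x every sample), logistic-regression deviance
test, BH-adjusted; a site is DM when |pooled difference| > 20 pp and
q < 0.1.  Writes dm_<group>.tsv/.bed under results/run/.
"""

import argparse
from pathlib import Path

from stressmeth import diffmeth
from stressmeth.io_formats import load_coverage_dir, read_design, write_bed, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--outdir", type=Path, default=Path("results/run"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

design = read_design(args.study / "design.tsv")
mat = load_coverage_dir(args.study / "coverage", design)
print(f"{mat.n_sites} destranded CpGs across {len(design.samples)} samples")

for group in [g for g in design.groups if g != "CO"]:
    filtered = diffmeth.filter_sites(mat, design, group)
    dm = diffmeth.call_dm(diffmeth.dm_test(filtered, design, group))
    s = diffmeth.summarize_dm(dm, filtered)
    write_tsv(dm, args.outdir / f"dm_{group}.tsv")
    sig = dm[dm["status"] != "ns"]
    write_bed(list(zip(sig["chrom"], sig["pos"], sig["status"])),
              args.outdir / f"dm_{group}.bed")
    print(
        f"{group} vs CO: {s['n_sites_tested']} tested, "
        f"{s['n_hyper']} hyper / {s['n_hypo']} hypo "
        f"(excess {s['hyper_excess_pct']:+.1f}%), "
        f"global methylation {s['global_methylation_pct']:.1f}%"
    )
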
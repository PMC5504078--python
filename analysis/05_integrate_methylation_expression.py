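#!/usr/bin/env python
"""Methylation change over gene bodies +/- 10 kb for consistent DE genes.

Filters CpGs (>=6x average coverage, >=8 pp change), averages the change
per gene region, cross-classifies methylation sign with expression
direction into quadrants, and contrasts up- vs down-regulated gene sets
with Welch's t-test.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stressmeth import integration
from stressmeth.io_formats import load_coverage_dir, read_design, read_gtf, read_tsv, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--outdir", type=Path, default=Path("results/run"))
args = parser.parse_args()

design = read_design(args.study / "design.tsv")
mat = load_coverage_dir(args.study / "coverage", design)
genes = read_gtf(args.study / "annotation.gtf")
consistent = read_tsv(args.outdir / "consistent_de.tsv")
direction = dict(zip(consistent["gene_id"], consistent["direction"]))

profiles = []
for group in [g for g in design.groups if g != "CO"]:
    sites = integration.integration_change_table(mat, design, group)
    print(f"{group}: {len(sites)} CpGs pass the 6x / 8 pp filters")
    profiles.append(
        integration.profile_genes(genes, sites, direction,
                                  comparison=f"{group}_vs_CO")
    )
profiles = pd.concat(profiles, ignore_index=True)
write_tsv(profiles, args.outdir / "integration_profiles.tsv")

pct = integration.classify_quadrants(profiles)
print("quadrant split over gene x comparison profiles with usable CpGs:")
for quad in integration.QUADRANTS:
    print(f"  {quad:10s} {pct.get(quad, 0.0):5.1f}%")

informative = profiles[profiles["quadrant"] != "flat"]
up = informative.loc[informative["expr_direction"] == "up", "mean_meth_change"]
down = informative.loc[informative["expr_direction"] == "down", "mean_meth_change"]
result = {"quadrant_percentages": pct, "welch_up_vs_down": None}
if len(up) >= 2 and len(down) >= 2:
    t, df, p = integration.welch_t(up, down)
    result["welch_up_vs_down"] = {"t": t, "df": df, "p": p}
    print(f"Welch t (up vs down gene sets): t={t:.2f}, df={df:.1f}, p={p:.3g}")
(args.outdir / "quadrant_summary.json").write_text(
    json.dumps(result, indent=2, sort_keys=True) + "\n"
)
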
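"""1 Mb sliding-window co-localization of DM sites and DE genes.

Chromosomes are tiled with fixed-size windows (default 1 Mb, step =
window size; a smaller step gives overlapping sliding windows).  A
window counts the hyper-/hypo-methylated sites positioned inside it and
the genes whose spans overlap it; windows holding at least one DM site
and at least one significantly differentially expressed gene are flagged
as co-localized and ranked as candidate regulatory regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 1_000_000


@dataclass
class WindowSummary:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_hyper: int = 0
    n_hypo: int = 0
    de_genes: list = field(default_factory=list)  # (gene_id, log2fc, status)
    colocalized: bool = False

    @property
    def n_dm(self) -> int:
        return self.n_hyper + self.n_hypo

    @property
    def n_de(self) -> int:
        return sum(1 for _, _, s in self.de_genes if s != "ns")


def tile_windows(chrom_lengths: dict, window_size=DEFAULT_WINDOW, step=None):
    """Tile each chromosome with [start, end] windows (last truncated)."""
    if step is None:
        step = window_size
    if step > window_size:
        raise ValueError("step must not exceed window size")
    if step < 1 or window_size < 1:
        raise ValueError("window size and step must be positive")
    windows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        start = 1
        while start <= length:
            windows.append(
                WindowSummary(chrom, start, min(start + window_size - 1, length))
            )
            start += step
    return windows


def infer_chrom_lengths(dm_records, genes, chrom_lengths=None) -> dict:
    """Chromosome extents from data when true lengths are not supplied."""
    if chrom_lengths:
        return dict(chrom_lengths)
    lengths = {}
    if len(dm_records):
        for chrom, pos in zip(dm_records["chrom"], dm_records["pos"]):
            lengths[chrom] = max(lengths.get(chrom, 0), int(pos))
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end)
    return lengths


def scan_windows(
    dm_records: pd.DataFrame,
    de_records: pd.DataFrame,
    genes,
    window_size: int = DEFAULT_WINDOW,
    step: int = None,
    chrom_lengths: dict = None,
):
    """Per-window DM-site and DE-gene content for one comparison.

    A DM site belongs to a window by position; a gene by any overlap of
    its span, so boundary-spanning genes are counted in every window they
    touch.  ``de_records`` is a de_test frame indexed by gene_id.
    """
    lengths = infer_chrom_lengths(dm_records, genes, chrom_lengths)
    windows = tile_windows(lengths, window_size, step)
    by_chrom = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)

    sig = dm_records[dm_records["status"] != "ns"]
    for chrom, pos, status in zip(sig["chrom"], sig["pos"], sig["status"]):
        for i in by_chrom.get(chrom, ()):
            w = windows[i]
            if w.start <= pos <= w.end:
                if status == "hyper":
                    w.n_hyper += 1
                else:
                    w.n_hypo += 1

    for g in genes:
        if g.gene_id not in de_records.index:
            continue
        rec = de_records.loc[g.gene_id]
        for i in by_chrom.get(g.chrom, ()):
            w = windows[i]
            if g.start <= w.end and g.end >= w.start:
                w.de_genes.append(
                    (g.gene_id, float(rec["log2fc"]), str(rec["status"]))
                )

    for w in windows:
        w.colocalized = w.n_dm >= 1 and w.n_de >= 1
    return windows


def _gene_distance(pos, gene) -> int:
    """Gap between a site and a gene span; 0 when the site lies inside."""
    if pos < gene.start:
        return gene.start - pos
    if pos > gene.end:
        return pos - gene.end
    return 0


def rank_candidate_regulatory_windows(
    windows, dm_records: pd.DataFrame = None, genes=None
):
    """Rank co-localized windows as candidate regulatory regions.

    Score = (number of significant DM sites) x (number of significant DE
    genes); ties break by the summed |log2fc| of the window's DE genes,
    then by coordinates for determinism.  When ``dm_records`` and
    ``genes`` are given, each ranked window also reports the distance
    from each of its DM sites to the nearest significant DE gene.
    """
    gene_by_id = {g.gene_id: g for g in genes} if genes else {}
    ranked = []
    for w in windows:
        if not w.colocalized:
            continue
        score = w.n_dm * w.n_de
        tiebreak = sum(abs(fc) for _, fc, s in w.de_genes if s != "ns")
        distances = []
        if dm_records is not None and gene_by_id:
            sig = dm_records[
                (dm_records["status"] != "ns")
                & (dm_records["chrom"] == w.chrom)
                & (dm_records["pos"] >= w.start)
                & (dm_records["pos"] <= w.end)
            ]
            de_genes = [
                gene_by_id[gid]
                for gid, _, s in w.de_genes
                if s != "ns" and gid in gene_by_id
            ]
            for pos in sig["pos"]:
                d = min(_gene_distance(int(pos), g) for g in de_genes)
                distances.append(int(d))
        ranked.append((score, tiebreak, w, distances))
    ranked.sort(key=lambda r: (-r[0], -r[1], r[2].chrom, r[2].start))
    return [
        {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "score": score,
            "n_hyper": w.n_hyper,
            "n_hypo": w.n_hypo,
            "n_de": w.n_de,
            "sum_abs_log2fc": tiebreak,
            "dm_to_nearest_de_gene_bp": distances,
        }
        for score, tiebreak, w, distances in ranked
    ]


def windows_to_frame(windows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_hyper": w.n_hyper,
                "n_hypo": w.n_hypo,
                "n_de_genes": w.n_de,
                "de_gene_ids": ",".join(
                    gid for gid, _, s in w.de_genes if s != "ns"
                ),
                "colocalized": w.colocalized,
            }
            for w in windows
        ]
    )


def window_text_report(windows, comparison: str, max_rows: int = 40) -> str:
    """Per-chromosome text panel: DM bars and DE log2fc peaks per window."""
    lines = [f"Window scan — {comparison}"]
    for w in windows[:max_rows]:
        if w.n_dm == 0 and w.n_de == 0:
            continue
        bar = "+" * min(w.n_hyper, 30) + "-" * min(w.n_hypo, 30)
        peaks = " ".join(
            f"{gid}:{fc:+.1f}" for gid, fc, s in w.de_genes if s != "ns"
        )
        flag = " *colocalized*" if w.colocalized else ""
        lines.append(
            f"{w.chrom}:{w.start}-{w.end}  DM[{bar}] ({w.n_hyper}h/{w.n_hypo}l)"
            f"  DE[{peaks}]{flag}"
        )
    return "\n".join(lines) + "\n"
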
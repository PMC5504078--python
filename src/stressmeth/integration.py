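"""Methylation–transcription association over gene bodies and flanks.

For a set of consistently differentially expressed genes, per-CpG
methylation changes (percentage points, stressed minus control) are
filtered — average coverage of at least 6 reads per sample and an
absolute change of at least 8 pp — and averaged over the gene body plus
10 kb flanks.  Genes are then cross-classified by methylation-change
sign and expression direction into four quadrants (hyper-down,
hyper-up, hypo-up, hypo-down).  Welch's two-sample t-test compares mean
methylation changes between gene sets or comparisons, and paralog pairs
from the duplicated-block scan are checked for direction concordance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CpGMatrix, GeneModel, SampleDesign

DEFAULT_MIN_AVG_COV = 6.0
DEFAULT_MIN_ABS_CHANGE = 8.0  # percentage points
DEFAULT_FLANK = 10_000

QUADRANTS = ["hyper_down", "hyper_up", "hypo_up", "hypo_down"]


def filter_cpgs_for_integration(
    mat: CpGMatrix,
    change_pct: np.ndarray,
    min_avg_cov: float = DEFAULT_MIN_AVG_COV,
    min_abs_change: float = DEFAULT_MIN_ABS_CHANGE,
    per_sample_min: bool = False,
) -> np.ndarray:
    """Boolean mask of sites usable for the association step.

    A site is kept when its coverage averaged over all samples is at
    least ``min_avg_cov`` (with ``per_sample_min=True``, every single
    sample must reach it instead) AND the absolute methylation change in
    the comparison at hand is at least ``min_abs_change`` percentage
    points.  Both thresholds keep values meeting-or-exceeding the cutoff.
    """
    change_pct = np.asarray(change_pct, dtype=float)
    if change_pct.shape[0] != mat.n_sites:
        raise ValueError("change vector does not match site count")
    if per_sample_min:
        cov_ok = (mat.cov >= min_avg_cov).all(axis=1)
    else:
        cov_ok = mat.cov.mean(axis=1) >= min_avg_cov
    return cov_ok & (np.abs(change_pct) >= min_abs_change)


def gene_region_mean_change(
    gene: GeneModel, sites: pd.DataFrame, flank: int = DEFAULT_FLANK
):
    """Mean filtered methylation change over gene body +/- ``flank`` bp.

    ``sites`` must hold chrom/pos/change columns for already-filtered
    CpGs.  The region is [start - flank, end + flank], inclusive on both
    boundaries and clipped at the chromosome start.  Returns
    (n_cpg_used, mean change in pp); zero usable sites give (0, nan).
    """
    lo = max(1, gene.start - flank)
    hi = gene.end + flank
    sub = sites[
        (sites["chrom"] == gene.chrom)
        & (sites["pos"] >= lo)
        & (sites["pos"] <= hi)
    ]
    if sub.empty:
        return 0, float("nan")
    return int(len(sub)), float(sub["change"].mean())


def welch_t(sample_a, sample_b):
    """Welch's two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def profile_genes(
    genes,
    sites: pd.DataFrame,
    expr_direction: dict,
    comparison: str,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Per-gene methylation profile and quadrant for one comparison.

    ``expr_direction`` maps gene_id -> 'up'/'down' (from consistent_de or
    a single comparison's calls); genes absent from it are skipped.
    """
    rows = []
    for g in genes:
        direction = expr_direction.get(g.gene_id)
        if direction is None:
            continue
        n, mean_change = gene_region_mean_change(g, sites, flank=flank)
        if n == 0 or mean_change == 0:
            quadrant = "flat"
        elif mean_change > 0:
            quadrant = "hyper_down" if direction == "down" else "hyper_up"
        else:
            quadrant = "hypo_up" if direction == "up" else "hypo_down"
        rows.append(
            {
                "gene_id": g.gene_id,
                "comparison": comparison,
                "n_cpg_used": n,
                "mean_meth_change": mean_change,
                "expr_direction": direction,
                "quadrant": quadrant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "comparison",
            "n_cpg_used",
            "mean_meth_change",
            "expr_direction",
            "quadrant",
        ],
    )


def classify_quadrants(profiles: pd.DataFrame) -> dict:
    """Percentages per quadrant over genes with a non-flat quadrant.

    Returned in fixed order hyper_down, hyper_up, hypo_up, hypo_down;
    empty input (all flat) yields an empty dict.
    """
    informative = profiles[profiles["quadrant"] != "flat"]
    n = len(informative)
    if n == 0:
        import logging

        logging.getLogger(__name__).warning(
            "no gene has usable CpGs; quadrant report is empty"
        )
        return {}
    counts = informative["quadrant"].value_counts()
    return {q: 100.0 * counts.get(q, 0) / n for q in QUADRANTS}


def integration_change_table(
    mat: CpGMatrix,
    design: SampleDesign,
    group: str,
    control: str = "CO",
    min_avg_cov: float = DEFAULT_MIN_AVG_COV,
    min_abs_change: float = DEFAULT_MIN_ABS_CHANGE,
) -> pd.DataFrame:
    """Filtered per-site change table (chrom, pos, change) for one comparison."""
    from .diffmeth import pooled_meth_change

    change = pooled_meth_change(mat, design, group, control)
    mask = filter_cpgs_for_integration(
        mat, change, min_avg_cov=min_avg_cov, min_abs_change=min_abs_change
    )
    return pd.DataFrame(
        {"chrom": mat.chrom[mask], "pos": mat.pos[mask], "change": change[mask]}
    )


def paralog_direction_concordance(de_records: pd.DataFrame, pairs) -> float:
    """Fraction of paralog pairs changing expression in the same direction.

    Only pairs where both copies are significantly differentially
    expressed (status != 'ns') are counted; with no such pair the
    concordance is undefined and NaN is returned.
    """
    status = de_records["status"]
    same = total = 0
    for a, b in pairs:
        if a not in status.index or b not in status.index:
            continue
        sa, sb = status[a], status[b]
        if sa == "ns" or sb == "ns":
            continue
        total += 1
        same += int(sa == sb)
    return same / total if total else float("nan")
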
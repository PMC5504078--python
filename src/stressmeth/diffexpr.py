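"""Expression normalization and differential-expression classification.

Counts are normalized by the median-of-ratios rule: each sample's size
factor is the median, over genes with all-positive counts, of that
sample's count divided by the gene's geometric mean across samples.
Per-gene group differences are assessed with Welch's t-test on
log2(normalized + 1) and BH-adjusted; a gene is classified up/down when
the fold change on normalized means is at least ``fc`` (default 1.5) and
the adjusted p-value is below ``alpha`` (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .io_formats import SampleDesign, ValidationError

DEFAULT_FC = 1.5
DEFAULT_ALPHA = 0.05


def median_of_ratios_norm(counts: pd.DataFrame, pseudo_reference: bool = False):
    """Size factors and normalized matrix by the median-of-ratios rule.

    Parameters
    ----------
    counts : genes x samples raw count matrix (non-negative).
    pseudo_reference : if True, genes with any zero are given a geometric
        mean over their positive entries only (fallback for sparse
        matrices with no all-positive row).

    Returns
    -------
    (size_factors : pd.Series indexed by sample, normalized : pd.DataFrame)
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative counts")
    positive = (x > 0).all(axis=1)
    if not positive.any() and not pseudo_reference:
        raise ValidationError(
            "no gene has positive counts in every sample; rerun with "
            "pseudo_reference=True"
        )
    if pseudo_reference:
        with np.errstate(divide="ignore", invalid="ignore"):
            logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        geomean = np.exp(np.nanmean(logx, axis=1))
        use = ~np.isnan(geomean) & (geomean > 0)
    else:
        geomean = np.exp(np.log(x[positive]).mean(axis=1))
        use = None
    if use is None:
        ratios = x[positive] / geomean[:, None]
    else:
        ratios = np.where(x[use] > 0, x[use] / geomean[use, None], np.nan)
    size_factors = pd.Series(
        np.nanmedian(ratios, axis=0), index=counts.columns, name="size_factor"
    )
    if (size_factors <= 0).any() or size_factors.isna().any():
        raise ValidationError("degenerate size factors; check the count matrix")
    # rescale to geometric mean 1: makes factors equivariant under
    # per-sample rescaling (scaling one sample by c scales exactly its
    # factor by c) without touching their ratios
    size_factors = size_factors / np.exp(np.log(size_factors).mean())
    normalized = counts / size_factors
    return size_factors, normalized


def de_test(
    normalized: pd.DataFrame,
    design: SampleDesign,
    group: str,
    control: str = "CO",
    fc: float = DEFAULT_FC,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(normalized + 1), BH adjusted.

    Returns a frame indexed like ``normalized`` with columns
    log2fc, p, p_adj, status (up/down/ns).  log2fc is computed on
    normalized group means with a pseudocount of 1 (stressed vs control).
    """
    a = normalized[design.samples_in(control)].to_numpy(dtype=float)
    b = normalized[design.samples_in(group)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs >= 2 replicates")
    log_a = np.log2(a + 1.0)
    log_b = np.log2(b + 1.0)
    res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p undefined from the t statistic
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(log_b.mean(axis=1), log_a.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    log2fc = np.log2((b.mean(axis=1) + 1.0) / (a.mean(axis=1) + 1.0))
    p_adj = bh_adjust(p)
    log2_fc_cut = np.log2(fc)
    status = np.full(len(p), "ns", dtype=object)
    sig = p_adj < alpha
    status[(log2fc >= log2_fc_cut) & sig] = "up"
    status[(log2fc <= -log2_fc_cut) & sig] = "down"
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p_adj, "status": status},
        index=normalized.index,
    )


def consistent_de(de_by_group: dict, fc: float = DEFAULT_FC) -> pd.DataFrame:
    """Genes with a consistent >= ``fc`` fold change in every comparison.

    ``de_by_group`` maps each stressed group to its de_test frame.  A gene
    qualifies when |fold change| >= fc in *all* comparisons with the same
    sign throughout.  Returns gene_id-indexed frame with ``direction``
    (up/down) and per-group log2fc columns.
    """
    if not de_by_group:
        return pd.DataFrame(columns=["direction"])
    groups = sorted(de_by_group)
    cut = np.log2(fc)
    fcs = pd.DataFrame(
        {g: de_by_group[g]["log2fc"] for g in groups}
    ).dropna()
    up = (fcs >= cut).all(axis=1)
    down = (fcs <= -cut).all(axis=1)
    out = fcs.loc[up | down].copy()
    out.insert(0, "direction", np.where(up[up | down], "up", "down"))
    out.columns = ["direction"] + [f"log2fc_{g}" for g in groups]
    return out
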
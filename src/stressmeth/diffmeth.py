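"""Per-CpG differential methylation testing (stressed group vs control).

The test is a binomial logistic regression of per-sample methylated /
unmethylated counts on a group indicator, assessed by the likelihood-ratio
(deviance) statistic against the intercept-only model.  With a single
binary covariate the maximum-likelihood fit is available in closed form —
the fitted group probabilities are the coverage-pooled proportions — so the
whole scan is vectorized across sites.  A CpG is called differentially
methylated when the pooled methylation difference exceeds ``delta``
percentage points in absolute value and the BH-adjusted p-value falls
below ``q_threshold`` (defaults 20 pp and 0.1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .io_formats import CpGMatrix, SampleDesign

log = logging.getLogger(__name__)

DEFAULT_DELTA = 20.0  # percentage points
DEFAULT_Q = 0.1
DEFAULT_MIN_COV = 10
DEFAULT_MAX_COV_PERCENTILE = 99.9


def filter_sites(
    mat: CpGMatrix,
    design: SampleDesign,
    group: str,
    control: str = "CO",
    min_cov: int = DEFAULT_MIN_COV,
    max_cov_percentile: float = DEFAULT_MAX_COV_PERCENTILE,
) -> CpGMatrix:
    """Coverage prefilter before testing.

    Keeps sites whose coverage is >= ``min_cov`` in *every* sample of the
    two compared groups and at most each sample's ``max_cov_percentile``
    coverage percentile (guard against PCR-duplicate pileups).
    """
    cols = mat.sample_index(design.samples_in(control) + design.samples_in(group))
    cov = mat.cov[:, cols]
    keep = (cov >= min_cov).all(axis=1)
    if max_cov_percentile is not None and len(mat.pos):
        caps = np.percentile(cov, max_cov_percentile, axis=0)
        keep &= (cov <= caps).all(axis=1)
    if not keep.any():
        log.warning("coverage filter removed every site")
    return mat.subset(keep)


def _pooled(mat: CpGMatrix, design: SampleDesign, group: str):
    cols = mat.sample_index(design.samples_in(group))
    return mat.meth[:, cols].sum(axis=1), mat.cov[:, cols].sum(axis=1)


def _binom_ll(m, c, p):
    """Binomial log-likelihood kernel (constants dropped)."""
    return xlogy(m, p) + xlogy(c - m, 1.0 - p)


def lrt_logistic_test_arrays(ma, ca, mb, cb):
    """Vectorized deviance test of the two-group binomial logistic model.

    Parameters are pooled (methylated, coverage) counts for control (a)
    and stressed (b) groups.  Returns (meth_diff in percentage points,
    two-sided p from the upper chi-square_1 tail).  Sites where either
    group has zero coverage, or where methylation is identically 0 or 1
    in both groups, return meth_diff = 0 and p = 1.
    """
    ma, ca, mb, cb = (np.asarray(x, dtype=float) for x in (ma, ca, mb, cb))
    ok = (ca > 0) & (cb > 0)
    pa = np.divide(ma, ca, out=np.zeros_like(ma), where=ok)
    pb = np.divide(mb, cb, out=np.zeros_like(mb), where=ok)
    pp = np.divide(ma + mb, ca + cb, out=np.zeros_like(ma), where=ok)
    with np.errstate(all="ignore"):
        dev = 2.0 * (
            _binom_ll(ma, ca, pa)
            + _binom_ll(mb, cb, pb)
            - _binom_ll(ma + mb, ca + cb, pp)
        )
    dev = np.clip(np.nan_to_num(dev), 0.0, None)
    p = np.where(ok, stats.chi2.sf(dev, df=1), 1.0)
    meth_diff = np.where(ok, 100.0 * (pb - pa), 0.0)
    # degenerate: all-zero or all-one methylation in both groups
    degenerate = ok & ((ma + mb == 0) | (ma + mb == ca + cb))
    p = np.where(degenerate, 1.0, p)
    return meth_diff, p


def lrt_logistic_test(site, design: SampleDesign, group_a: str, group_b: str):
    """Per-site test on a CpGSiteCounts-like record.

    ``site.counts`` holds per-sample (n_meth, n_unmeth) pairs ordered as
    ``design.samples``; group_a is the control.
    """
    counts = np.asarray(site.counts, dtype=float)
    ia = [design.samples.index(s) for s in design.samples_in(group_a)]
    ib = [design.samples.index(s) for s in design.samples_in(group_b)]
    ma = counts[ia, 0].sum()
    ca = counts[ia].sum()
    mb = counts[ib, 0].sum()
    cb = counts[ib].sum()
    d, p = lrt_logistic_test_arrays([ma], [ca], [mb], [cb])
    return float(d[0]), float(p[0])


def fisher_exact_pooled(ma, ca, mb, cb):
    """Exact test on the pooled 2x2 table (fallback for tiny counts)."""
    table = [[int(ma), int(ca - ma)], [int(mb), int(cb - mb)]]
    return stats.fisher_exact(table)[1]


def pooled_meth_change(
    mat: CpGMatrix, design: SampleDesign, group: str, control: str = "CO"
) -> np.ndarray:
    """Per-site pooled methylation difference (group minus control), pp."""
    ma, ca = _pooled(mat, design, control)
    mb, cb = _pooled(mat, design, group)
    diff, _ = lrt_logistic_test_arrays(ma, ca, mb, cb)
    return diff


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dm_test(
    mat: CpGMatrix, design: SampleDesign, group: str, control: str = "CO"
) -> pd.DataFrame:
    """Run the per-CpG logistic LRT for one stressed-vs-control comparison."""
    ma, ca = _pooled(mat, design, control)
    mb, cb = _pooled(mat, design, group)
    meth_diff, p = lrt_logistic_test_arrays(ma, ca, mb, cb)
    return pd.DataFrame(
        {
            "chrom": mat.chrom,
            "pos": mat.pos,
            "meth_diff": meth_diff,
            "p": p,
        }
    )


def call_dm(
    records: pd.DataFrame, delta: float = DEFAULT_DELTA, q_threshold: float = DEFAULT_Q
) -> pd.DataFrame:
    """Attach q-values and hyper/hypo/ns status to test results."""
    out = records.copy()
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    status = np.full(len(out), "ns", dtype=object)
    if len(out):
        sig = out["q"].to_numpy() < q_threshold
        status[(out["meth_diff"].to_numpy() > delta) & sig] = "hyper"
        status[(out["meth_diff"].to_numpy() < -delta) & sig] = "hypo"
    out["status"] = status
    return out


def summarize_dm(dm: pd.DataFrame, mat: CpGMatrix = None) -> dict:
    """Headline summary: DM counts, hyper excess, global methylation."""
    n_hyper = int((dm["status"] == "hyper").sum()) if len(dm) else 0
    n_hypo = int((dm["status"] == "hypo").sum()) if len(dm) else 0
    excess = 100.0 * (n_hyper - n_hypo) / n_hypo if n_hypo else float("nan")
    summary = {
        "n_sites_tested": int(len(dm)),
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "hyper_excess_pct": excess,
    }
    if mat is not None and mat.cov.sum() > 0:
        summary["global_methylation_pct"] = float(
            100.0 * mat.meth.sum() / mat.cov.sum()
        )
    return summary
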
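import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressmeth import integration
from stressmeth.io_formats import CpGMatrix, GeneModel

from conftest import methylation_scenario


def _matrix(cov_rows, samples=None):
    cov = np.asarray(cov_rows)
    samples = samples or [f"s{i}" for i in range(cov.shape[1])]
    return CpGMatrix(
        chrom=np.array(["chr1"] * len(cov), dtype=object),
        pos=np.arange(10, 10 + 10 * len(cov), 10),
        samples=samples,
        meth=np.zeros_like(cov),
        cov=cov,
    )


# ---------------------------------------------------------------------------
# CpG filter
# ---------------------------------------------------------------------------


def test_filter_coverage_boundary_inclusive_at_6():
    mat = _matrix([[5, 6, 6, 6], [6, 6, 6, 6]])  # means 5.75 and 6.0
    mask = integration.filter_cpgs_for_integration(
        mat, np.array([20.0, 20.0]), min_avg_cov=6.0
    )
    assert mask.tolist() == [False, True]


def test_filter_change_boundary_inclusive_at_8pp():
    mat = _matrix([[10, 10], [10, 10]])
    mask = integration.filter_cpgs_for_integration(mat, np.array([7.9, 8.0]))
    assert mask.tolist() == [False, True]
    mask_neg = integration.filter_cpgs_for_integration(mat, np.array([-8.0, -7.9]))
    assert mask_neg.tolist() == [True, False]


def test_filter_per_sample_min_variant_is_stricter():
    mat = _matrix([[2, 10, 10, 10]])  # mean 8 but one sample below 6
    change = np.array([20.0])
    assert integration.filter_cpgs_for_integration(mat, change)[0]
    assert not integration.filter_cpgs_for_integration(
        mat, change, per_sample_min=True
    )[0]


def test_filter_matches_bruteforce_on_simulated_sites():
    mat, design, _ = methylation_scenario(13, 500, np.zeros(500))
    from stressmeth.diffmeth import pooled_meth_change

    change = pooled_meth_change(mat, design, "E")
    mask = integration.filter_cpgs_for_integration(mat, change)
    expected = np.array(
        [
            mat.cov[i].mean() >= 6.0 and abs(change[i]) >= 8.0
            for i in range(mat.n_sites)
        ]
    )
    np.testing.assert_array_equal(mask, expected)


# ---------------------------------------------------------------------------
# gene-region mean change
# ---------------------------------------------------------------------------


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "change"])


def test_region_mean_is_unweighted_average():
    g = GeneModel(gene_id="g", chrom="chr1", strand="+", start=50_000, end=60_000,
                  exons=[(50_000, 60_000)])
    sites = _sites([("chr1", 55_000, 10.0), ("chr1", 58_000, 30.0)])
    n, mean = integration.gene_region_mean_change(g, sites)
    assert (n, mean) == (2, 20.0)


def test_region_boundaries_inclusive_at_flank_edge():
    g = GeneModel(gene_id="g", chrom="chr1", strand="+", start=50_000, end=60_000,
                  exons=[(50_000, 60_000)])
    sites = _sites(
        [("chr1", 40_000, 5.0), ("chr1", 39_999, 99.0), ("chr1", 70_000, 15.0)]
    )
    n, mean = integration.gene_region_mean_change(g, sites, flank=10_000)
    assert n == 2
    assert mean == pytest.approx(10.0)


def test_region_mean_invariant_to_site_order():
    rng = np.random.default_rng(5)
    g = GeneModel(gene_id="g", chrom="chr1", strand="+", start=100_000, end=120_000,
                  exons=[(100_000, 120_000)])
    rows = [
        ("chr1", int(p), float(c))
        for p, c in zip(
            rng.integers(80_000, 140_000, size=50), rng.normal(0, 20, size=50)
        )
    ]
    a = integration.gene_region_mean_change(g, _sites(rows))
    b = integration.gene_region_mean_change(g, _sites(rows[::-1]))
    assert a[0] == b[0] and a[1] == pytest.approx(b[1])


def test_zero_sites_is_flat():
    g = GeneModel(gene_id="g", chrom="chr5", strand="+", start=1000, end=2000,
                  exons=[(1000, 2000)])
    n, mean = integration.gene_region_mean_change(g, _sites([]))
    assert n == 0 and np.isnan(mean)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------


def test_welch_identical_samples_null():
    t, df, p = integration.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_welch_matches_textbook_formulas_and_scipy():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    t, df, p = integration.welch_t(a, b)
    # hand computation: means 2 and 5, s^2 = 1 each, se^2 = 2/3
    assert t == pytest.approx((2 - 5) / np.sqrt(2 / 3))
    assert df == pytest.approx(4.0)  # equal var & n -> 2n-2
    res = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(res.statistic)
    assert p == pytest.approx(res.pvalue)


def test_welch_null_p_uniformity():
    rng = np.random.default_rng(17)
    pvals = [
        integration.welch_t(rng.normal(size=8), rng.normal(size=12))[2]
        for _ in range(1000)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# quadrants and paralog concordance
# ---------------------------------------------------------------------------


def _profiles(counts):
    rows = []
    for quad, n in counts.items():
        sign = 1.0 if quad.startswith("hyper") else -1.0
        direction = "down" if quad.endswith("down") else "up"
        rows += [
            {"gene_id": f"{quad}{i}", "comparison": "E", "n_cpg_used": 3,
             "mean_meth_change": sign * 10.0, "expr_direction": direction,
             "quadrant": quad}
            for i in range(n)
        ]
    return pd.DataFrame(rows)


def test_quadrant_percentages_arithmetic():
    pct = integration.classify_quadrants(
        _profiles({"hyper_down": 9, "hyper_up": 5, "hypo_up": 3, "hypo_down": 3})
    )
    assert pct == {
        "hyper_down": 45.0, "hyper_up": 25.0, "hypo_up": 15.0, "hypo_down": 15.0
    }
    assert sum(pct.values()) == pytest.approx(100.0)


def test_all_flat_returns_empty_report(caplog):
    flat = pd.DataFrame(
        [{"gene_id": "g", "comparison": "E", "n_cpg_used": 0,
          "mean_meth_change": np.nan, "expr_direction": "up", "quadrant": "flat"}]
    )
    with caplog.at_level("WARNING"):
        assert integration.classify_quadrants(flat) == {}


def test_profile_quadrant_sign_convention():
    g = GeneModel(gene_id="g", chrom="chr1", strand="+", start=1000, end=3000,
                  exons=[(1000, 3000)])
    sites = _sites([("chr1", 2000, 12.0)])
    prof = integration.profile_genes([g], sites, {"g": "down"}, "E")
    assert prof["quadrant"].item() == "hyper_down"


def test_paralog_concordance_fraction_and_na():
    de = pd.DataFrame(
        {"status": ["up", "up", "down", "down", "up", "down", "ns"]},
        index=[f"g{i}" for i in range(7)],
    )
    frac = integration.paralog_direction_concordance(
        de, [("g0", "g1"), ("g2", "g3"), ("g4", "g5"), ("g4", "g6")]
    )
    assert frac == pytest.approx(2 / 3)
    assert np.isnan(
        integration.paralog_direction_concordance(de, [("g0", "g6")])
    )
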
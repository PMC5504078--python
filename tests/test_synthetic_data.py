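import numpy as np
import pandas as pd
import pytest

from stressmeth.io_formats import load_coverage_dir, read_gtf
from stressmeth.synthetic_data import (
    SimulationConfig,
    make_design,
    simulate_genome,
    simulate_methylation,
    simulate_expression,
    simulate_study,
)


def test_config_validation_catches_bad_fractions():
    with pytest.raises(ValueError, match="dm_fraction"):
        SimulationConfig(dm_fraction=1.5).validate()
    with pytest.raises(ValueError, match="quadrant_mix"):
        SimulationConfig(quadrant_mix=(0.5, 0.5, 0.5, 0.5)).validate()


def test_design_is_four_groups_by_six():
    design = make_design(SimulationConfig())
    assert len(design.samples) == 24
    assert design.groups == ["CO", "E", "PH", "EPH"]
    assert all(len(design.samples_in(g)) == 6 for g in design.groups)


def test_genome_is_deterministic_and_exact_cpg_count():
    cfg = SimulationConfig(seed=3, n_genes=60, n_cpg=1000)
    g1, cl1, cpg1 = simulate_genome(cfg, np.random.default_rng(3))
    g2, cl2, cpg2 = simulate_genome(cfg, np.random.default_rng(3))
    assert [(g.gene_id, g.start, g.end) for g in g1] == [
        (g.gene_id, g.start, g.end) for g in g2
    ]
    pd.testing.assert_frame_equal(cpg1, cpg2)
    assert len(cpg1) == 1000
    assert not cpg1.duplicated(["chrom", "pos"]).any()


def test_genes_do_not_overlap():
    cfg = SimulationConfig(seed=5, n_genes=90)
    genes, _, _ = simulate_genome(cfg, np.random.default_rng(5))
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            assert a.end < b.start


def test_infeasible_packing_raises():
    cfg = SimulationConfig(n_chrom=1, chrom_length=50_000, n_genes=30)
    with pytest.raises(ValueError, match="packing"):
        simulate_genome(cfg, np.random.default_rng(0))


def test_global_methylation_tracks_beta_mean():
    # Beta(8, 2) has mean 0.8, so pooled methylation should sit near 80%
    for n_cpg, tol in ((1000, 3.0), (10_000, 1.5)):
        cfg = SimulationConfig(seed=1, n_cpg=n_cpg)
        rng = np.random.default_rng(1)
        cpg = pd.DataFrame(
            {"chrom": ["chr1"] * n_cpg, "pos": np.arange(10, 10 + n_cpg * 5, 5)}
        )
        design = make_design(cfg)
        mat, _ = simulate_methylation(cfg, cpg, np.zeros(n_cpg), design, rng)
        global_pct = 100 * mat.meth.sum() / mat.cov.sum()
        assert global_pct == pytest.approx(80.0, abs=tol)


def test_null_simulation_has_no_group_effect():
    cfg = SimulationConfig(seed=2, n_cpg=2000)
    rng = np.random.default_rng(2)
    cpg = pd.DataFrame(
        {"chrom": ["chr1"] * 2000, "pos": np.arange(10, 10 + 2000 * 5, 5)}
    )
    design = make_design(cfg)
    mat, _ = simulate_methylation(cfg, cpg, np.zeros(2000), design, rng)
    co = [i for i, s in enumerate(design.samples) if s.startswith("CO")]
    e = [i for i, s in enumerate(design.samples) if s.startswith("E") and not s.startswith("EPH")]
    diff = mat.meth[:, e].sum() / mat.cov[:, e].sum() - mat.meth[:, co].sum() / mat.cov[:, co].sum()
    assert abs(diff) < 0.01


def test_precision_limit_approaches_binomial_variance():
    # overdispersion factor ~1 for huge precision, >1.5 for precision 20
    def dispersion_ratio(theta, seed=6):
        cfg = SimulationConfig(seed=seed, bb_precision=theta)
        rng = np.random.default_rng(seed)
        n = 2000
        cpg = pd.DataFrame(
            {"chrom": ["chr1"] * n, "pos": np.arange(10, 10 + n * 5, 5)}
        )
        design = make_design(cfg)
        mat, baseline = simulate_methylation(cfg, cpg, np.zeros(n), design, rng)
        ok = (mat.cov > 0).all(axis=1)
        phat = mat.meth[ok] / mat.cov[ok]
        observed = phat.var(axis=1, ddof=1)
        p = phat.mean(axis=1)[:, None]
        binom = (p * (1 - p) / mat.cov[ok]).mean(axis=1)
        keep = binom > 1e-6
        return float(np.median(observed[keep] / binom[keep]))

    assert dispersion_ratio(1e9) == pytest.approx(1.0, abs=0.15)
    assert dispersion_ratio(20.0) > 1.5


def test_expression_null_and_planted_fold_change():
    cfg = SimulationConfig(
        seed=4, expr_log_mean=np.log(500.0), expr_log_sd=0.0,
        size_factor_low=1.0, size_factor_high=1.0 + 1e-9,
    )
    design = make_design(cfg)
    genes = [f"g{i}" for i in range(600)]
    fc = {g: 2.0 for g in genes[:300]}  # planted log2FC = 2 for half
    counts = simulate_expression(cfg, genes, fc, design, np.random.default_rng(4))
    co = design.samples_in("CO")
    e = design.samples_in("E")
    ratio_planted = counts.loc[genes[:300], e].mean(axis=1).mean() / \
        counts.loc[genes[:300], co].mean(axis=1).mean()
    ratio_null = counts.loc[genes[300:], e].mean(axis=1).mean() / \
        counts.loc[genes[300:], co].mean(axis=1).mean()
    assert ratio_planted == pytest.approx(4.0, rel=0.1)
    assert ratio_null == pytest.approx(1.0, rel=0.1)


def test_same_seed_studies_are_identical(default_study):
    other = simulate_study(SimulationConfig(seed=11))
    np.testing.assert_array_equal(default_study.methylation.meth, other.methylation.meth)
    np.testing.assert_array_equal(default_study.methylation.cov, other.methylation.cov)
    pd.testing.assert_frame_equal(default_study.counts, other.counts)
    pd.testing.assert_frame_equal(default_study.hits, other.hits)
    pd.testing.assert_frame_equal(default_study.truth.dm_sites, other.truth.dm_sites)


def test_planted_truth_bookkeeping(default_study):
    study = default_study
    site_set = set(zip(study.methylation.chrom, study.methylation.pos))
    for row in study.truth.dm_sites.itertuples(index=False):
        assert (row.chrom, row.pos) in site_set
    # every planted shift has full headroom: baseline + shift within (0, 1)
    planted = study.shift != 0
    assert np.all(study.baseline[planted] + study.shift[planted] < 1.0)
    assert np.all(study.baseline[planted] + study.shift[planted] > 0.0)
    rep_pairs = set(zip(study.hits["query_id"], study.hits["subject_id"]))
    for row in study.truth.pairs.itertuples(index=False):
        assert any(row.gene_a in q and row.gene_b in s for q, s in rep_pairs)


def test_written_study_round_trips(study_dir, default_study):
    design = default_study.design
    mat = load_coverage_dir(study_dir / "coverage", design, destrand=True)
    # destranded read-back reproduces the in-memory matrix exactly
    np.testing.assert_array_equal(mat.pos, default_study.methylation.pos)
    np.testing.assert_array_equal(mat.meth, default_study.methylation.meth)
    np.testing.assert_array_equal(mat.cov, default_study.methylation.cov)
    genes = read_gtf(study_dir / "annotation.gtf")
    assert {g.gene_id for g in genes} == {g.gene_id for g in default_study.genes}
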
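import numpy as np
import pandas as pd
import pytest

from stressmeth import diffexpr
from stressmeth.io_formats import SampleDesign, ValidationError


def _design(n_per_group=6, groups=("CO", "E")):
    rows = [
        {"sample_id": f"{g}{i+1}", "group": g, "replicate": i + 1}
        for g in groups
        for i in range(n_per_group)
    ]
    return SampleDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# median-of-ratios normalization
# ---------------------------------------------------------------------------


def test_size_factor_ratio_on_doubled_sample():
    rng = np.random.default_rng(1)
    base = rng.integers(10, 1000, size=50)
    counts = pd.DataFrame({"s1": base, "s2": 2 * base})
    sf, norm = diffexpr.median_of_ratios_norm(counts)
    assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
    pd.testing.assert_series_equal(norm["s1"], norm["s2"], check_names=False)


def test_identical_samples_get_equal_factors():
    counts = pd.DataFrame({"a": [5, 9, 100], "b": [5, 9, 100], "c": [5, 9, 100]})
    sf, _ = diffexpr.median_of_ratios_norm(counts)
    np.testing.assert_allclose(sf, sf.iloc[0])


def test_single_gene_factors_are_ratios_to_geomean():
    counts = pd.DataFrame({"a": [4], "b": [9]})
    sf, _ = diffexpr.median_of_ratios_norm(counts)
    geomean = 6.0
    assert sf["a"] == pytest.approx(4 / geomean)
    assert sf["b"] == pytest.approx(9 / geomean)


def test_scaling_equivariance_property():
    # multiplying one sample by c multiplies its factor relative to every
    # other sample by exactly c, and normalized values change only by one
    # global constant (the reference geomeans absorb c^(1/m))
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(40, 4)), columns=list("abcd")
    )
    c = 3.0
    sf0, norm0 = diffexpr.median_of_ratios_norm(counts)
    scaled = counts.copy()
    scaled["c"] = scaled["c"] * c
    sf1, norm1 = diffexpr.median_of_ratios_norm(scaled)
    for other in "abd":
        ratio0 = sf0["c"] / sf0[other]
        ratio1 = sf1["c"] / sf1[other]
        assert ratio1 == pytest.approx(c * ratio0)
    rescale = norm1.iloc[0, 0] / norm0.iloc[0, 0]
    pd.testing.assert_frame_equal(norm1 / rescale, norm0)


def test_no_all_positive_row_errors_and_fallback_works():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValidationError, match="pseudo"):
        diffexpr.median_of_ratios_norm(counts)
    sf, _ = diffexpr.median_of_ratios_norm(counts, pseudo_reference=True)
    assert (sf > 0).all()


# ---------------------------------------------------------------------------
# DE classification
# ---------------------------------------------------------------------------


def test_constant_gene_is_ns():
    design = _design()
    norm = pd.DataFrame(
        {s: [100.0, 50.0] for s in design.samples}, index=["g1", "g2"]
    )
    de = diffexpr.de_test(norm, design, "E")
    assert de.loc["g1", "log2fc"] == 0.0
    assert (de["status"] == "ns").all()


def test_fold_change_boundary_is_exclusive_below_1_5():
    # ratio 1.49 < 1.5 stays ns no matter how significant
    design = _design()
    a = {s: [100.0] for s in design.samples_in("CO")}
    b = {s: [149.5 - 1.0] for s in design.samples_in("E")}  # (mean_b+1)/(mean_a+1)=1.485
    norm = pd.DataFrame({**a, **b}, index=["g"])[design.samples]
    de = diffexpr.de_test(norm, design, "E")
    assert de.loc["g", "log2fc"] < np.log2(1.5)
    assert de.loc["g", "status"] == "ns"


def test_label_swap_negates_log2fc():
    rng = np.random.default_rng(3)
    design = _design()
    norm = pd.DataFrame(
        rng.uniform(10, 1000, size=(30, 12)), columns=design.samples
    )
    fwd = diffexpr.de_test(norm, design, "E", control="CO")
    rev = diffexpr.de_test(norm, design, "CO", control="E")
    np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
    np.testing.assert_allclose(fwd["p"], rev["p"])


def test_null_rejection_rate_near_nominal():
    rng = np.random.default_rng(4)
    design = _design()
    norm = pd.DataFrame(
        rng.lognormal(5, 0.3, size=(4000, 12)), columns=design.samples
    )
    de = diffexpr.de_test(norm, design, "E")
    assert (de["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.012)


def test_planted_fold_change_recovery(default_study):
    from stressmeth.synthetic_data import SimulationConfig

    study = default_study
    _, norm = diffexpr.median_of_ratios_norm(study.counts)
    de = diffexpr.de_test(norm, study.design, "E")
    truth = dict(zip(study.truth.de_genes["gene_id"], study.truth.de_genes["log2fc"]))
    up_truth = [g for g, fc in truth.items() if fc > 0]
    called_up = set(de.index[de["status"] == "up"])
    assert len(called_up & set(up_truth)) / len(up_truth) >= 0.8


# ---------------------------------------------------------------------------
# consistent DE across all stressed groups
# ---------------------------------------------------------------------------


def test_consistent_de_requires_same_sign_everywhere():
    idx = ["g_up", "g_mixed", "g_down", "g_weak"]
    frames = {}
    for g, fcs in (
        ("E", [1.0, 1.0, -1.0, 0.4]),
        ("PH", [1.0, 1.0, -1.0, 0.4]),
        ("EPH", [1.0, -1.0, -1.0, 0.4]),
    ):
        frames[g] = pd.DataFrame(
            {"log2fc": fcs, "p": 0.001, "p_adj": 0.001, "status": "up"}, index=idx
        )
    out = diffexpr.consistent_de(frames)
    assert list(out.index) == ["g_up", "g_down"]
    assert out.loc["g_up", "direction"] == "up"
    assert out.loc["g_down", "direction"] == "down"


def test_consistent_de_recovers_noise_free_construction():
    idx = [f"g{i}" for i in range(10)]
    fcs = np.array([2.0] * 4 + [-2.0] * 3 + [0.0] * 3)
    frames = {
        g: pd.DataFrame(
            {"log2fc": fcs, "p": 0.5, "p_adj": 0.5, "status": "ns"}, index=idx
        )
        for g in ("E", "PH", "EPH")
    }
    out = diffexpr.consistent_de(frames)
    assert len(out) == 7
    assert (out["direction"].iloc[:4] == "up").all()
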
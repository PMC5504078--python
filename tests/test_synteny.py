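import numpy as np
import pandas as pd
import pytest

from stressmeth import synteny
from stressmeth.io_formats import GeneModel, Transcript, ValidationError


def _gene(gid, chrom, start, end, tx_lengths=(1000,)):
    txs = []
    for i, L in enumerate(tx_lengths):
        txs.append(Transcript(f"{gid}.t{i+1}", ((start, start + L - 1),)))
    return GeneModel(
        gene_id=gid, chrom=chrom, strand="+", start=start, end=end,
        exons=[(start, end)], transcripts=txs,
    )


def _hits(rows):
    """rows: (query_tx, subject_tx, e_value[, bit_score])"""
    return pd.DataFrame(
        [
            {
                "query_id": q, "subject_id": s, "percent_identity": 95.0,
                "alignment_length": 500, "mismatches": 5, "gap_opens": 0,
                "q_start": 1, "q_end": 500, "s_start": 1, "s_end": 500,
                "e_value": e, "bit_score": (r[3] if len(r) > 3 else 100.0),
            }
            for r in rows
            for q, s, e in [r[:3]]
        ]
    )


# ---------------------------------------------------------------------------
# representative transcripts and best hits
# ---------------------------------------------------------------------------


def test_longest_transcript_selection_and_ties():
    g1 = _gene("g1", "chr1", 100, 2000, tx_lengths=(900, 1200))
    g2 = _gene("g2", "chr1", 5000, 7000, tx_lengths=(800,))
    g3 = _gene("g3", "chr1", 9000, 11000, tx_lengths=(600, 600))
    rep = synteny.longest_transcript_db([g1, g2, g3])
    assert rep == {"g1": "g1.t2", "g2": "g2.t1", "g3": "g3.t1"}


def test_second_best_hit_skips_self_and_orders_by_evalue():
    tx2g = {"gA.t1": "gA", "gB.t1": "gB", "gC.t1": "gC"}
    hits = _hits(
        [
            ("gA.t1", "gA.t1", 0.0),      # self, dropped
            ("gA.t1", "gB.t1", 1e-50),
            ("gA.t1", "gC.t1", 1e-20),
        ]
    )
    best = synteny.second_best_hits(hits, tx2g)
    assert best["gA"][0] == "gB"


def test_hit_above_cutoff_leaves_gene_unmapped():
    tx2g = {"gA.t1": "gA", "gB.t1": "gB"}
    best = synteny.second_best_hits(_hits([("gA.t1", "gB.t1", 1e-9)]), tx2g)
    assert "gA" not in best


def test_second_best_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(31)
    genes = [f"g{i}" for i in range(12)]
    tx2g = {f"g{i}.t1": f"g{i}" for i in range(12)}
    for _ in range(200):
        n = int(rng.integers(5, 40))
        rows = []
        for _ in range(n):
            q, s = rng.choice(12, size=2)
            rows.append(
                (f"g{q}.t1", f"g{s}.t1", float(10.0 ** -rng.uniform(0, 40)),
                 float(rng.integers(50, 500)))
            )
        hits = _hits(rows)
        got = synteny.second_best_hits(hits, tx2g, e_cutoff=1e-10)
        # brute force min-scan
        expected = {}
        for row in hits.itertuples(index=False):
            qg, sg = tx2g[row.query_id], tx2g[row.subject_id]
            if qg == sg or row.e_value > 1e-10:
                continue
            key = (row.e_value, -row.bit_score, sg)
            if qg not in expected or key < expected[qg][0]:
                expected[qg] = (key, sg)
        assert {g: v[1] for g, v in expected.items()} == {
            g: v[0] for g, v in got.items()
        }


def test_reciprocal_requires_mutuality():
    best = {"A": ("B", 1e-30), "B": ("A", 1e-25), "C": ("A", 1e-30)}
    pairs = synteny.reciprocal_pairs(best)
    assert [(p.gene_a, p.gene_b) for p in pairs] == [("A", "B")]


# ---------------------------------------------------------------------------
# block chaining
# ---------------------------------------------------------------------------


def _collinear_setup(n_pairs, inverted=False, chrom_b="chr2"):
    genes = []
    pairs = []
    for i in range(n_pairs):
        a = _gene(f"a{i:02d}", "chr1", 1000 + i * 10_000, 1000 + i * 10_000 + 5000)
        genes.append(a)
    for i in range(n_pairs):
        j = n_pairs - 1 - i if inverted else i
        b = _gene(f"b{j:02d}", chrom_b, 1000 + i * 10_000, 1000 + i * 10_000 + 5000)
        genes.append(b)
    for i in range(n_pairs):
        pairs.append(
            synteny.ReciprocalPair(f"a{i:02d}", f"b{i:02d}", 1e-40, 1e-40)
        )
    return genes, pairs


def test_twelve_collinear_pairs_form_one_same_orientation_block():
    genes, pairs = _collinear_setup(12)
    blocks = synteny.chain_blocks(pairs, synteny.gene_order(genes))
    assert len(blocks) == 1
    assert blocks[0].n_genes == 12
    assert blocks[0].orientation == "same"


def test_nine_pairs_below_min_genes_yield_no_block():
    genes, pairs = _collinear_setup(9)
    assert synteny.chain_blocks(pairs, synteny.gene_order(genes),
                                min_genes=10) == []


def test_reversed_partner_order_gives_inverted_block():
    genes, pairs = _collinear_setup(12, inverted=True)
    blocks = synteny.chain_blocks(pairs, synteny.gene_order(genes))
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"


def test_chain_broken_by_large_gap():
    genes, pairs = _collinear_setup(12)
    # remove 3 consecutive anchors in the middle -> gap of 3 > max_gap=2
    pruned = [p for p in pairs if p.gene_a not in {"a05", "a06", "a07"}]
    blocks = synteny.chain_blocks(pruned, synteny.gene_order(genes), min_genes=4)
    assert [b.n_genes for b in blocks] == [5, 4]
    assert synteny.chain_blocks(
        pruned, synteny.gene_order(genes), min_genes=5
    )[0].n_genes == 5


def test_missing_gene_in_annotation_is_an_error():
    genes, pairs = _collinear_setup(3)
    with pytest.raises(ValidationError, match="ghost"):
        synteny.chain_blocks(
            pairs + [synteny.ReciprocalPair("ghost", "b00", 1e-40, 1e-40)],
            synteny.gene_order(genes), min_genes=2,
        )


def test_block_symmetry_under_role_swap():
    genes, pairs = _collinear_setup(12)
    swapped = [
        synteny.ReciprocalPair(p.gene_b, p.gene_a, p.e_value_ba, p.e_value_ab)
        for p in pairs
    ]
    order = synteny.gene_order(genes)
    b1 = synteny.chain_blocks(pairs, order)
    b2 = synteny.chain_blocks(swapped, order)
    regions1 = {(b.chrom_a, b.index_range_a, b.chrom_b, b.index_range_b) for b in b1}
    regions2 = {(b.chrom_a, b.index_range_a, b.chrom_b, b.index_range_b) for b in b2}
    assert regions1 == regions2


# ---------------------------------------------------------------------------
# end to end on planted simulations
# ---------------------------------------------------------------------------


def test_planted_blocks_recovered_exactly(default_study):
    study = default_study
    blocks, pairs = synteny.find_blocks(study.genes, study.hits)
    assert len(blocks) == len(study.truth.blocks)
    planted_pairs = {
        tuple(sorted(p))
        for p in zip(study.truth.pairs["gene_a"], study.truth.pairs["gene_b"])
    }
    found_pairs = {tuple(sorted((p.gene_a, p.gene_b))) for p in pairs}
    assert planted_pairs == found_pairs
    for b in blocks:
        assert b.orientation == "same"
        # every member pair is reciprocal below the cutoff (re-check)
        for p in b.pairs:
            assert max(p.e_value_ab, p.e_value_ba) <= 1e-10


def test_zero_planted_blocks_yield_zero_blocks():
    from stressmeth.synthetic_data import SimulationConfig, simulate_study

    study = simulate_study(
        SimulationConfig(seed=23, n_blocks=0, n_genes=80, n_cpg=500)
    )
    blocks, pairs = synteny.find_blocks(study.genes, study.hits)
    assert blocks == [] and pairs == []
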
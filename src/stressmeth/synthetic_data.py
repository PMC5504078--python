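"""Synthetic study generator with planted, recoverable signal.

Emulates the study design the pipeline is built for: four groups (one
unstressed control ``CO`` and three stress regimes ``E``, ``PH``,
``EPH``) with six biological replicates each, profiled with reduced
representation bisulfite sequencing (per-CpG methylated/unmethylated
counts) and RNA-seq (per-gene counts).

Generative model
----------------
* Each CpG has a baseline methylation level pi ~ Beta(a, b) (default
  Beta(8, 2), global mean 80%).  Per sample, coverage is negative
  binomial (mean 30) and methylated reads are beta-binomial around the
  site's level with precision ``bb_precision`` (biological replicate
  overdispersion).
* Planted differentially methylated sites shift pi by a fixed number of
  percentage points in every stressed group; baselines at planted sites
  are drawn from the Beta prior truncated to leave headroom for the full
  shift, so the true effect equals the nominal one.
* Gene expression counts are negative binomial around
  s_j * mu_i * 2^(log2FC_i * 1{stressed}), with log-normal baselines,
  log-uniform sample size factors and a shared fold change across
  stressed groups (the study's concordant response).
* A configurable fraction of differentially expressed genes is *linked*:
  each receives planted DM CpGs in its gene body +/- flank with a signed
  pairing drawn from the quadrant mix (default 45/25/16/14 for
  hyper-down / hyper-up / hypo-up / hypo-down).
* Duplicated blocks copy runs of consecutive genes to another
  chromosome, preserving (or inverting) order; the hit table contains
  self-hits (best), paralog hits (second best, e <= 1e-20) and background
  hits above the 1e-10 cutoff so block recovery is exact by
  construction.  ``hard_mode_hits`` adds sub-cutoff noise hits.

Everything is driven by one integer seed; the same seed yields
byte-identical study directories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    CpGMatrix,
    GeneModel,
    HitRecord,
    SampleDesign,
    SiteCount,
    Transcript,
    write_counts,
    write_coverage_file,
    write_design,
    write_gtf,
    write_hits,
    write_tsv,
)

QUADRANTS = ["hyper_down", "hyper_up", "hypo_up", "hypo_down"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # genome layout
    n_chrom: int = 3
    chrom_length: int = 3_000_000
    n_genes: int = 300
    n_cpg: int = 6000
    frac_genic_cpg: float = 0.5
    min_gene_len: int = 2000
    max_gene_len: int = 8000
    # design
    groups: tuple = ("CO", "E", "PH", "EPH")
    control: str = "CO"
    replicates: int = 6
    # methylation model
    meth_beta_a: float = 8.0
    meth_beta_b: float = 2.0
    bb_precision: float = 1000.0
    cov_mean: float = 30.0
    cov_dispersion: float = 8.0  # NB size parameter
    dm_fraction: float = 0.05
    dm_shift: float = 0.40  # probability-scale shift (40 pp)
    dm_hyper_fraction: float = 0.537  # ~16% more hyper than hypo
    stranded_output: bool = True
    # expression model
    expr_log_mean: float = 5.3  # log of ~200 fragments
    expr_log_sd: float = 1.2
    expr_dispersion: float = 8.0  # NB size parameter
    de_fraction: float = 0.08
    de_log2fc: float = 2.0
    de_up_fraction: float = 0.5
    size_factor_low: float = 0.7
    size_factor_high: float = 1.4
    # methylation-expression linkage
    linked_fraction: float = 0.5
    n_linked: int = None  # overrides linked_fraction when set
    quadrant_mix: tuple = (0.45, 0.25, 0.16, 0.14)
    cpgs_per_linked_gene: int = 4
    linked_shift: float = 0.30
    flank: int = 10_000
    # duplications
    n_blocks: int = 2
    genes_per_block: int = 12
    block_orientation: str = "same"  # or "inverted"
    n_background_hits: int = 200
    hard_mode_hits: bool = False

    def validate(self):
        fracs = dict(
            frac_genic_cpg=self.frac_genic_cpg,
            dm_fraction=self.dm_fraction,
            dm_hyper_fraction=self.dm_hyper_fraction,
            de_fraction=self.de_fraction,
            de_up_fraction=self.de_up_fraction,
            linked_fraction=self.linked_fraction,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.quadrant_mix) - 1.0) > 1e-9:
            raise ValueError("quadrant_mix must sum to 1")
        if not 0 < self.dm_shift < 1 or not 0 < self.linked_shift < 1:
            raise ValueError("planted shifts must lie in (0, 1)")
        if self.control not in self.groups:
            raise ValueError("control group missing from groups")
        if self.block_orientation not in ("same", "inverted"):
            raise ValueError("block_orientation must be 'same' or 'inverted'")
        return self


@dataclass
class Truth:
    """Planted ground truth, the acceptance surface of the generator."""

    dm_sites: pd.DataFrame  # chrom, pos, shift_pp, kind
    de_genes: pd.DataFrame  # gene_id, log2fc
    linked_genes: pd.DataFrame  # gene_id, quadrant
    blocks: pd.DataFrame  # block_id, chrom_a, chrom_b, n_genes, orientation
    pairs: pd.DataFrame  # gene_a, gene_b, block_id


@dataclass
class Study:
    config: SimulationConfig
    design: SampleDesign
    genes: list
    chrom_lengths: dict
    methylation: CpGMatrix
    baseline: np.ndarray  # per-site baseline pi
    shift: np.ndarray  # per-site planted probability shift (signed)
    counts: pd.DataFrame
    hits: pd.DataFrame
    truth: Truth


def make_design(config: SimulationConfig) -> SampleDesign:
    rows = [
        {"sample_id": f"{g}{r + 1}", "group": g, "replicate": r + 1}
        for g in config.groups
        for r in range(config.replicates)
    ]
    return SampleDesign(pd.DataFrame(rows))


def _largest_remainder_counts(total: int, proportions) -> list:
    """Integer counts summing to ``total`` proportional to ``proportions``."""
    raw = [total * p for p in proportions]
    counts = [math.floor(r) for r in raw]
    rest = total - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in order[:rest]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping gene models plus CpG positions.

    Returns (genes, chrom_lengths, cpg positions DataFrame).  Genes are
    laid left to right with random intergenic gaps; CpGs are placed both
    inside gene bodies and in intergenic space, all distinct and >= 3 bp
    apart so strand merging stays unambiguous.
    """
    config.validate()
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    per_chrom = _largest_remainder_counts(
        config.n_genes, [1.0 / config.n_chrom] * config.n_chrom
    )
    genes = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = 1
        for _ in range(n_here):
            gap = int(rng.integers(2000, 12000))
            length = int(rng.integers(config.min_gene_len, config.max_gene_len + 1))
            start = cursor + gap
            end = start + length - 1
            if end > config.chrom_length - 2000:
                raise ValueError(
                    f"gene packing infeasible on {chrom}; increase chrom_length "
                    f"or lower n_genes"
                )
            gid += 1
            genes.append(_make_gene(f"g{gid:05d}", chrom, start, end, rng))
            cursor = end
    cpg = _place_cpgs(config, genes, chrom_lengths, rng)
    return genes, chrom_lengths, cpg


def _make_gene(gene_id, chrom, start, end, rng) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1:
        exons = [(start, end)]
    else:
        inner = rng.choice(
            np.arange(start + 100, end - 100), size=2 * (n_exons - 1), replace=False
        )
        cuts = sorted(int(c) for c in inner)
        bounds = [start] + cuts + [end]
        exons = [
            (bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)
        ]
    exons = [(s, e) for s, e in exons if e >= s]
    # UTRs: leading/trailing slices of the terminal exons, strand-aware
    utr_len = 150
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    left_utr = [(first_s, min(first_s + utr_len - 1, first_e))]
    right_utr = [(max(last_e - utr_len + 1, last_s), last_e)]
    utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
    transcripts = [Transcript(f"{gene_id}.t1", tuple(exons))]
    if len(exons) >= 3 and rng.random() < 0.3:
        drop = int(rng.integers(1, len(exons) - 1))
        sub = tuple(e for i, e in enumerate(exons) if i != drop)
        transcripts.append(Transcript(f"{gene_id}.t2", sub))
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        exons=list(exons),
        utr5=utr5,
        utr3=utr3,
        transcripts=transcripts,
    )


def _place_cpgs(config, genes, chrom_lengths, rng) -> pd.DataFrame:
    n_genic = round(config.n_cpg * config.frac_genic_cpg)
    n_inter = config.n_cpg - n_genic
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    taken = {c: set() for c in chrom_lengths}

    def admit(chrom, pos):
        if pos < 2 or pos > chrom_lengths[chrom] - 2:
            return False
        cells = taken[chrom]
        if any((pos + d) in cells for d in (-2, -1, 0, 1, 2)):
            return False
        cells.add(pos)
        return True

    records = []
    # genic: uniform within a uniformly chosen gene body
    count = 0
    while count < n_genic:
        g = genes[int(rng.integers(len(genes)))]
        pos = int(rng.integers(g.start, g.end + 1))
        if admit(g.chrom, pos):
            records.append((g.chrom, pos))
            count += 1
    # intergenic: rejection-sample positions outside every gene span
    chroms = sorted(chrom_lengths)
    spans = {
        c: np.array(sorted(by_chrom.get(c, [])), dtype=np.int64).reshape(-1, 2)
        for c in chroms
    }
    count = 0
    while count < n_inter:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(2, chrom_lengths[chrom] - 2))
        sp = spans[chrom]
        if len(sp):
            i = np.searchsorted(sp[:, 0], pos, side="right") - 1
            if i >= 0 and sp[i, 0] <= pos <= sp[i, 1]:
                continue
        if admit(chrom, pos):
            records.append((chrom, pos))
            count += 1
    cpg = pd.DataFrame(records, columns=["chrom", "pos"])
    return cpg.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def _truncated_beta(rng, a, b, lo, hi, size):
    """Beta(a, b) draws restricted to [lo, hi] via inverse-CDF sampling."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def simulate_methylation(
    config: SimulationConfig,
    cpg: pd.DataFrame,
    shift: np.ndarray,
    design: SampleDesign,
    rng: np.random.Generator,
):
    """Beta-binomial methylation counts for every sample.

    ``shift`` holds the signed probability-scale effect per site (0 for
    null sites), applied in every stressed group and clipped to (0, 1).
    Returns (CpGMatrix, baseline pi array).
    """
    n_sites = len(cpg)
    a, b = config.meth_beta_a, config.meth_beta_b
    baseline = rng.beta(a, b, size=n_sites)
    shift = np.asarray(shift, dtype=float)
    # planted sites: redraw baselines from the prior truncated to leave
    # headroom for the full shift (margin keeps Beta parameters finite)
    margin = 0.02
    hyper = shift > 0
    hypo = shift < 0
    if hyper.any():
        baseline[hyper] = _truncated_beta(
            rng, a, b, margin, 1.0 - shift[hyper] - margin, int(hyper.sum())
        )
    if hypo.any():
        baseline[hypo] = _truncated_beta(
            rng, a, b, -shift[hypo] + margin, 1.0 - margin, int(hypo.sum())
        )

    stressed = np.array(
        [g != config.control for g in design.table["group"]], dtype=float
    )
    p = baseline[:, None] + shift[:, None] * stressed[None, :]
    p = np.clip(p, 1e-4, 1.0 - 1e-4)

    k = config.cov_dispersion
    nb_p = k / (k + config.cov_mean)
    cov = rng.negative_binomial(k, nb_p, size=(n_sites, len(stressed)))
    theta = config.bb_precision
    p_draw = rng.beta(theta * p, theta * (1.0 - p))
    meth = rng.binomial(cov, p_draw)
    mat = CpGMatrix(
        chrom=cpg["chrom"].to_numpy(dtype=object),
        pos=cpg["pos"].to_numpy(dtype=np.int64),
        samples=design.samples,
        meth=meth,
        cov=cov,
    )
    return mat, baseline


def split_strands(mat: CpGMatrix, rng: np.random.Generator) -> dict:
    """Per-sample stranded SiteCount records (plus C at p, minus G at p+1).

    Coverage splits binomially between strands; methylated reads split
    hypergeometrically so the per-strand totals sum back exactly.
    """
    out = {}
    for j, sample in enumerate(mat.samples):
        cov = mat.cov[:, j]
        meth = mat.meth[:, j]
        cov_plus = rng.binomial(cov, 0.5)
        meth_plus = rng.hypergeometric(
            np.maximum(meth, 0), np.maximum(cov - meth, 0), cov_plus
        )
        recs = []
        for i in range(mat.n_sites):
            c_p, m_p = int(cov_plus[i]), int(meth_plus[i])
            c_m = int(cov[i] - c_p)
            m_m = int(meth[i] - m_p)
            chrom, pos = mat.chrom[i], int(mat.pos[i])
            if c_p + c_m == 0:
                continue
            # both strand lines are written whenever the CpG was observed,
            # so adjacency pairing at read-back is unambiguous
            recs.append(SiteCount(chrom, pos, m_p, c_p - m_p))
            recs.append(SiteCount(chrom, pos + 1, m_m, c_m - m_m))
        out[sample] = recs
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    gene_ids,
    log2fc: dict,
    design: SampleDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Negative-binomial counts around s_j * mu_i * 2^(FC_i * stressed)."""
    n = len(gene_ids)
    mu = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)
    fc = np.array([log2fc.get(g, 0.0) for g in gene_ids])
    s = np.exp(
        rng.uniform(
            np.log(config.size_factor_low),
            np.log(config.size_factor_high),
            size=len(design.samples),
        )
    )
    stressed = np.array(
        [g != config.control for g in design.table["group"]], dtype=float
    )
    mean = s[None, :] * mu[:, None] * 2.0 ** (fc[:, None] * stressed[None, :])
    k = config.expr_dispersion
    counts = rng.negative_binomial(k, k / (k + mean))
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                        columns=design.samples)


# ---------------------------------------------------------------------------
# duplications and hit table
# ---------------------------------------------------------------------------


def simulate_duplications(
    config: SimulationConfig,
    genes,
    chrom_lengths: dict,
    rng: np.random.Generator,
):
    """Plant duplicated blocks and build the all-vs-all hit table.

    Copies ``genes_per_block`` consecutive genes to a different
    chromosome (order preserved, or reversed for inverted blocks) and
    emits self, paralog and background hits at the representative
    transcript level.  Returns (genes incl. duplicates, chrom_lengths,
    hits DataFrame, blocks truth, pairs truth).
    """
    from .io_formats import hits_to_frame
    from .synteny import longest_transcript_db

    genes = list(genes)
    chrom_lengths = dict(chrom_lengths)
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)
    chroms = sorted(by_chrom)

    block_rows, pair_rows = [], []
    new_genes = []
    used = set()
    for b in range(config.n_blocks):
        src_chrom = chroms[b % len(chroms)]
        dst_chrom = chroms[(b + 1) % len(chroms)]
        source_genes = by_chrom[src_chrom]
        n_needed = config.genes_per_block
        if len(source_genes) < n_needed:
            raise ValueError(
                f"{src_chrom} has too few genes for a {n_needed}-gene block"
            )
        # pick a run of consecutive, not-yet-duplicated genes
        starts = [
            i
            for i in range(len(source_genes) - n_needed + 1)
            if all(
                source_genes[i + j].gene_id not in used for j in range(n_needed)
            )
        ]
        if not starts:
            raise ValueError("no free run of genes left to duplicate")
        i0 = int(rng.choice(starts))
        run = source_genes[i0 : i0 + n_needed]
        used.update(g.gene_id for g in run)

        placed = run if config.block_orientation == "same" else list(reversed(run))
        cursor = max(g.end for g in by_chrom[dst_chrom]) + 20_000
        for src in placed:
            length = src.end - src.start + 1
            start = cursor + int(rng.integers(3000, 8000))
            end = start + length - 1
            offset = start - src.start
            dup_id = f"{src.gene_id}_dup"
            dup = GeneModel(
                gene_id=dup_id,
                chrom=dst_chrom,
                strand=src.strand,
                start=start,
                end=end,
                exons=[(s + offset, e + offset) for s, e in src.exons],
                utr5=[(s + offset, e + offset) for s, e in src.utr5],
                utr3=[(s + offset, e + offset) for s, e in src.utr3],
                transcripts=[
                    Transcript(
                        f"{dup_id}.t1",
                        tuple(
                            (s + offset, e + offset)
                            for s, e in src.transcripts[0].exons
                        ),
                    )
                ],
            )
            new_genes.append(dup)
            by_chrom[dst_chrom].append(dup)
            pair_rows.append(
                {"gene_a": src.gene_id, "gene_b": dup_id, "block_id": b}
            )
            cursor = end
        chrom_lengths[dst_chrom] = max(chrom_lengths[dst_chrom], cursor + 20_000)
        block_rows.append(
            {
                "block_id": b,
                "chrom_a": src_chrom,
                "chrom_b": dst_chrom,
                "n_genes": n_needed,
                "orientation": config.block_orientation,
            }
        )

    all_genes = sorted(genes + new_genes, key=lambda g: (g.chrom, g.start))
    rep = longest_transcript_db(all_genes)
    hit_records = []

    def hit(q, s, e_value, bit, pident=99.0, length=500):
        hit_records.append(
            HitRecord(q, s, pident, length, 5, 0, 1, length, 1, length,
                      float(e_value), float(bit))
        )

    for g in all_genes:
        hit(rep[g.gene_id], rep[g.gene_id], 0.0, 5000.0, pident=100.0)
    for row in pair_rows:
        e_ab = 10.0 ** (-rng.uniform(25, 60))
        e_ba = 10.0 ** (-rng.uniform(25, 60))
        hit(rep[row["gene_a"]], rep[row["gene_b"]], e_ab, 2000.0)
        hit(rep[row["gene_b"]], rep[row["gene_a"]], e_ba, 2000.0)
    gene_ids = [g.gene_id for g in all_genes]
    for _ in range(config.n_background_hits):
        qa, qb = rng.choice(len(gene_ids), size=2, replace=False)
        e = 10.0 ** (-rng.uniform(0, 5))  # >= 1e-5, above the 1e-10 cutoff
        hit(rep[gene_ids[qa]], rep[gene_ids[qb]], e, 60.0, pident=80.0)
    if config.hard_mode_hits:
        for _ in range(config.n_background_hits // 4):
            qa, qb = rng.choice(len(gene_ids), size=2, replace=False)
            e = 10.0 ** (-rng.uniform(11, 20))
            hit(rep[gene_ids[qa]], rep[gene_ids[qb]], e, 300.0, pident=85.0)

    hits = hits_to_frame(hit_records)
    blocks = pd.DataFrame(
        block_rows,
        columns=["block_id", "chrom_a", "chrom_b", "n_genes", "orientation"],
    )
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "block_id"])
    return all_genes, chrom_lengths, hits, blocks, pairs


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig, outdir=None) -> Study:
    """Generate a complete study; optionally write it as a directory.

    The directory layout is exactly what the pipeline reads back:
    ``design.tsv``, ``coverage/<sample>.cov``, ``counts.tsv``,
    ``annotation.gtf``, ``hits.tsv`` and ``truth/*.tsv``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(config)

    genes, chrom_lengths, cpg = simulate_genome(config, rng)
    genes, chrom_lengths, hits, blocks_truth, pairs_truth = simulate_duplications(
        config, genes, chrom_lengths, rng
    )
    original_ids = [g.gene_id for g in genes if not g.gene_id.endswith("_dup")]
    dup_partner = dict(zip(pairs_truth["gene_a"], pairs_truth["gene_b"]))

    # --- differential expression truth -------------------------------------
    n_de = round(len(original_ids) * config.de_fraction)
    de_ids = [
        original_ids[i]
        for i in sorted(rng.choice(len(original_ids), size=n_de, replace=False))
    ]
    n_linked = (
        config.n_linked
        if config.n_linked is not None
        else round(n_de * config.linked_fraction)
    )
    if n_linked > n_de:
        raise ValueError("n_linked exceeds the number of DE genes")
    linked_ids = [
        de_ids[i]
        for i in sorted(rng.choice(n_de, size=n_linked, replace=False))
    ]
    quad_counts = _largest_remainder_counts(n_linked, config.quadrant_mix)
    quad_labels = np.repeat(QUADRANTS, quad_counts)
    rng.shuffle(quad_labels)
    quadrant_of = dict(zip(linked_ids, quad_labels))

    log2fc = {}
    for g in de_ids:
        quad = quadrant_of.get(g)
        if quad is not None:
            up = quad in ("hyper_up", "hypo_up")
        else:
            up = rng.random() < config.de_up_fraction
        log2fc[g] = config.de_log2fc if up else -config.de_log2fc
    for src, dup in dup_partner.items():
        if src in log2fc:  # duplicates co-respond with their source copy
            log2fc[dup] = log2fc[src]

    # --- methylation truth --------------------------------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    taken = set(zip(cpg["chrom"], cpg["pos"]))
    linked_rows = []
    for gid in linked_ids:
        g = gene_by_id[gid]
        sign = 1.0 if quadrant_of[gid].startswith("hyper") else -1.0
        placed = 0
        while placed < config.cpgs_per_linked_gene:
            lo = max(2, g.start - config.flank)
            hi = min(chrom_lengths[g.chrom] - 2, g.end + config.flank)
            pos = int(rng.integers(lo, hi + 1))
            if any((g.chrom, pos + d) in taken for d in (-2, -1, 0, 1, 2)):
                continue
            taken.add((g.chrom, pos))
            linked_rows.append(
                {
                    "chrom": g.chrom,
                    "pos": pos,
                    "shift_pp": 100.0 * sign * config.linked_shift,
                    "kind": "linked",
                    "gene_id": gid,
                }
            )
            placed += 1

    n_dm_bg = round(config.n_cpg * config.dm_fraction)
    bg_idx = sorted(rng.choice(config.n_cpg, size=n_dm_bg, replace=False))
    n_hyper = round(n_dm_bg * config.dm_hyper_fraction)
    signs = np.array([1.0] * n_hyper + [-1.0] * (n_dm_bg - n_hyper))
    rng.shuffle(signs)
    bg_rows = [
        {
            "chrom": cpg.iloc[i]["chrom"],
            "pos": int(cpg.iloc[i]["pos"]),
            "shift_pp": 100.0 * s * config.dm_shift,
            "kind": "background",
            "gene_id": "",
        }
        for i, s in zip(bg_idx, signs)
    ]
    dm_truth = pd.DataFrame(
        bg_rows + linked_rows,
        columns=["chrom", "pos", "shift_pp", "kind", "gene_id"],
    )

    all_cpg = (
        pd.concat(
            [cpg, dm_truth.loc[dm_truth["kind"] == "linked", ["chrom", "pos"]]],
            ignore_index=True,
        )
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    shift = np.zeros(len(all_cpg))
    site_index = {
        (c, p): i for i, (c, p) in enumerate(zip(all_cpg["chrom"], all_cpg["pos"]))
    }
    for row in dm_truth.itertuples(index=False):
        shift[site_index[(row.chrom, row.pos)]] = row.shift_pp / 100.0

    methylation, baseline = simulate_methylation(
        config, all_cpg, shift, design, rng
    )
    counts = simulate_expression(
        config, [g.gene_id for g in genes], log2fc, design, rng
    )

    truth = Truth(
        dm_sites=dm_truth.sort_values(["chrom", "pos"]).reset_index(drop=True),
        de_genes=pd.DataFrame(
            sorted(log2fc.items()), columns=["gene_id", "log2fc"]
        ),
        linked_genes=pd.DataFrame(
            sorted(quadrant_of.items()), columns=["gene_id", "quadrant"]
        ),
        blocks=blocks_truth,
        pairs=pairs_truth,
    )
    study = Study(
        config=config,
        design=design,
        genes=genes,
        chrom_lengths=chrom_lengths,
        methylation=methylation,
        baseline=baseline,
        shift=shift,
        counts=counts,
        hits=hits,
        truth=truth,
    )
    if outdir is not None:
        write_study(study, outdir, rng)
    return study


def write_study(study: Study, outdir, rng: np.random.Generator):
    """Write the study as a self-contained directory of text files."""
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    header = f"stressmeth simulate seed={study.config.seed}"

    write_design(study.design, outdir / "design.tsv", header=header)
    write_gtf(study.genes, outdir / "annotation.gtf", header=header)
    write_counts(study.counts, outdir / "counts.tsv", header=header)
    write_hits(
        [HitRecord(**row) for row in study.hits.to_dict("records")],
        outdir / "hits.tsv",
    )
    if study.config.stranded_output:
        per_sample = split_strands(study.methylation, rng)
    else:
        per_sample = {
            sample: [
                SiteCount(
                    study.methylation.chrom[i],
                    int(study.methylation.pos[i]),
                    int(study.methylation.meth[i, j]),
                    int(study.methylation.cov[i, j] - study.methylation.meth[i, j]),
                )
                for i in range(study.methylation.n_sites)
                if study.methylation.cov[i, j] > 0
            ]
            for j, sample in enumerate(study.methylation.samples)
        }
    for sample, recs in per_sample.items():
        write_coverage_file(recs, outdir / "coverage" / f"{sample}.cov",
                            header=header)

    write_tsv(study.truth.dm_sites, outdir / "truth" / "dm_sites.tsv")
    write_tsv(study.truth.de_genes, outdir / "truth" / "de_genes.tsv")
    write_tsv(study.truth.linked_genes, outdir / "truth" / "linked_genes.tsv")
    write_tsv(study.truth.blocks, outdir / "truth" / "blocks.tsv")
    write_tsv(study.truth.pairs, outdir / "truth" / "pairs.tsv")
    chrom_df = pd.DataFrame(
        sorted(study.chrom_lengths.items()), columns=["chrom", "length"]
    )
    write_tsv(chrom_df, outdir / "chrom_lengths.tsv")
    cfg = pd.DataFrame(
        [(k, v) for k, v in asdict(study.config).items()],
        columns=["key", "value"],
    )
    write_tsv(cfg, outdir / "sim_config.tsv")
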
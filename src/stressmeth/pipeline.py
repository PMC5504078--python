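"""End-to-end orchestration: simulate -> test -> annotate -> integrate
-> windows -> synteny -> report, all stage outputs as headered TSV/JSON.

A single :class:`PipelineConfig` carries every path and threshold; the
same config and inputs reproduce byte-identical outputs (no timestamps,
sorted tables, seeded randomness).  Stages communicate only through
their declared output files; the final report is assembled purely from
those files and validated against a pydantic schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import __version__
from . import diffexpr, diffmeth, feature_annotation, integration, synteny, window_scan
from .io_formats import (
    ValidationError,
    hits_to_frame,
    load_coverage_dir,
    read_counts,
    read_design,
    read_gtf,
    read_hits,
    read_tsv,
    write_bed,
    write_tsv,
)
from .synthetic_data import SimulationConfig, simulate_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    study_dir: Optional[str] = None  # directory in the simulator's layout
    coverage_dir: Optional[str] = None
    counts: Optional[str] = None
    gtf: Optional[str] = None
    hits: Optional[str] = None
    design: Optional[str] = None
    outdir: str = "stressmeth_run"
    simulate: bool = False  # generate study_dir before running
    control: str = "CO"
    destrand: bool = True
    delta: float = diffmeth.DEFAULT_DELTA
    q: float = diffmeth.DEFAULT_Q
    fc: float = diffexpr.DEFAULT_FC
    alpha: float = diffexpr.DEFAULT_ALPHA
    min_cov: int = diffmeth.DEFAULT_MIN_COV
    max_cov_percentile: float = diffmeth.DEFAULT_MAX_COV_PERCENTILE
    avg_cov: float = integration.DEFAULT_MIN_AVG_COV
    min_change: float = integration.DEFAULT_MIN_ABS_CHANGE
    flank: int = integration.DEFAULT_FLANK
    window: int = window_scan.DEFAULT_WINDOW
    step: Optional[int] = None
    evalue: float = synteny.DEFAULT_E_CUTOFF
    min_genes: int = synteny.DEFAULT_MIN_GENES
    max_gap: int = synteny.DEFAULT_MAX_GAP
    promoter_up: int = feature_annotation.DEFAULT_PROMOTER_UP
    promoter_down: int = feature_annotation.DEFAULT_PROMOTER_DOWN
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def resolve_paths(self):
        """Fill per-file paths from the study directory layout."""
        if self.study_dir is not None:
            d = Path(self.study_dir)
            self.coverage_dir = self.coverage_dir or str(d / "coverage")
            self.counts = self.counts or str(d / "counts.tsv")
            self.gtf = self.gtf or str(d / "annotation.gtf")
            self.hits = self.hits or str(d / "hits.tsv")
            self.design = self.design or str(d / "design.tsv")
        return self

    def validate(self):
        self.resolve_paths()
        positive = dict(
            delta=self.delta, q=self.q, fc=self.fc, alpha=self.alpha,
            min_cov=self.min_cov, avg_cov=self.avg_cov,
            min_change=self.min_change, flank=self.flank,
            window=self.window, evalue=self.evalue,
            min_genes=self.min_genes,
        )
        for name, v in positive.items():
            if v is None or v <= 0:
                raise ValidationError(f"threshold {name} must be positive, got {v}")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")
        if not self.simulate:
            for name in ("coverage_dir", "counts", "gtf", "hits", "design"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValidationError(f"input {name} missing or unreadable: {path}")
        return self

    #: fields that locate files rather than parameterize the analysis
    _PATH_FIELDS = ("study_dir", "coverage_dir", "counts", "gtf", "hits",
                    "design", "outdir")

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (thresholds + seed), not paths."""
        params = {
            k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS
        }
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides):
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------


class ComparisonSummary(BaseModel):
    group: str
    n_sites_tested: int
    n_hyper: int
    n_hypo: int
    hyper_excess_pct: Optional[float] = None
    global_methylation_pct: Optional[float] = None
    n_de_up: int
    n_de_down: int


class RunReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    pipeline_version: str
    config_hash: str
    seed: int
    comparisons: list[ComparisonSummary]
    n_consistent_de_genes: int
    feature_percentages: dict[str, float]
    quadrant_percentages: dict[str, float]
    welch_up_vs_down: Optional[dict[str, float]] = None
    n_candidate_windows: int
    n_synteny_blocks: int
    n_reciprocal_pairs: int
    paralog_direction_concordance: Optional[float] = None
    recovery: Optional[dict] = None


REPORT_SCHEMA = RunReport.model_json_schema()


def _clean(x):
    """NaN -> None so the report JSON stays strictly valid."""
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _clean_tree(obj):
    """Recursively replace non-finite floats with None in nested dicts."""
    if isinstance(obj, dict):
        return {k: _clean_tree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_tree(v) for v in obj]
    return _clean(obj)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig) -> RunReport:
    """Run every stage in order and write all result tables + report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"stressmeth v{__version__} config={config.config_hash}"

    if config.simulate:
        if config.study_dir is None:
            raise ValidationError("simulate=True requires study_dir")
        sim = SimulationConfig(seed=config.seed, **config.sim_overrides)
        log.info("stage simulate -> %s", config.study_dir)
        simulate_study(sim, outdir=config.study_dir)
        config.resolve_paths()
        config.validate()

    design = read_design(config.design)
    stressed_groups = [g for g in design.groups if g != config.control]
    mat = load_coverage_dir(config.coverage_dir, design, destrand=config.destrand)
    genes = read_gtf(config.gtf)
    counts = read_counts(config.counts)
    hits = hits_to_frame(read_hits(config.hits))

    # --- differential methylation (pairwise vs control) --------------------
    dm_by_group = {}
    dm_summaries = {}
    for group in stressed_groups:
        log.info("stage dm-test %s vs %s", group, config.control)
        filtered = diffmeth.filter_sites(
            mat, design, group, config.control,
            min_cov=config.min_cov, max_cov_percentile=config.max_cov_percentile,
        )
        dm = diffmeth.call_dm(
            diffmeth.dm_test(filtered, design, group, config.control),
            delta=config.delta, q_threshold=config.q,
        )
        dm_by_group[group] = dm
        dm_summaries[group] = diffmeth.summarize_dm(dm, filtered)
        write_tsv(dm, outdir / f"dm_{group}.tsv", header=tag)
        sig = dm[dm["status"] != "ns"]
        write_bed(
            list(zip(sig["chrom"], sig["pos"], sig["status"])),
            outdir / f"dm_{group}.bed", header=tag,
        )

    # --- differential expression -------------------------------------------
    size_factors, normalized = diffexpr.median_of_ratios_norm(counts)
    write_tsv(
        size_factors.rename_axis("sample_id").reset_index(),
        outdir / "size_factors.tsv", header=tag,
    )
    de_by_group = {}
    for group in stressed_groups:
        log.info("stage de-test %s vs %s", group, config.control)
        de = diffexpr.de_test(
            normalized, design, group, config.control,
            fc=config.fc, alpha=config.alpha,
        )
        de_by_group[group] = de
        write_tsv(
            de.rename_axis("gene_id").reset_index(),
            outdir / f"de_{group}.tsv", header=tag,
        )
    consistent = diffexpr.consistent_de(de_by_group, fc=config.fc)
    write_tsv(
        consistent.rename_axis("gene_id").reset_index(),
        outdir / "consistent_de.tsv", header=tag,
    )

    # --- feature annotation of DM sites ------------------------------------
    log.info("stage annotate")
    dm_union = (
        pd.concat(
            [dm[dm["status"] != "ns"][["chrom", "pos"]] for dm in dm_by_group.values()],
            ignore_index=True,
        )
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    index = feature_annotation.build_feature_index(
        genes, promoter_up=config.promoter_up, promoter_down=config.promoter_down
    )
    assignments, feature_pct = feature_annotation.annotate_sites(dm_union, index)
    write_tsv(assignments, outdir / "feature_assignments.tsv", header=tag)
    (outdir / "feature_summary.json").write_text(
        json.dumps(feature_pct, indent=2, sort_keys=True) + "\n"
    )

    # --- methylation-expression integration --------------------------------
    log.info("stage integrate")
    direction = dict(zip(consistent.index, consistent["direction"]))
    profiles = []
    for group in stressed_groups:
        sites = integration.integration_change_table(
            mat, design, group, config.control,
            min_avg_cov=config.avg_cov, min_abs_change=config.min_change,
        )
        profiles.append(
            integration.profile_genes(
                genes, sites, direction, comparison=f"{group}_vs_{config.control}",
                flank=config.flank,
            )
        )
    profiles = (
        pd.concat(profiles, ignore_index=True)
        if profiles
        else integration.profile_genes([], pd.DataFrame(), {}, "none")
    )
    write_tsv(profiles, outdir / "integration_profiles.tsv", header=tag)
    quad_pct = integration.classify_quadrants(profiles)
    welch = None
    informative = profiles[profiles["quadrant"] != "flat"]
    up_changes = informative.loc[
        informative["expr_direction"] == "up", "mean_meth_change"
    ]
    down_changes = informative.loc[
        informative["expr_direction"] == "down", "mean_meth_change"
    ]
    if len(up_changes) >= 2 and len(down_changes) >= 2:
        t, df_, p = integration.welch_t(up_changes, down_changes)
        welch = {"t": t, "df": df_, "p": p}
    (outdir / "quadrant_summary.json").write_text(
        json.dumps(
            {"quadrant_percentages": quad_pct, "welch_up_vs_down": welch},
            indent=2, sort_keys=True,
        )
        + "\n"
    )

    # --- window scan --------------------------------------------------------
    log.info("stage windows")
    candidates_all = []
    for group in stressed_groups:
        windows = window_scan.scan_windows(
            dm_by_group[group], de_by_group[group], genes,
            window_size=config.window, step=config.step,
        )
        write_tsv(
            window_scan.windows_to_frame(windows),
            outdir / f"windows_{group}.tsv", header=tag,
        )
        ranked = window_scan.rank_candidate_regulatory_windows(
            windows, dm_by_group[group], genes
        )
        for r in ranked:
            r["comparison"] = f"{group}_vs_{config.control}"
        candidates_all.extend(ranked)
        (outdir / f"windows_{group}.txt").write_text(
            window_scan.window_text_report(windows, f"{group} vs {config.control}")
        )
    cand_frame = pd.DataFrame(
        [
            {**{k: v for k, v in r.items() if k != "dm_to_nearest_de_gene_bp"},
             "dm_to_nearest_de_gene_bp": ",".join(
                 str(d) for d in r["dm_to_nearest_de_gene_bp"])}
            for r in candidates_all
        ],
        columns=["comparison", "chrom", "start", "end", "score", "n_hyper",
                 "n_hypo", "n_de", "sum_abs_log2fc", "dm_to_nearest_de_gene_bp"],
    )
    write_tsv(cand_frame, outdir / "candidate_windows.tsv", header=tag)

    # --- synteny ------------------------------------------------------------
    log.info("stage synteny")
    blocks, pairs = synteny.find_blocks(
        genes, hits, e_cutoff=config.evalue,
        min_genes=config.min_genes, max_gap=config.max_gap,
    )
    write_tsv(synteny.blocks_to_frame(blocks), outdir / "synteny_blocks.tsv",
              header=tag)
    write_tsv(synteny.pairs_to_frame(pairs), outdir / "synteny_pairs.tsv",
              header=tag)

    # paralog direction concordance over all stressed comparisons
    pair_list = [(p.gene_a, p.gene_b) for p in pairs]
    concordances = [
        integration.paralog_direction_concordance(de_by_group[g], pair_list)
        for g in stressed_groups
    ]
    finite = [c for c in concordances if np.isfinite(c)]
    concordance = float(np.mean(finite)) if finite else None

    summary = {
        "dm": dm_summaries,
        "de": {
            g: {
                "n_up": int((de_by_group[g]["status"] == "up").sum()),
                "n_down": int((de_by_group[g]["status"] == "down").sum()),
            }
            for g in stressed_groups
        },
        "paralog_direction_concordance": concordance,
        "n_candidate_windows": len(candidates_all),
    }
    (outdir / "stage_summary.json").write_text(
        json.dumps(_clean_tree(summary), indent=2, sort_keys=True) + "\n"
    )
    meta = {
        "pipeline_version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "control": config.control,
        "groups": stressed_groups,
    }
    (outdir / "run_meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    config.to_yaml(outdir / "config.yaml")

    truth_dir = None
    if config.study_dir is not None and (Path(config.study_dir) / "truth").is_dir():
        truth_dir = Path(config.study_dir) / "truth"
    return report(outdir, truth_dir=truth_dir)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def _dm_recovery(outdir: Path, truth_dir: Path, groups) -> dict:
    truth = read_tsv(truth_dir / "dm_sites.tsv")
    truth_sign = {
        (r.chrom, r.pos): np.sign(r.shift_pp) for r in truth.itertuples(index=False)
    }
    sens, prec, sign_acc = [], [], []
    for g in groups:
        dm = read_tsv(outdir / f"dm_{g}.tsv")
        called = dm[dm["status"] != "ns"]
        call_sign = {
            (r.chrom, r.pos): 1.0 if r.status == "hyper" else -1.0
            for r in called.itertuples(index=False)
        }
        hits = [k for k in call_sign if k in truth_sign]
        sens.append(len(hits) / len(truth_sign) if truth_sign else np.nan)
        prec.append(len(hits) / len(call_sign) if call_sign else np.nan)
        correct = sum(call_sign[k] == truth_sign[k] for k in hits)
        sign_acc.append(correct / len(hits) if hits else np.nan)
    return {
        "dm_sensitivity": float(np.nanmean(sens)),
        "dm_precision": float(np.nanmean(prec)),
        "dm_sign_accuracy": float(np.nanmean(sign_acc)),
    }


def _de_recovery(outdir: Path, truth_dir: Path, groups) -> dict:
    truth = read_tsv(truth_dir / "de_genes.tsv")
    truth_dir_map = dict(
        zip(truth["gene_id"], np.where(truth["log2fc"] > 0, "up", "down"))
    )
    sens, prec = [], []
    for g in groups:
        de = read_tsv(outdir / f"de_{g}.tsv")
        called = de[de["status"] != "ns"]
        hits = sum(
            truth_dir_map.get(r.gene_id) == r.status
            for r in called.itertuples(index=False)
        )
        sens.append(hits / len(truth_dir_map) if len(truth_dir_map) else np.nan)
        prec.append(hits / len(called) if len(called) else np.nan)
    return {
        "de_sensitivity": float(np.nanmean(sens)),
        "de_precision": float(np.nanmean(prec)),
    }


def _block_recovery(outdir: Path, truth_dir: Path) -> dict:
    truth_blocks = read_tsv(truth_dir / "blocks.tsv")
    truth_pairs = read_tsv(truth_dir / "pairs.tsv")
    found_pairs = read_tsv(outdir / "synteny_pairs.tsv")
    found = {
        tuple(sorted(p)) for p in zip(found_pairs["gene_a"], found_pairs["gene_b"])
    } if len(found_pairs) else set()
    planted = {
        tuple(sorted(p)) for p in zip(truth_pairs["gene_a"], truth_pairs["gene_b"])
    }
    blocks = read_tsv(outdir / "synteny_blocks.tsv")
    return {
        "n_blocks_planted": int(len(truth_blocks)),
        "n_blocks_found": int(len(blocks)),
        "pair_recovery": (
            len(found & planted) / len(planted) if planted else float("nan")
        ),
    }


def report(outdir, truth_dir=None) -> RunReport:
    """Assemble the run report from stage output files and validate it.

    Writes ``report.json`` (schema-validated) and a human-readable
    ``report.txt``.  When a truth directory is available, recovery
    metrics against the planted signal are included.
    """
    outdir = Path(outdir)
    meta = json.loads((outdir / "run_meta.json").read_text())
    stage = json.loads((outdir / "stage_summary.json").read_text())
    feature_pct = json.loads((outdir / "feature_summary.json").read_text())
    quad = json.loads((outdir / "quadrant_summary.json").read_text())
    consistent = read_tsv(outdir / "consistent_de.tsv")
    blocks = read_tsv(outdir / "synteny_blocks.tsv")
    pairs = read_tsv(outdir / "synteny_pairs.tsv")
    groups = meta["groups"]

    comparisons = []
    for g in groups:
        dm = stage["dm"][g]
        de = stage["de"][g]
        comparisons.append(
            ComparisonSummary(
                group=g,
                n_sites_tested=dm["n_sites_tested"],
                n_hyper=dm["n_hyper"],
                n_hypo=dm["n_hypo"],
                hyper_excess_pct=_clean(dm.get("hyper_excess_pct")),
                global_methylation_pct=_clean(dm.get("global_methylation_pct")),
                n_de_up=de["n_up"],
                n_de_down=de["n_down"],
            )
        )

    recovery = None
    if truth_dir is not None:
        truth_dir = Path(truth_dir)
        recovery = {}
        recovery.update(_dm_recovery(outdir, truth_dir, groups))
        recovery.update(_de_recovery(outdir, truth_dir, groups))
        recovery.update(_block_recovery(outdir, truth_dir))
        linked = read_tsv(truth_dir / "linked_genes.tsv")
        if len(linked):
            planted_pct = {
                q: float(100.0 * (linked["quadrant"] == q).sum() / len(linked))
                for q in integration.QUADRANTS
            }
            recovery["planted_quadrant_percentages"] = planted_pct
        recovery = _clean_tree(recovery)

    rep = RunReport(
        pipeline_version=meta["pipeline_version"],
        config_hash=meta["config_hash"],
        seed=meta["seed"],
        comparisons=comparisons,
        n_consistent_de_genes=int(len(consistent)),
        feature_percentages=feature_pct,
        quadrant_percentages=quad["quadrant_percentages"],
        welch_up_vs_down=quad.get("welch_up_vs_down"),
        n_candidate_windows=stage["n_candidate_windows"],
        n_synteny_blocks=int(len(blocks)),
        n_reciprocal_pairs=int(len(pairs)),
        paralog_direction_concordance=_clean(
            stage.get("paralog_direction_concordance")
        ),
        recovery=recovery,
    )
    (outdir / "report.json").write_text(
        json.dumps(rep.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.txt").write_text(_format_report(rep))
    return rep


def _format_report(rep: RunReport) -> str:
    lines = [
        f"stressmeth v{rep.pipeline_version} run report "
        f"(config {rep.config_hash}, seed {rep.seed})",
        "",
        "Differential methylation / expression per comparison vs control:",
    ]
    for c in rep.comparisons:
        excess = (
            f"{c.hyper_excess_pct:+.1f}%" if c.hyper_excess_pct is not None else "n/a"
        )
        glob = (
            f"{c.global_methylation_pct:.1f}%"
            if c.global_methylation_pct is not None
            else "n/a"
        )
        lines.append(
            f"  {c.group}: {c.n_hyper} hyper / {c.n_hypo} hypo DM sites "
            f"(excess {excess}; global methylation {glob}); "
            f"{c.n_de_up} up / {c.n_de_down} down DE genes"
        )
    lines.append("")
    lines.append(
        "Feature split of DM sites (%): "
        + ", ".join(f"{k}={v:.1f}" for k, v in sorted(rep.feature_percentages.items()))
    )
    if rep.quadrant_percentages:
        lines.append(
            "Quadrant split of consistent DE genes (%): "
            + ", ".join(
                f"{k}={rep.quadrant_percentages[k]:.1f}"
                for k in integration.QUADRANTS
                if k in rep.quadrant_percentages
            )
        )
    if rep.welch_up_vs_down:
        w = rep.welch_up_vs_down
        lines.append(
            f"Welch t (mean methylation change, up- vs down-regulated genes): "
            f"t={w['t']:.2f}, df={w['df']:.1f}, p={w['p']:.3g}"
        )
    lines.append(
        f"Consistent DE genes: {rep.n_consistent_de_genes}; "
        f"candidate regulatory windows: {rep.n_candidate_windows}; "
        f"duplicated blocks: {rep.n_synteny_blocks} "
        f"({rep.n_reciprocal_pairs} reciprocal pairs)"
    )
    if rep.paralog_direction_concordance is not None:
        lines.append(
            f"Paralog expression direction concordance: "
            f"{rep.paralog_direction_concordance:.2f}"
        )
    if rep.recovery:
        lines.append("")
        lines.append("Recovery vs planted truth:")
        for k, v in sorted(rep.recovery.items()):
            lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
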
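"""Readers and writers for every external format the pipeline touches.

Conventions, fixed across the package:

* internal coordinates are 1-based inclusive (GTF convention);
* BED exports are 0-based half-open, converted only at the boundary;
* the percent-methylation column of coverage files is never trusted —
  methylation levels are always recomputed from read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: columns of the 12-column tabular hit format (BLAST outfmt 6)
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteCount:
    """Methylated/unmethylated read counts at one CpG for one sample."""

    chrom: str
    pos: int  # 1-based position of the C on the plus strand
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class CpGSiteCounts:
    """One CpG position with per-sample (methylated, unmethylated) counts."""

    chrom: str
    pos: int
    counts: tuple  # per-sample (n_meth, n_unmeth) pairs, fixed sample order

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for m, u in self.counts:
            if m < 0 or u < 0:
                raise ValidationError(
                    f"negative count at {self.chrom}:{self.pos}"
                )


@dataclass
class CpGMatrix:
    """Vectorized container: CpG sites x samples count matrices.

    Rows are sorted by (chrom, pos); ``cov - meth`` gives unmethylated
    counts.  This is the in-memory workhorse behind the record-level API.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int64
    samples: list
    meth: np.ndarray  # (n_sites, n_samples) int64
    cov: np.ndarray  # (n_sites, n_samples) int64

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.cov = np.asarray(self.cov, dtype=np.int64)
        if self.meth.shape != self.cov.shape:
            raise ValidationError("meth/cov shape mismatch")
        if self.meth.shape != (len(self.pos), len(self.samples)):
            raise ValidationError("matrix shape inconsistent with sites/samples")
        if (self.meth > self.cov).any():
            raise ValidationError("methylated counts exceed coverage")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, mask) -> "CpGMatrix":
        return CpGMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            samples=list(self.samples),
            meth=self.meth[mask],
            cov=self.cov[mask],
        )

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple  # ((start, end), ...) 1-based inclusive, sorted

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GeneModel:
    """Gene coordinates with exon/UTR structure and derived intervals."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)  # merged, sorted
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    transcripts: list = field(default_factory=list)

    def __post_init__(self):
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"exon ({s},{e}) outside span of gene {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        """Transcription start site, strand-aware."""
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> list:
        """Gene span minus merged exons; derived, never stored."""
        return subtract_intervals([(self.start, self.end)], self.exons)


@dataclass(frozen=True)
class HitRecord:
    """One row of the 12-column tabular hit format."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float


@dataclass
class SampleDesign:
    """Sample-to-group assignment for the 4-group x 6-replicate design."""

    table: pd.DataFrame  # columns: sample_id, group, replicate

    def __post_init__(self):
        required = {"sample_id", "group", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"design table needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in design")

    @property
    def samples(self) -> list:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    def samples_in(self, group: str) -> list:
        sub = self.table.loc[self.table["group"] == group, "sample_id"]
        if sub.empty:
            raise ValidationError(f"group {group!r} has no samples")
        return list(sub)


# ---------------------------------------------------------------------------
# interval helpers (1-based inclusive throughout)
# ---------------------------------------------------------------------------


def merge_intervals(intervals):
    """Merge overlapping or bookended 1-based inclusive intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged = []
    for s, e in ivs:
        if e < s:
            raise ValidationError(f"degenerate interval ({s},{e})")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(base, holes):
    """Subtract merged ``holes`` from merged ``base`` (1-based inclusive)."""
    result = []
    holes = merge_intervals(holes)
    for bs, be in merge_intervals(base):
        cur = bs
        for hs, he in holes:
            if he < cur or hs > be:
                continue
            if hs > cur:
                result.append((cur, hs - 1))
            cur = max(cur, he + 1)
            if cur > be:
                break
        if cur <= be:
            result.append((cur, be))
    return result


# ---------------------------------------------------------------------------
# coverage files (6-column bisulfite-caller dialect)
# ---------------------------------------------------------------------------


def read_coverage_file(path, sample_id=None):
    """Read one sample's CpG coverage file.

    The expected dialect is the 6-column bisulfite-caller coverage format:
    chrom, start, end, percent methylation, count methylated,
    count unmethylated (tab-separated, 1-based positions).  The percent
    column is ignored; levels are recomputed from counts downstream.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                pos = int(parts[1])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if pos < 1:
                raise ValidationError(f"{path}:{lineno}: position {pos} < 1")
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            records.append(SiteCount(chrom, pos, n_meth, n_unmeth))
    if not records:
        log.warning("coverage file %s is empty", path)
    return records


def write_coverage_file(records, path, header=None):
    """Write SiteCount records in the 6-column coverage dialect."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for r in records:
            cov = r.coverage
            pct = 100.0 * r.n_meth / cov if cov else 0.0
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:.6g}\t{r.n_meth}\t{r.n_unmeth}\n"
            )


def destrand_cpg(plus_record, minus_record=None):
    """Merge the two strands of one CpG into a single record.

    The minus-strand record sits at ``pos + 1`` (the G of the CpG on the
    plus strand); merged counts are attributed to the plus-strand C.
    """
    if minus_record is None:
        return plus_record
    if plus_record.chrom != minus_record.chrom:
        raise ValidationError(
            f"cannot destrand records on different chromosomes "
            f"({plus_record.chrom} vs {minus_record.chrom})"
        )
    if minus_record.pos != plus_record.pos + 1:
        raise ValidationError(
            f"minus-strand record must sit at pos+1 "
            f"({plus_record.pos} vs {minus_record.pos})"
        )
    if isinstance(plus_record, SiteCount):
        return SiteCount(
            plus_record.chrom,
            plus_record.pos,
            plus_record.n_meth + minus_record.n_meth,
            plus_record.n_unmeth + minus_record.n_unmeth,
        )
    counts = tuple(
        (pm + mm, pu + mu)
        for (pm, pu), (mm, mu) in zip(plus_record.counts, minus_record.counts)
    )
    return CpGSiteCounts(plus_record.chrom, plus_record.pos, counts)


def destrand_records(records):
    """Merge adjacent-position records (p, p+1) into plus-strand CpGs.

    Coverage files carry no strand column, so strand pairs are recovered
    by adjacency: a record at p+1 immediately following one at p is taken
    to be the minus-strand G of the CpG at p.  Pairing is greedy from the
    left, which is unambiguous whenever distinct CpGs are >=3 bp apart.
    """
    out = []
    by_chrom = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        i = 0
        while i < len(recs):
            if i + 1 < len(recs) and recs[i + 1].pos == recs[i].pos + 1:
                out.append(destrand_cpg(recs[i], recs[i + 1]))
                i += 2
            else:
                out.append(recs[i])
                i += 1
    return out


def assemble_matrix(records_by_sample, samples=None) -> CpGMatrix:
    """Combine per-sample SiteCount lists into a sites x samples matrix.

    Sites absent from a sample get coverage 0 for that sample.
    """
    if samples is None:
        samples = sorted(records_by_sample)
    site_set = set()
    for recs in records_by_sample.values():
        site_set.update((r.chrom, r.pos) for r in recs)
    sites = sorted(site_set)
    idx = {site: i for i, site in enumerate(sites)}
    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for j, sample in enumerate(samples):
        for r in records_by_sample[sample]:
            i = idx[(r.chrom, r.pos)]
            meth[i, j] += r.n_meth
            cov[i, j] += r.coverage
    chrom = np.array([c for c, _ in sites], dtype=object)
    pos = np.array([p for _, p in sites], dtype=np.int64)
    return CpGMatrix(chrom=chrom, pos=pos, samples=list(samples), meth=meth, cov=cov)


def load_coverage_dir(directory, design: SampleDesign, destrand=True) -> CpGMatrix:
    """Read ``<sample_id>.cov`` for every design sample into one matrix."""
    from pathlib import Path

    records_by_sample = {}
    for sample in design.samples:
        path = Path(directory) / f"{sample}.cov"
        recs = read_coverage_file(path, sample)
        if destrand:
            recs = destrand_records(recs)
        records_by_sample[sample] = recs
    return assemble_matrix(records_by_sample, samples=design.samples)


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_utr", "5UTR", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "3UTR", "three_prime_UTR"}


def read_gtf(path):
    """Read a GTF/GFF2 annotation into GeneModel records (one per gene_id).

    Requires gene/transcript/exon features with ``gene_id`` and
    ``transcript_id`` attributes; UTR features are optional.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted attribute errors
        raise ParseError(f"failed to parse GTF {path}: {exc}") from exc

    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if "gene_id" not in g.attributes:
            raise ParseError(f"gene feature without gene_id at {g.seqid}:{g.start}")
        gene_id = g.attributes["gene_id"][0]
        transcripts = []
        all_exons = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            t_id = t.attributes["transcript_id"][0]
            exons = tuple(
                sorted(
                    (e.start, e.end)
                    for e in db.children(t, featuretype="exon")
                )
            )
            transcripts.append(Transcript(t_id, exons))
            all_exons.extend(exons)
        utr5, utr3 = [], []
        for child in db.children(g):
            if child.featuretype in _UTR5_TYPES:
                utr5.append((child.start, child.end))
            elif child.featuretype in _UTR3_TYPES:
                utr3.append((child.start, child.end))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                exons=all_exons,
                utr5=merge_intervals(utr5) if utr5 else [],
                utr3=merge_intervals(utr3) if utr3 else [],
                transcripts=sorted(transcripts, key=lambda t: t.transcript_id),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes, path, header=None):
    """Write GeneModel records as GTF (gene/transcript/exon/UTR features)."""

    def attrs(gene_id, transcript_id=None):
        a = f'gene_id "{gene_id}";'
        if transcript_id:
            a += f' transcript_id "{transcript_id}";'
        return a

    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            row = [g.chrom, "stressmeth", "gene", str(g.start), str(g.end),
                   ".", g.strand, ".", attrs(g.gene_id)]
            fh.write("\t".join(row) + "\n")
            for t in g.transcripts:
                fh.write("\t".join(
                    [g.chrom, "stressmeth", "transcript",
                     str(t.exons[0][0]), str(t.exons[-1][1]),
                     ".", g.strand, ".", attrs(g.gene_id, t.transcript_id)]
                ) + "\n")
                for s, e in t.exons:
                    fh.write("\t".join(
                        [g.chrom, "stressmeth", "exon", str(s), str(e),
                         ".", g.strand, ".", attrs(g.gene_id, t.transcript_id)]
                    ) + "\n")
            first_t = g.transcripts[0].transcript_id if g.transcripts else None
            for s, e in g.utr5:
                fh.write("\t".join(
                    [g.chrom, "stressmeth", "five_prime_utr", str(s), str(e),
                     ".", g.strand, ".", attrs(g.gene_id, first_t)]
                ) + "\n")
            for s, e in g.utr3:
                fh.write("\t".join(
                    [g.chrom, "stressmeth", "three_prime_utr", str(s), str(e),
                     ".", g.strand, ".", attrs(g.gene_id, first_t)]
                ) + "\n")


# ---------------------------------------------------------------------------
# hit tables, BED, TSV
# ---------------------------------------------------------------------------


def read_hits(path):
    """Read a 12-column tabular hit table into HitRecord rows."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                rec = HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not np.isfinite(rec.e_value) or rec.e_value < 0:
                raise ValidationError(f"{path}:{lineno}: bad e-value {parts[10]}")
            records.append(rec)
    return records


def write_hits(records, path):
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity:.3f}",
                        str(r.alignment_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        f"{r.e_value:.3g}",
                        f"{r.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def hits_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=HIT_COLUMNS)


def write_bed(sites, path, header=None):
    """Write (chrom, pos[, name]) site tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for site in sites:
            chrom, pos = site[0], int(site[1])
            name = str(site[2]) if len(site) > 2 else "."
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\n")


def write_tsv(table: pd.DataFrame, path, header=None):
    """Write a result table as TSV with an optional leading comment line."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_design(path) -> SampleDesign:
    return SampleDesign(read_tsv(path))


def write_design(design: SampleDesign, path, header=None):
    write_tsv(design.table, path, header=header)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample count matrix; first column = gene_id (index)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.values < 0).any():
        raise ValidationError(f"negative counts in {path}")
    return df


def write_counts(counts: pd.DataFrame, path, header=None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        counts.to_csv(fh, sep="\t", index_label="gene_id")
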
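# Methods

`stressmeth` re-implements, as a tested pipeline over synthetic data, the
computational core of an early-life-stress methylome/transcriptome study
design in Atlantic salmon: four treatment groups — unstressed control
(`CO`), stressed during embryogenesis (`E`), post-hatch (`PH`), or both
(`EPH`) — with six biological replicates each, profiled by reduced
representation bisulfite sequencing (RRBS, per-CpG methylated and
unmethylated read counts) and RNA-seq (per-gene fragment counts).

## Differential methylation (`diffmeth`)

Per CpG, methylated/unmethylated counts are modeled as per-sample
binomials with a logistic link on the group indicator:

    logit(pi_j) = b0 + b1 * 1{sample j in stressed group}.

Because the only covariate is binary, the IRLS fixed point is available
in closed form — the fitted group probabilities are the coverage-pooled
proportions — so the likelihood-ratio statistic reduces to the deviance
(G) statistic of the pooled 2x2 table, referred to chi-square with 1 df.
This is implemented vectorized across sites; there is no iterative
fitting and hence no non-convergence path (a pooled Fisher-exact helper
is provided for tiny-count situations).  The effect size is the pooled
percentage-point difference `100 * (m_b/c_b - m_a/c_a)` (stressed minus
control).  Degenerate sites (all-zero or all-one methylation in both
groups, or zero coverage in a group) report a difference of 0 and p = 1.

Calls: a site is hyper-/hypo-methylated when |difference| > 20 pp *and*
the Benjamini–Hochberg adjusted p (q) is below 0.1.  BH replaces the
sliding-linear-model q-values used by the upstream R package: that
procedure's dependence-structure fit is not reproducible from its
description, and BH is the standard, conservative substitute at the same
q < 0.1 threshold.

Prefilter: coverage >= 10 in every sample of the two compared groups and
at most each sample's 99.9th coverage percentile (PCR-duplicate guard).
Both are configurable.  Recovery of planted effects is quoted among
sites that pass this filter: a site too thinly covered to be tested is a
coverage limitation, not a test failure (the pipeline's own recovery
report additionally quotes the all-planted-sites figure, which is lower
by exactly the filter pass rate).

Known behavior: the pooled test ignores between-replicate overdispersion
and becomes anti-conservative as the beta-binomial precision falls; the
suite asserts both near-nominal type-I error at the default precision
and the directional inflation under strong overdispersion.

## Differential expression (`diffexpr`)

Counts are normalized by the median-of-ratios rule: size factor
`s_j = median_i counts_ij / geomean_i` over genes with all-positive
counts, then rescaled to geometric mean 1.  The rescaling leaves all
factor ratios and the normalized-value ratios untouched; it makes the
factors equivariant (scaling one sample by c scales its factor,
relative to every other sample, by exactly c).  A pseudo-reference
fallback handles matrices with no all-positive gene.

The group test is Welch's t on log2(normalized + 1) with BH adjustment —
a deliberately simple, documented stand-in for an assembled-transcript
negative-binomial model, kept behind a single function so it can be
swapped.  Classification uses the fold-change threshold on the ratio
scale: up if `log2fc >= log2(1.5)` and adjusted p < 0.05, down
symmetrically, with `log2fc = log2((mean_b + 1) / (mean_a + 1))` on
normalized means (pseudocount 1 keeps zeros finite).

"Consistent" genes — the set carried into the integration stage — are
those with |fold change| >= 1.5 in *every* stressed-vs-control
comparison with the same sign throughout; significance is deliberately
not required at this step, only the consistent fold change.

## Feature annotation (`feature_annotation`)

Each CpG receives exactly one category with precedence
promoter > 5' UTR > 3' UTR > exon > intron > intergenic; ties between
genes within one category break by distance to the nearest TSS, then
lexicographic gene id, so assignment is deterministic and independent of
gene input order.  The promoter is TSS +/- 1 kb (strand-aware) by
default — the single biggest lever on the promoter percentage, and
configurable.  "Exon" means non-UTR exonic sequence; introns are the
gene span minus merged exons, derived on the fly.

## Methylation–expression integration (`integration`)

For each consistent DE gene and comparison: CpGs are filtered to mean
coverage across all samples >= 6 reads (a stricter every-sample variant
is a flag) and |pooled methylation change| >= 8 pp, then averaged,
unweighted, over the gene body plus 10 kb flanks (inclusive boundaries,
clipped at the chromosome start).  The per-site change is the pooled
difference reused from `diffmeth`, not recomputed.  Genes with no
usable CpG are "flat".  Quadrants cross the sign of the mean change
with the expression direction (hyper-down, hyper-up, hypo-up,
hypo-down); percentages are reported over non-flat gene x comparison
profiles.  Welch's t-test (Satterthwaite df, hand-coded and verified
against an independent implementation) contrasts mean methylation
changes between the up- and down-regulated gene sets by default; the
comparison-vs-comparison contrast is also available, since which pair
of samples entered the original description is ambiguous.

## Window scan (`window_scan`)

Chromosomes are tiled with 1 Mb windows (step = size by default; a
smaller step yields sliding windows).  A DM site belongs to a window by
position, a gene by any span overlap (boundary-spanning genes count in
both windows).  A window is co-localized when it holds >= 1 significant
DM site and >= 1 significant DE gene.  Candidate regulatory windows are
ranked by (n DM sites) x (n DE genes) — an explicitly replaceable
default, since no ranking rule is prescribed for "key regulatory loci" —
with ties broken by summed |log2fc| and coordinates.  Each ranked window
reports the distance from every DM site to the nearest DE-gene span
edge (0 inside the gene).

## Duplicated blocks (`synteny`)

Each gene is represented by its longest transcript (ties: smallest
transcript id).  In an all-vs-all search of that set against itself the
best hit of every sequence is itself, so homologs are *second-best*
hits: after mapping transcripts to genes and dropping self-hits, each
gene keeps its minimal-e-value hit at e <= 1e-10 (ties by bit score,
then subject id).  Mutual best non-self hits form reciprocal pairs.
Pairs are chained into blocks along the first chromosome while the
gene-rank gap is <= 2 intervening genes on both sides with a consistent
direction per block (same or inverted); "neighboring" and collinearity
are not further specified upstream, so both the gap and the orientation
constraint are configurable, including a permissive no-orientation
mode.  Blocks need >= 10 anchor pairs; longest chains claim genes first
within a chromosome pairing.

## Synthetic data (`synthetic_data`)

The generator's defaults are the study conditions; they were fixed once
and are not tuned per test:

| parameter | default | rationale |
|---|---|---|
| design | 4 groups x 6 replicates | the study design |
| baseline methylation | Beta(8, 2) per CpG | mean 80%, matching the reported 77–80% global CpG methylation |
| coverage | NB(mean 30, size 8) per sample/site | RRBS-like depth with realistic overdispersion |
| replicate precision | beta-binomial, theta = 1000 | modest biological variation within one full-sib family (~3% variance inflation at 30x) |
| planted DM shift | 40 pp, 5% of sites, 53.7% hyper | detectable at the 20 pp threshold; hyper excess ~16% |
| expression baseline | log-normal(log 200, 1.2), NB size 8 | RNA-seq-like dispersion |
| planted DE | 8% of genes at log2FC +/- 2 | clear of the 1.5-fold threshold |
| linkage | 50% of DE genes, 4 CpGs each at +/-30 pp in body +/- 10 kb, quadrant mix 45/25/16/14 | gives the integration stage a known target split |
| duplications | 2 blocks x 12 consecutive genes | above the 10-gene block threshold |

Planted shifts are specified in percentage points on the probability
scale; baselines at planted sites are drawn from the Beta prior
truncated to leave full headroom, so the true effect equals the nominal
one (methylation-responsive CpGs are, realistically, sites with dynamic
range).  Stressed groups share each planted effect, mirroring the
concordant response across treatments.  Duplicated gene copies inherit
their source gene's fold change, so direction concordance is 1 by
construction.  Hit tables contain self-hits (e = 0), paralog hits
(e <= 1e-20) and background hits kept above the 1e-10 cutoff, making
block recovery exact on defaults; a hard mode adds sub-cutoff noise.

Coverage files are written stranded by default (plus-strand C at p,
minus-strand G at p + 1, counts split binomially/hypergeometrically so
strand sums are exact); both strand lines are emitted whenever a CpG
was observed.  Because the file format carries no strand column,
read-back destranding pairs adjacent positions greedily from the left —
unambiguous here because generated CpGs are >= 3 bp apart.  On real
data with directly adjacent CpGs this heuristic could mis-pair;
destranding can be disabled.

What the generator does *not* emulate: read-level artifacts (mapping,
bisulfite conversion errors), CpG-island clustering, covariate
structure beyond treatment, isoform-level expression, and degraded or
fragmented duplications.  Passing recovery tests therefore demonstrates
correctness of the computations under the stated generative model, not
performance on real RRBS libraries.

## Numerical and degenerate-input choices

* All thresholds keep values meeting-or-exceeding the cutoff
  (>= 6x, >= 8 pp, >= 1.5-fold; DM uses strict > 20 pp as specified).
* Internal coordinates are 1-based inclusive; BED output is 0-based
  half-open; conversions happen only at the writers.
* Deviances are clipped at 0 and NaN-guarded; probabilities are clipped
  to (1e-4, 1 - 1e-4) inside the generator before Beta parameterization.
* Empty inputs degrade to empty outputs with a warning (empty coverage
  file, all-flat quadrant report, gene with no surviving hit).
* Determinism: one integer seed drives every generator; rerunning the
  pipeline with the same config and inputs is byte-identical (tables
  sorted, no timestamps, config hash covers parameters but not paths).

## Problem sizes

Default study: 3 chromosomes x 3 Mb, 300 genes (+24 duplicates), 6,000
CpGs, 24 samples — the full pipeline runs in a few seconds.  The
quadrant-recovery analysis uses 2,500 genes on 5 x 9 Mb chromosomes with
200 linked genes; calibration checks use 5,000 null sites and 500
random 2x2 tables.  These sizes were chosen so every distributional
check has tight Monte-Carlo error while the whole suite stays fast.
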
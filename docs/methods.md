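# Methods

This note documents the models and procedures implemented in `epishift`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and inputs

All genomic coordinates are BED-convention: 0-based, half-open. Inputs are
plain text — BED4 segmentations (chrom, start, end, state), diffReps-like
per-mark region tables (chrom, start, end, direction, log2FC, padj), a DMP
table (cpg_id, chrom, pos, delta_beta, q, in_cgi), a TSV gene model
(comma-separated exon boundary lists, optional UTRs), an FPKM matrix with
a tumor/normal pairing table, a PPI edge list, and a survival table
(sample, time, event, subtype) with its own expression matrix. Upstream
callers (segmentation training, differential-region calling, FPKM
assembly, subtype assignment) are out of scope; their outputs are
consumed as given.

## Chromatin-state transitions

Both segmentations are discretized on a shared 200-bp grid (`bin_size`
configurable). A bin wholly inside one state interval takes that state; a
bin straddling a boundary takes the state covering the majority of its
bases, with exact ties resolved to the leftmost interval — segmentation
tools emit multiples of 200 bp, so the tie-break rarely fires. Bins
covered in only one track are excluded from all totals (not imputed) and
their count is reported.

For the joint occupancy matrix `observed[i][j]` (normal state *i*, tumor
state *j*), the independence null gives
`expected[i][j] = row_i × col_j / N`; `RES = observed / expected` and
`NES[i][j] = RES[i][j] / RES[j][i]`. Cells with zero expectation, or with
a zero reverse enrichment, are flagged undefined (NaN), never ±infinity,
so downstream ranking simply skips them; the diagonal NES is 1 wherever
the diagonal RES is positive, since a state mapping onto itself is not a
transition. NES is computed on the pooled segmentation pair; per-sample
NES with averaging is left as future work. The independence test is a
Pearson chi-square on the observed grid after dropping all-zero rows and
columns. Transition loci are reported as genes whose TSS ±2 kb promoter
contains at least one bin with the queried (from, to) pair.

The 19-label state vocabulary ships as a preset with functional group
annotations (promoter 1–4, transcribed 5–8, enhancer 9–14, ZNF 15,
bivalent TSS 16, bivalent/weak enhancer 17, polycomb 18, quiescent 19),
but state labels are free strings throughout.

## Interval engine and feature annotation

Interval intersection, overlap counting and merging are delegated to
pyranges behind the module's own interval types. Co-localization
significance follows the bedtools-fisher contingency model: with region
sets A and B, `n11` counts A-regions overlapping any B-region, `n12`/`n21`
the exclusive counts, and the no-overlap cell is estimated as
`genome_size / (mean_len(A) + mean_len(B)) − n11 − n12 − n21`, clipped at
zero; a two-sided Fisher exact test is applied. The estimate is documented
here precisely because it is a model choice, not an exact count.

Feature annotation assigns exactly one category per interval, judged at
the interval midpoint (this keeps the assignment single-valued for
intervals spanning boundaries), with fixed priority
Promoter(<1 kb) > Promoter(1–2 kb) > UTR5 > UTR3 > first exon > other
exon > first intron > other intron > downstream (≤3 kb past the
strand-aware gene end) > distal intergenic. Promoter sub-categories use
unsigned distance to the TSS, while the promoter window used everywhere
else is the symmetric TSS ±2 kb. Gene ties break by nearest TSS, then
lexicographic gene id. The priority order is a convention (promoter-first,
matching common annotators) and is recorded in output metadata. Feature
fractions are emitted both per-region (default) and per-bp.

Mark-combination analysis partitions the union of all marked bases by the
exact subset of marks covering each base; the partition conserves total
union bp by construction.

## Mark-expression integration

A gene's profile records at most one direction per mark, from alterations
overlapping its promoter: histone directions are the sign of the
bp-weighted up/down vote, mC's direction is the majority sign of promoter
DMP delta-betas (bp-weighting is meaningless for point CpGs); exact ties
drop the mark with a warning. Subgroups follow the voting rule: active
marks (H3K4me1, H3K4me3, H3K27ac, H3K36me3) up or repressive marks
(H3K27me3, mC) down vote "activating"; unanimous activating → active,
unanimous silencing → repressive, mixed → poised. The classification is a
partition and is invariant to mark order.

Expression uses `log2(FPKM + ε)` with ε = 0.01 — a pseudocount chosen to
keep zero-FPKM genes finite while perturbing typical values only in the
third decimal. Per-gene fold change is
`log2((mean tumor + ε) / (mean normal + ε))`. The additive-effect table
crosses mark-count groups (1/2/3/4+) with subgroups; its paired t-test
compares per-patient mean log2 expression of the cell's genes between
tumor and normal. Candidate retention is gated per gene: a paired t-test
across patients on log2(FPKM + ε) (≥3 pairs required), raw p < 0.05 and
log2 FC beyond ±1; Benjamini-Hochberg q-values are reported alongside but
raw p gates retention, matching how such thresholds are conventionally
applied. The subgroup-level t-test is also reported; the per-gene test is
the gate because retention is a per-gene decision.

The methylation-expression correlation is computed across genes (promoter
mean delta-beta vs log2 fold change, Pearson), with the anticorrelated
fraction defined by a negative product; a per-sample variant is not
implemented. Stratified Spearman correlations compare each mark's
alteration stat against fold change separately for genes carrying only
that mark vs ≥2 marks (strata under 5 genes suppressed). Pairwise mark
correlations use signed per-gene stats over genes where both marks are
altered in the scoped region — promoter, or CDS defined as the union of
exons minus UTRs — masking entries with p ≥ 0.05.

## PPI hub screen, kappa grouping, ORA

Centralities are degree and harmonic closeness `Σ 1/d(u,v)` over shortest
paths (unreachable pairs contribute 0). Harmonic closeness is used because
it is unbounded and scales with network size, which is the only reading
compatible with an absolute screening threshold in the hundreds on a
network of a few hundred nodes; the threshold (default 130) is a config
knob. The hub filter keeps candidates with closeness strictly above the
threshold, then all underexpressed candidates plus the top
`ceil(0.30 × n)` overexpressed candidates by degree (ties by closeness,
then id). Filtering candidates before computing the retained set follows
the screen's stated order; both orders are trivially composable from the
library functions.

Term-term similarity is Cohen's kappa on binary membership vectors over a
declared universe; groups are connected components of the kappa ≥ 0.4
graph (components, not cliques — deterministic and testable, simplifying
iterative merging schemes). The over-representation test is an upper-tail
hypergeometric with fold enrichment observed/expected; BH adjustment
across terms is the caller's responsibility.

## Survival

Univariate Cox fits use the partial likelihood with Breslow tie handling
(lifelines); failures — fewer than 2 events, zero expression variance,
non-convergence — are flagged and the gene skipped, not raised. Screening
uses the Wald p (likelihood-ratio p is reported alongside). The signature
keeps candidates at p < 0.05 in input order; the risk score is the exact
linear combination `Σ β_i × Exp_i`. Median dichotomization sends scores
equal to the cutoff to the low-risk arm; an all-equal score vector is an
error. Kaplan-Meier estimation and the two-group log-rank test come from
lifelines. Subtype-stratified marker tables refit the univariate model
within each subtype (ALL = no filter, then CIN/GS/EBV/MSI), keep p < 0.05
and class genes Risky (β > 0) or Protective; refitting per subtype (rather
than reusing pooled coefficients) matches subtype-specific survival
stratification. Subtypes with fewer than 2 events are skipped with a
warning.

## Synthetic-data generator

The generator emulates the *processed products* of a paired tumor/normal
epigenome study — never raw reads, array noise models or batch effects.
Defaults define the study conditions; all randomness flows from one seed
through per-stage child streams, and regeneration is byte-identical.

- **Genome and genes**: one gene per 12-kb slot (default 300 genes on a
  3.6-Mb chromosome), 2–5 exons, random strand, UTRs at the transcript
  ends; promoters never leave their slot, and background alterations are
  confined to the first 500 bp of each slot, which no promoter reaches.
- **Segmentations**: normal states follow a first-order spatial chain
  (stay probability 0.92) in 200-bp bins over the 19-label preset; the
  tumor track resamples 10% of bins to a random other state (background
  discordance, so every transition cell is populated) and then rewrites a
  fraction f of state-i bins to state j for each planted pair (default
  E4 → E1 at f = 0.3). Converted bins are logged in the truth sidecar.
- **Marks and methylation**: 75% of genes are marked. A marked gene is
  mC-only with probability 0.35 (DNA methylation predominantly acts
  alone; its direction then splits evenly between hypo and hyper);
  otherwise it draws a subgroup (active 0.4 / repressive 0.3 / poised
  0.3) and a mark count (1–6, decaying), taking marks from a fixed
  co-occurrence module at the co-localization rate or uniformly
  otherwise. Directions realize the subgroup's votes. mC is emitted as
  3–8 promoter DMPs sharing the vote's sign; hypermethylated positions
  fall in CGIs with probability 0.8, hypomethylated with 0.15. A
  background pool of 3000 distal DMPs is 87% hypomethylated, so the
  genome-wide pool is dominated by hypomethylation while promoter CpGs
  carry the planted signals.
- **Expression**: 19 tumor/normal pairs. Gene baselines are
  N(3, 1.2²) log2 FPKM; each patient adds N(0, 0.3²) noise per sample.
  The tumor shift is the sum of signed per-mark effects (default
  0.5 log2 per mark, positive for activating votes) plus gene-level
  noise whose standard deviation is solved, from the realized moments of
  the planted shifts and methylation magnitudes, so that the correlation
  between gene-level delta-beta and the tumor shift hits the configured
  target (default −0.436) over mC-marked genes; `gene_noise_sd` overrides
  the solver for null experiments.
- **PPI and survival**: a preferential-attachment graph over all marked
  genes, with 5 planted hubs (strongly shifted active and repressive
  genes) each wired to 60 extra neighbors so they clear the closeness
  screen. Survival draws 300 patients with TCGA-like subtype proportions
  (CIN 0.50 / GS 0.20 / EBV 0.09 / MSI 0.21), standard-normal per-gene
  expression, exponential times with per-subject log hazard
  `Σ β × expression` over the plants applying to the subject's subtype
  (default: one cohort-wide and one CIN-specific gene at log HR 1.0),
  and independent censoring at rate 0.3.

What passing tests show — and do not show. The generator's planted
structure makes recovery tests sharp: enrichment ranking, subgroup
round-trips, additive means, hub retention and subtype-marker specificity
all have known answers. It does not reproduce genomic length
distributions, linkage between neighboring genes, array measurement
error, mappability artifacts or cohort heterogeneity, so passing here
demonstrates correctness of the computations, not performance on real
cohorts.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen so each property has the
power it needs: oracle equivalence runs on ≤10-kb genomes where per-base
brute force is exact; null calibrations use 200 replicates (chi-square
level within the binomial 99% CI) or 100 replicates (candidate false
retention, Cox bias); additive-effect recovery uses ≥200 active genes per
mark-count group; survival recovery uses n = 300 with 100 seeds. Cox fits
use lifelines defaults (Newton iterations, convergence on the step norm);
NES and RES undefined entries propagate as NaN; the subtype-specificity
check uses a decision rule fixed in advance (≥4/5 replicates recover the
planted CIN marker; ≤3 spurious flags across the 15 null
subtype-replicate combinations, the binomial(15, 0.05) upper ~0.5%
tail).

## Known limitations

Per-sample (as opposed to pooled) transition enrichment, multivariate or
penalized Cox models, time-dependent covariates, GTF parsing, nearest-gene
annotation beyond the fixed categories, and retrieval from external
databases (STRING, pathway collections, TCGA) are deliberately out of
scope. Gene-set terms for kappa grouping and ORA are supplied by the user
as GMT files.
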
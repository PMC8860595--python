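# Methods

## Problem setting

`threeprime` analyses strand-specific transcript 3′-end sequencing of
nucleoplasmic RNA under depletion of nuclear RNA-decay factors. The decay
machinery of interest is the RNA exosome (core subunit EXOSC3) and its two
nucleoplasmic adaptors: the NEXT complex (ZCCHC8, targeting nonadenylated
3′ ends) and the PAXT connection (ZFC3H1, targeting polyadenylated 3′ ends).
Two depletion regimes are compared — rapid auxin-degron (AID) time courses
(0/2/6 h) and long-term RNAi — in paired library types: pA⁺ (in-vivo
adenylated ends only) and pA⁺/⁻ (all ends, captured after in-vitro
polyadenylation). The central question is which 3′-end clusters are *direct*
pathway targets (respond to rapid depletion) and which accumulate only under
long-term depletion, i.e. are likely indirect.

## Coordinate and data conventions

All coordinates are 0-based half-open `[start, end)`; GTF input is converted
on read. Strand is mandatory everywhere and every overlap query is
strand-matched. A transcript 3′ end is recorded at its last transcribed
nucleotide. The splice-acceptor (SA) position of an intron is the first
nucleotide of the downstream exon in transcription orientation (for a
minus-strand intron `[s, e)` this is genomic position `s − 1`), so intron
3′ ends accumulate at orientation offset −1 from the SA anchor.

## Normalization

Bulk mRNA levels are assumed insensitive to exosome depletion, so library
size factors are estimated from 3′-end counts summed over protein-coding
last exons only (all ends in the exon are summed). Exons are filtered to
those with strictly more than `min_reads` (default 100) reads in at least
one library. After adding a pseudocount of 1, factors are median-of-ratios:
the per-exon reference is the geometric mean across libraries and a
library's factor is the median of its pseudocounted counts over that
reference. One estimator serves both AID and RNAi libraries. Numerical
choices: the median uses the lower-of-two convention on even counts for bit
reproducibility, and ratios are computed as `x / exp(mean(log x))` so the
result is reproducible to the last ulp against the straightforward
arithmetic. Exosome-sensitive clusters never enter the size-factor matrix,
so factors are invariant to their presence.

## Cluster calling and annotation

3′-end clusters are called from raw counts pooled across all libraries:
positions with pooled count ≥ `min_pos_count` (default 3) seed clusters, and
same-strand seeds separated by ≤ `max_gap` nt (default 25) are merged by
single linkage; the cluster interval spans the merged seeds and the summit
is the (leftmost) maximum-signal nucleotide. These caller parameters are
this package's defaults, exposed in configuration.

Each cluster receives exactly one biotype by strand-matched overlap with a
fixed most-specific-first priority (PROMPT > eRNA > snoRNA > lncRNA >
protein-coding > not annotated) and, within protein-coding transcription
units, at most one feature label (SA of a snoRNA-hosting intron > SA of a
regular intron > PAS > TSS-proximal > exonic > intronic). A cluster is "at
an SA" when its summit lies within `sa_window` nt (default 10) upstream of
the SA in transcription orientation; "at the PAS" within 25 nt upstream of
the annotated 3′ end; "TSS-proximal" within 3 kb downstream of the TSS on
the sense strand (this captures prematurely terminated transcripts). The
priority orders and the PAS/TSS windows are design choices made to yield a
deterministic single label per cluster, as composition percentages require.

## Differential expression

Cluster counts are modelled per cluster as negative binomial with
`var = μ + αμ²`, fit by a log-link GLM (IRLS, ≤ 100 iterations, deviance
tolerance 10⁻⁸) with `log(size factor)` offsets, a condition indicator and,
for RNAi designs prepared in separate batches, batch dummies. The contrast
coefficient is tested by a two-sided Wald test; p-values are
Benjamini–Hochberg adjusted (non-converged fits get NA and are excluded
from the correction, never crash the run). Upregulated calls use strict
thresholds `log2FC > 1` and `padj < 0.1`.

Dispersion is a per-cluster method-of-moments estimate (pooled within-group
variance on size-factor-normalized counts) shrunk toward a parametric trend
`α(μ) = a₀ + a₁/μ` fitted across clusters by non-negative least squares,
with a fixed trend weight of 0.8, floored at 10⁻⁶ and capped at 10. The
heavy trend weight is deliberate: with duplicate libraries per condition the
per-cluster moment estimate is extremely noisy, and Wald tests built on it
are anticonservative; borrowing strength across clusters restores
calibration (verified by simulation: on a 2000-cluster global null with
n = 2 vs 2 the raw-p < 0.05 fraction is ≈ 0.05, while recall of planted
4-fold effects remains ≈ 0.99). There is no empirical-Bayes machinery
beyond this fixed-weight shrinkage, and no shrunken-LFC estimator.

PCA of libraries uses `log2(normalized count + 1)` as a simple
variance-stabilizing transform, the top 2000 clusters by variance across
libraries, per-cluster centering and SVD.

## Sensitivity statistic and target classification

The depletion response of a cluster is summarized as

    sensitivity = (treated − ctrl) / max(ctrl, treated, 1)

on replicate-averaged (arithmetic mean), size-factor-normalized counts. The
statistic is bounded in [−1, 1]: +1 for signal exclusive to the depletion
sample, −1 for signal exclusive to the reference, 0 for equal signal; the
unit floor keeps sub-unit signals from saturating the bound. AID contrasts
are referenced to the 0 h libraries of the same tagged line; RNAi contrasts
to the control-siRNA libraries.

Targeting classes intersect upregulated calls: NEXT candidates are clusters
up in both RNAi and 6 h AID ZCCHC8 depletion, PAXT candidates likewise for
ZFC3H1; upregulated calls from pA⁺ and pA⁺/⁻ libraries are unioned per
method before intersecting (intersection and per-mode behaviour are
available as options). Mutual exclusion is applied after the RNAi∩AID
intersection: clusters in both candidate sets are dropped from both classes.
Class composition is reported as percentages over single-labelled members.

The intron-length stratification uses classes <700 nt, 700–4000 nt
(inclusive on both ends) and >4000 nt. The SA-overlap summary reports, per
length class and condition, the percentage of SA sites with at least one
upregulated cluster whose summit falls in the `sa_window` upstream of the
SA; both an all-anchors and an expressed-anchors denominator are available
(default: all anchors).

## Metagene profiles and the trimming read-out

Metagenes are computed at single-nucleotide resolution over orientation
offsets −150..+99 around oriented anchors (window configurable), on
normalized tracks. Default aggregation sums coverage across anchors per
offset for treated and reference separately, then takes one
`log2((T + 1)/(R + 1))` per offset — robust to per-anchor zeros; a
mean-of-per-anchor-log-ratios mode is available. Anchors whose window would
cross the chromosome start are skipped (not clipped) so per-offset
denominators stay uniform; the skip count is reported.

The qPCR trimming factor is the ratio of SA-distal to SA-proximal amplicon
quantities after ΔCt normalization (`2^−ΔCt`); values > 1 indicate 3′-trimmed
species retaining the distal but not the proximal region, and any common
fold change of both amplicons cancels. The in-silico analogue sums
normalized 3′-end signal in a distal window (offsets −150..−20, inclusive)
and a proximal window (−10..0) around SA anchors and reports
`(distal + 1)/(proximal + 1)`. The window bounds are design choices that
bracket the ~50 nt upstream positional bias of trimmed intermediates while
excluding the sharp SA peak.

## Synthetic data generator

The generator emulates the full experimental design: a synthetic chromosome
of multi-intron protein-coding genes (intron lengths drawn from a
configurable mixture over the three length classes; a configurable fraction
of introns ≥ 450 nt host a 100-nt snoRNA placed ~250 nt upstream of the
SA), antisense PROMPT regions upstream of TSSs, intergenic eRNA and lncRNA
loci; and one raw track per library of the default 52-library design
(3 AID lines × 3 time points × 2 pA modes × 2 replicates, plus RNAi with a
control and two batches).

Planted structure, recorded in a ground-truth table:

* **Pathway effects.** PROMPT/eRNA/lncRNA end clusters draw a pathway label
  (NEXT 0.4 / PAXT 0.4 / both 0.1 / none 0.1); snoRNA-hosting SA clusters
  are NEXT; PAS clusters are unaffected (they carry the normalization
  anchor). The per-pathway effect is log2FC = 2 by default. Effect sizes
  are configurable study conditions, not measured values.
* **Kinetics.** NEXT effects under rapid ZCCHC8 loss plateau (full effect at
  2 h, held at 6 h — the fail-safe handover to PAXT caps accumulation);
  PAXT and all EXOSC3 effects grow linearly in log2FC over the time course.
  Exact rates are inventions; only the plateau/progressive contrast is
  meaningful.
* **pA handover.** A configurable fraction (0.3) of NEXT clusters start
  nearly nonadenylated (pA⁺ fraction 0.05) and switch to mostly adenylated
  (0.6) under ZCCHC8 or EXOSC3 depletion, so their pA⁺ signal rises while
  pA⁺/⁻ signal persists.
* **RNAi-specific indirect effects.** SA clusters of regular introns gain an
  RNAi-only extra log2FC of 0 / 0.7 / 1.5 for short/medium/long introns
  under ZCCHC8 RNAi, reproducing the length-scaled long-term phenotype.
* **Trimming smear.** In EXOSC3-depleted libraries a fraction (0.8) of each
  snoRNA-hosting SA cluster's signal is redistributed from the SA peak into
  a Gaussian of 3′ ends centered 50 nt upstream of the SA (sd 30 nt),
  truncated to the region between the hosted snoRNA 3′ end and the SA.

Counts are negative binomial (`var = μ + αμ²`, α = 0.05) around log-normal
baseline means (median 200, σ = 0.8; PAS clusters 5× higher so last exons
clear the expression filter). Within a cluster, baseline ends scatter
multinomially with geometric decay 0.5 from the summit; the *effect* signal
uses a sharper decay of 0.25, reflecting that stabilized decay
intermediates pile up at the precise SA/3′-end position. RNAi libraries
carry a two-level multiplicative batch offset (log2 0.3) to exercise the
batch covariate. Everything is deterministic given the seed.

**What the generator does not emulate:** mechanistic decay kinetics (no
rate equations), read-level error or mappability, alternative 3′-end
isoform choice, chromatin context, inter-gene correlation, and real cluster
shape diversity. Passing tests therefore demonstrate that the analysis
recovers the statistical structure it assumes — planted effects, kinetics,
handover, smears — not that it reproduces any particular published dataset,
whose cluster coordinates and class sizes depend on external sequencing
data.

## Problem sizes

Default test and demonstration runs use 60 protein-coding genes (~270
introns), ~20 eRNA and 10 lncRNA loci, ~300 planted clusters and 52
libraries; statistical validation of the differential test uses matrix-level
simulations of 2000 clusters. These sizes make every property measurable
with comfortable margins (e.g. ≥ 30 SA anchors per intron length class)
while keeping a full pipeline run to a few seconds.

## Known limitations

* The NB Wald test with fixed-weight trend shrinkage is calibrated at the
  simulated conditions but is not a drop-in replacement for DESeq2-style
  empirical-Bayes inference; p-values on real data with outliers or
  heavy-tailed dispersion will differ.
* The cluster caller is a simple seed-and-merge procedure; published
  cluster coordinates derived from other pipelines will not be reproduced
  exactly.
* Multi-overlap clusters receive a single label by fixed priority; analyses
  that count clusters multiply per feature need the raw overlap table.
* BigWig tracks are supported only through prior conversion to bedGraph.
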
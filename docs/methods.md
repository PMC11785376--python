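# Methods

## Scope and model

`cotarget` analyses two transcription factors' genome-wide binding (two
ChIP-seq peak sets on a shared genome build) jointly with two
mutant-vs-wild-type expression contrasts (per-gene log2FC, p, FDR). Its
object of inference is the division of regulatory labour between the two
factors: co-occupied binding sites, per-factor direct targets, co-regulated
versus exclusive target classes, and the phenotypic relevance of targets.
Read alignment, peak calling and count-level differential-expression
modelling are upstream of this package: it consumes their flat-file
outputs (BED, chrom.sizes, TSV tables) and never raw reads.

Coordinates are 0-based half-open throughout. Overlap always means ≥ 1
shared base under half-open arithmetic; touching intervals do not overlap.
All emitted collections are deterministically sorted and every stochastic
stage derives its own seed from the master seed by hashing an indexed
stage label, so inserting a stage never shifts another stage's draws.

## Co-occupancy geometry

Each peak is reduced to a centroid, `floor((start + end − 1) / 2)` — the
midpoint between the first and the (inclusive) last base. For each query
peak the absolute distance to the nearest other-set centroid *on the same
chromosome* is recorded and pooled across chromosomes; query peaks on
chromosomes without any target centroid are skipped and counted in a log
line. Two pairing modes exist because "nearest neighboring pair" admits
two readings: the default *directional* mode (every query peak reports its
nearest target centroid, targets reusable) and a *greedy-mutual* mode that
repeatedly extracts the globally smallest entry of the per-chromosome
distance matrix, using each peak at most once. The greedy mode is O(n·m)
per chromosome and intended for moderate set sizes. Neither mode is
claimed to reproduce any particular published midpoint; the scientific
content — observed distances collapse far below the null when factors
co-bind — is robust to the choice.

The randomization null re-places each peak uniformly on its own
chromosome (`start ~ U[0, L − width]`), preserving per-chromosome counts
and widths. Preserving width keeps overlap statistics comparable between
observed and randomized sets. One replicate is the default; the replicate
count is configurable and all replicate seeds are logged. For uniformly
placed target peaks at density λ = n/L, directional nearest-centroid
distances are approximately Exponential(2λ), so the ECDF midpoint
(interpolated empirical median) approaches ln(2)/(2λ); the test suite and
the acceptance script verify the implementation against this closed form
(observed agreement ~1–2% at n = 2000, L = 20 Mb, 10 seeds).

Overlap bookkeeping reports both directional counts (A peaks overlapping
≥ 1 B peak, and vice versa), the number of merged clusters containing both
labels — a candidate single "shared" count when directional counts differ
— and percentages that recompute exactly from the counts, reported to
0.1%.

## Direct-target inference

The regulatory potential `S_g = Σ_k exp(−(0.5 + 4Δ_k))` with
`Δ_k = |centroid_k − TSS| / d` sums over peaks with Δ ≤ 1. The window
default d = 3000 bp is the analysis' operating point; the exponential
decay is the form used by the established binding-and-expression target
method this stage follows, and a flat (no-decay) kernel is available for
sensitivity analysis. Peaks are not strand-adjusted: the TSS column of the
annotation is already strand-resolved, and distance from the TSS is all
that enters.

Ranking: binding rank r_S orders S_g descending; expression rank r_E
orders FDR ascending with ties broken by |log2FC| descending, then gene
id (all rank ties break by gene id last, for determinism). Ranking on FDR
rather than raw p is a documented choice; with BH adjustment within a
fixed contrast the two orderings agree except within tie blocks. The rank
product RP = (r_S/n)(r_E/n) ∈ (0, 1] is the integration score; a *call*
additionally requires FDR ≤ 0.05 (default) and ≥ 1 peak in the window.
Direction is the mutant contrast's log2FC sign: down-regulated in the
mutant ⇒ activated by the factor.

The function test compares RP of up-regulated DEGs (and separately
down-regulated DEGs) against non-DEG background genes with a one-tailed
KS statistic, D = max(ECDF_target − ECDF_background), alternative "target
set skewed toward smaller RP", p = exp(−2mn/(m+n)·D²). The asymptotic
one-sided formula holds its nominal level within ±0.01–0.02 at the sizes
used here (empirically 0.034–0.053 at α = 0.05); scipy's one-sided
two-sample KS is used as an independent cross-check in the tests. Each
compared set must contain ≥ 5 genes; a purely activating factor typically
has too few up-regulated DEGs, in which case the pipeline logs and skips
the test rather than fabricating a verdict. Note that because RP contains
the expression rank, any DEG set is mildly favoured against non-DEG
background; the type-I calibration therefore draws target scores from the
background distribution itself.

## Conditional DEG overlap

Intersecting two DEG lists at a hard double cutoff undercounts genes that
sit just past the threshold in one contrast. The conditional procedure
implemented here: (1) first-contrast DEGs at FDR ≤ 0.01; (2) partition
the second contrast's genes into first-contrast DEG / non-DEG groups;
(3) recompute BH-adjusted values from the second contrast's *raw*
p-values within each partition; (4) shared DEGs are first-contrast DEGs
whose partition-conditional adjusted value is ≤ 0.01. The A-DEG partition
is small, so BH within it is far less punishing than a transcriptome-wide
adjustment — that is the procedure's point, and the suite contains a
fixture where a marginal gene (raw p = 0.004 among 200 genes) is
recovered conditionally but lost globally. Genes non-significant in the
first contrast can never be shared, by construction. BH is used wherever
an FDR is recomputed, keeping the rule uniform across stages. The exact
partition-conditional-BH definition given here is normative for this
package.

## Target classification

A gene is co-regulated iff it is in the shared DEG set AND an A peak and
a B peak within its window overlap each other; co-regulated genes split
into same-sign and antagonistic purely by the product of the two
contrasts' log2FC signs (magnitudes are not used). Called-for-A genes not
co-regulated are A-exclusive; likewise for B, with B-exclusives split by
the B direction. These definitions make the bookkeeping identities exact
on any input, and the suite checks them both on synthetic runs and on a
fixture at the published scale (367 = 238 + 129, 129 = 114 + 15,
279 = 129 + 150).

HOT (high-occupancy target) regions are computed from user-supplied
per-factor peak collections by a sweep line over peak boundaries, after
merging each factor's own peaks so a base counts each *factor* once no
matter how many of its peaks stack there. Maximal intervals covered by
≥ 15 distinct factors (default) are merged and flagged; the count of
distinct factors rather than peaks is the deliberate reading of "bound by
N factors". Calling is invariant to the order of the factor collections
and is verified against a per-base occupancy oracle on toy chromosomes.

## Phenotype screen

Glass' Δ = (mean(control) − mean(test)) / sd(control), with the sample
(n − 1) standard deviation, signed so larger Δ means smaller animals.
Normalizing by the control sd alone keeps effect sizes comparable across
genetic backgrounds whose perturbed variances differ. Significance is a
two-sided Welch two-sample t-test per condition against the control, BH
adjustment across the screen, and the joint hit rule adjusted p ≤ 0.05
AND Δ ≥ 1. The Welch-plus-BH combination is a deliberate substitute for
omnibus-ANOVA-plus-Dunnett workflows: the screen's decision surface is the
effect size and the joint cutoff, not the exact post-hoc p, and Welch+BH
keeps the procedure dependency-light and exactly reproducible. Animals are
pooled across biological replicates in the default analysis; replicate
labels are carried for a per-replicate-mean variant.

## Synthetic data: what it emulates, what it does not

The generator plants a full truth structure so every stage can be scored
by parameter recovery:

* **Genome/annotation** — six 3-Mb chromosomes, 1000 genes placed
  uniformly with minimum inter-TSS spacing 2d = 6 kb (the spacing
  transform keeps placement uniform conditional on the gap), so target
  windows never collide by construction.
* **Classes** — each gene is co-activated (10%), antagonistic (2%),
  A-exclusive-activated (12%), B-exclusive-activated (10%),
  B-exclusive-repressed (14%) or unregulated (52%); proportions echo the
  emulated study's asymmetry (more B-exclusive than A-exclusive targets).
  Activation by a factor means true log2FC < 0 in that factor's mutant.
* **Peaks** — regulated genes get their factor's peak with centroid
  within 1 kb of the TSS (inside the 3-kb window); co-bound genes get an
  A/B pair with centroid offset ≤ 50 bp < minimum width 200 bp, hence
  overlapping by construction. Widths are uniform on 200–400 bp.
  Independent uniform background peaks (100 A, 700 B) and 400
  *non-functional co-bound pairs* complete the sets; the latter component
  reproduces the emulated peak-level geometry — most A peaks overlap a B
  peak (~72%), most B peaks are independent, and most co-occupied sites
  are associated with no expression change. Background peaks can land in
  gene windows by chance; such collisions are a documented property of
  the null, bounding false target calls at roughly the DEG FDR times the
  window hit rate (~0.4% of unregulated genes at the defaults).
* **Expression** — observed log2FC = β + Normal(0, σ) at the
  summary-statistic level with |β| = 2, σ = 0.25 for regulated genes,
  p = 2Φ(−|obs|/σ), BH FDR per contrast. The strong planted effect makes
  recovery failures attributable to the pipeline rather than to noise.
  Count-level simulation and GLM fitting are deliberately not emulated:
  the pipeline consumes summary tables.
* **Body lengths** — Normal(μ_g, 50) µm per genotype around a 1000-µm
  control, with "small" genotypes shifted by Δ_true control-sds; n = 50
  animals per group by default.

What passing on this generator does **not** show: robustness to real peak
width/shape distributions, to clustered or GC-biased binding, to
correlated noise across contrasts, to annotation errors, or to weak
effects near the significance boundary. Synthetic effect sizes and class
proportions are operating conditions of the test bed, not estimates of
any real dataset.

## Numerical and degenerate-input choices

* ECDF midpoint = `numpy.median` (linear interpolation between central
  order statistics); empty distance distributions are an error, as are
  negative distances.
* Nearest-neighbor ties break toward the leftmost target centroid
  (distance unaffected; pairing deterministic).
* Duplicate gene ids, out-of-bounds coordinates, p/FDR outside [0, 1],
  and gene/chromosome references absent from the build or annotation are
  rejected with the offending record named; parse errors carry line
  numbers.
* Randomizing a peak wider than its chromosome is an error.
* Glass' Δ with zero control sd is an error rather than ±inf.
* Direction-fidelity analyses (an activating factor's called targets are
  all down-regulated) are run with background peaks disabled, because a
  background peak colliding with a by-chance DEG produces a false call of
  arbitrary sign; with background on, the fidelity bound is 1 minus the
  collision rate, not exactly 1.

## Problem sizes

Default analysis sizes were chosen so that the whole suite and the
acceptance script complete in seconds while keeping every statistical
check well-powered: 1000-gene synthetic runs, 2000-peak null-calibration
sets on a 20-Mb chromosome (10 seeds), 1000-replicate KS calibration, 100
random instances for the brute-force oracle comparisons, and 10-seed
phenotype screens at n = 50.

## Known limitations

* The greedy-mutual pairing mode materialises a per-chromosome distance
  matrix; use the directional mode for very large peak sets.
* The conditional-overlap procedure is defined (and tested) for exactly
  two contrasts.
* HOT calling assumes factor collections fit in memory as flat peak
  lists; no streaming.
* The KS function test's asymptotic p-value is inaccurate below ~5 genes
  per set, which is why small sets are refused.
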
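# cotarget

Genome-wide integration of two transcription factors' ChIP-seq peaks with
mutant RNA-seq contrasts, for asking how a pair of DNA-binding factors —
for example a Smad and its Schnurri-family partner in a BMP signaling
pathway — divide regulatory labour: where do they bind together, which
genes does each directly regulate, which targets are co-regulated versus
factor-exclusive, and which of those targets matter for a downstream
phenotype such as body size.

The package is a library plus a `cotarget` command-line tool. It ships a
synthetic-data generator that plants known co-occupancy and regulatory
structure, so the entire pipeline runs, and is tested, without any
external download.

## What it computes

**Peak co-occupancy geometry.** Each peak is reduced to its centroid (the
midpoint between its border coordinates). For every peak of factor A the
distance to the nearest factor-B centroid on the same chromosome is
recorded; the ECDF midpoint of these inter-centroid distances is compared
with a randomization null in which every peak is re-placed uniformly on
its own chromosome (width and per-chromosome counts preserved). Interval
bookkeeping counts, per direction, peaks sharing ≥ 1 bp with the other
set (half-open coordinates; adjacency is not overlap).

**Direct-target inference.** Each gene g receives a regulatory potential
over peaks whose centroid lies within d = 3 kb of its TSS,

    S_g = Σ_k exp(−(0.5 + 4Δ_k)),   Δ_k = |centroid_k − TSS| / d ≤ 1,

the standard exponential decay of binding-and-expression target analysis.
Genes are ranked on binding (S_g, descending) and on differential
expression (FDR, ascending), and scored by the rank product
RP = (r_S/n)·(r_E/n) — smaller is stronger. A gene is *called* a direct
target iff its contrast FDR ≤ 0.05 and ≥ 1 peak lies in the window; its
direction follows the mutant log2FC sign (down-regulated in the mutant ⇒
activated by the factor). A one-tailed KS test on RP of up- vs
down-regulated DEGs against non-DEG background yields an
activator/repressor verdict.

**Conditional DEG overlap.** To intersect the two mutant contrasts
without the double-cutoff underestimate, the second contrast's genes are
partitioned by the first contrast's DEG status (FDR ≤ 0.01),
Benjamini–Hochberg adjustment is recomputed within each partition from
raw p-values, and shared DEGs are first-contrast DEGs whose conditional
adjusted value is ≤ 0.01.

**Target classification.** Genes are assigned to co-regulated (same-sign
or antagonistic, requiring both the shared-DEG condition and an
overlapping A/B peak pair in the window), A-exclusive, or B-exclusive
(split by direction), with exact bookkeeping identities
(|A-exclusive| + |co-regulated| = |A targets|, etc.). Peaks can
additionally be screened against high-occupancy target (HOT) regions —
loci covered by ≥ 15 distinct factors in a multi-factor compendium.

**Phenotype screen.** Candidate-gene knockdowns are scored by Glass'
Δ = (mean control − mean test) / sd(control) on body length, with Welch
t-tests and BH adjustment; hits satisfy adjusted p ≤ 0.05 AND Δ ≥ 1.

## Worked example

```sh
cotarget run-all --simulate --seed 42 --out-dir demo
```

simulates 1000 genes on six 3-Mb chromosomes with planted regulatory
classes, runs every stage, and writes TSV/JSON outputs plus a manifest.
From `demo/overlap_summary.json`:

```
observed_midpoint_bp   35.0        randomized_midpoint_bp  4529.5
pct_a_overlapping      72.0        pct_b_overlapping       37.3
```

The observed inter-centroid midpoint (35 bp) is two orders of magnitude
below the randomization null (4.5 kb): the two factors co-occupy sites
far more than chance placement allows. Most A peaks overlap a B peak,
while most B peaks are independent — the planted asymmetry.
`demo/category_counts.json` shows the target bookkeeping:

```
a_total 243 = a_exclusive 123 + co_regulated 120
b_total 363 = b_exclusive 243 + co_regulated 120
co_regulated 120 = same_sign 100 + antagonistic 20
```

and `demo/screen.tsv` recovers all five genotypes planted with Glass'
Δ = 2 as hits (estimated Δ 1.72–2.07, adjusted p < 1e-14) with zero false
hits among the null genotypes.

Every stage is also available as a subcommand on user-supplied files
(`simulate`, `geometry`, `targets`, `loa`, `classify`, `hot`, `screen`);
see `cotarget <cmd> --help` for the file formats (BED peaks, chrom.sizes,
gene/DEG TSVs).

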
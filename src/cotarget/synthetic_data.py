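"""Synthetic genomes, peak sets, DEG contrasts and body-length data.

The generator plants a known regulatory structure so every downstream stage
can be validated by parameter recovery:

* each simulated gene carries exactly one :class:`RegulatoryClass` fixing
  which factors bind near its TSS and how its expression responds in each
  mutant-vs-wild-type contrast (activated by a factor => down-regulated in
  that factor's mutant, so true log2FC < 0);
* co-regulated genes (co-activated or antagonistic) receive an A peak and a
  B peak with centroids offset by at most the co-bound offset — smaller
  than any peak width, so the pair overlaps by construction; exclusive
  genes receive one factor's peak only; background peaks are uniform over
  the genome and independent between sets;
* observed log2FC is the true effect plus Normal(0, sigma) noise at the
  summary-statistic level; p-values are two-sided normal tail areas and
  FDR is Benjamini–Hochberg within each contrast;
* body lengths are Normal per genotype, with "small" genotypes shifted down
  from the control mean by a planted Glass' delta times the control sd.

Defaults emulate the study's shape at desk scale: six chromosomes, 1000
genes, an asymmetric class mix with more B-exclusive than A-exclusive
targets and more B background peaks than A, strong planted effects
(|log2FC| = 2, sigma = 0.25) and peaks within 1 kb of the TSS, inside the
3 kb target window.  A pool of *non-functional co-bound pairs* (an A and a
B peak sharing a locus with no regulated gene planted nearby) reproduces
the study's peak-level geometry, in which most A peaks overlap B peaks
while the large majority of co-occupied sites are not associated with any
expression change, and most B peaks remain independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cotarget.io_core import DEGRecord, GeneModel, GenomeBuild, Peak, PeakSetPair
from cotarget.phenotype_screen import PhenotypeGroup
from cotarget.seeds import derive_seed


class RegulatoryClass(str, Enum):
    CO_ACTIVATED = "co_activated"
    ANTAGONISTIC = "antagonistic"
    A_EXCLUSIVE_ACTIVATED = "a_exclusive_activated"
    B_EXCLUSIVE_ACTIVATED = "b_exclusive_activated"
    B_EXCLUSIVE_REPRESSED = "b_exclusive_repressed"
    # value deliberately not the literal "null", which pandas would parse
    # back from a TSV as NaN
    NULL = "unregulated"


#: classes whose genes receive a planted A peak / B peak
_HAS_A_PEAK = {
    RegulatoryClass.CO_ACTIVATED,
    RegulatoryClass.ANTAGONISTIC,
    RegulatoryClass.A_EXCLUSIVE_ACTIVATED,
}
_HAS_B_PEAK = {
    RegulatoryClass.CO_ACTIVATED,
    RegulatoryClass.ANTAGONISTIC,
    RegulatoryClass.B_EXCLUSIVE_ACTIVATED,
    RegulatoryClass.B_EXCLUSIVE_REPRESSED,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the generator.  ``seed`` is mandatory; every stage
    derives its own sub-seed from it."""

    seed: int
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "chrI": 3_000_000, "chrII": 3_000_000, "chrIII": 3_000_000,
            "chrIV": 3_000_000, "chrV": 3_000_000, "chrX": 3_000_000,
        }
    )
    n_genes: int = 1000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            RegulatoryClass.CO_ACTIVATED.value: 0.10,
            RegulatoryClass.ANTAGONISTIC.value: 0.02,
            RegulatoryClass.A_EXCLUSIVE_ACTIVATED.value: 0.12,
            RegulatoryClass.B_EXCLUSIVE_ACTIVATED.value: 0.10,
            RegulatoryClass.B_EXCLUSIVE_REPRESSED.value: 0.14,
            RegulatoryClass.NULL.value: 0.52,
        }
    )
    effect_size: float = 2.0          # |true log2FC| for regulated genes
    sigma: float = 0.25               # per-contrast log2FC standard error
    window: int = 3000                # TSS target window d (bp)
    tss_jitter: int = 1000            # planted peak centroid within this of TSS
    co_bound_offset: int = 50         # max centroid offset of a co-bound pair
    background_a: int = 100           # independent background peaks, set A
    background_b: int = 700           # independent background peaks, set B
    background_co_bound: int = 400    # non-functional co-bound A/B pair count
    peak_width_min: int = 200
    peak_width_max: int = 400

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.tss_jitter >= self.window:
            raise ValueError("tss_jitter must be < window")
        if not 0 < self.peak_width_min <= self.peak_width_max:
            raise ValueError("invalid peak width range")
        if self.co_bound_offset >= self.peak_width_min:
            raise ValueError("co_bound_offset must be < min peak width "
                             "(overlap guarantee)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class TruthTable:
    """gene id -> (class, true log2FC in contrast A, in contrast B)."""

    classes: Mapping[str, RegulatoryClass]
    beta_a: Mapping[str, float]
    beta_b: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.classes)
        return pd.DataFrame(
            {
                "class": [self.classes[g].value for g in ids],
                "beta_a": [self.beta_a[g] for g in ids],
                "beta_b": [self.beta_b[g] for g in ids],
            },
            index=pd.Index(ids, name="gene_id"),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeBuild, list[GeneModel]]:
    """Uniform gene placement with minimum inter-TSS spacing 2 * window.

    Genes are allotted to chromosomes proportionally to length, then placed
    by the spacing transform: sorted uniforms over the slack plus fixed
    gaps, which is uniform conditional on all gaps >= 2 * window.  Raises
    ``ValueError`` if the requested genes cannot fit the spacing.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    genome = GenomeBuild(dict(config.chrom_lengths))
    chroms = genome.chromosomes
    lengths = np.asarray([genome[c] for c in chroms], dtype=float)

    # largest-remainder apportionment of genes to chromosomes
    quota = config.n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: config.n_genes - counts.sum()]:
        counts[i] += 1

    gap = 2 * config.window
    genes: list[GeneModel] = []
    gidx = 0
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        L = genome[chrom]
        slack = (L - 1) - (n - 1) * gap
        if slack < 0:
            raise ValueError(
                f"cannot place {n} genes with spacing {gap} on {chrom} ({L} bp)"
            )
        u = np.sort(rng.uniform(0, slack, size=n))
        tss = (u + gap * np.arange(n)).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n)
        for t, s in zip(tss, strands):
            gidx += 1
            genes.append(GeneModel(f"g{gidx:04d}", chrom, str(s), int(t)))
    return genome, genes


def assign_truth(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> TruthTable:
    """Assign each gene one regulatory class (largest-remainder counts from
    the configured proportions, randomly permuted over genes) and the
    implied true log2FC signs."""
    rng = np.random.default_rng(derive_seed(config.seed, "truth"))
    n = len(genes)
    names = list(config.class_proportions)
    quota = np.asarray([config.class_proportions[c] * n for c in names])
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n - counts.sum()]:
        counts[i] += 1

    labels: list[RegulatoryClass] = []
    for name, count in zip(names, counts):
        labels.extend([RegulatoryClass(name)] * int(count))
    labels = [labels[i] for i in rng.permutation(n)]

    b = config.effect_size
    classes, beta_a, beta_b = {}, {}, {}
    for gene, cls in zip(genes, labels):
        gid = gene.gene_id
        classes[gid] = cls
        if cls is RegulatoryClass.CO_ACTIVATED:
            beta_a[gid], beta_b[gid] = -b, -b
        elif cls is RegulatoryClass.ANTAGONISTIC:
            beta_a[gid], beta_b[gid] = -b, +b
        elif cls is RegulatoryClass.A_EXCLUSIVE_ACTIVATED:
            beta_a[gid], beta_b[gid] = -b, 0.0
        elif cls is RegulatoryClass.B_EXCLUSIVE_ACTIVATED:
            beta_a[gid], beta_b[gid] = 0.0, -b
        elif cls is RegulatoryClass.B_EXCLUSIVE_REPRESSED:
            beta_a[gid], beta_b[gid] = 0.0, +b
        else:
            beta_a[gid], beta_b[gid] = 0.0, 0.0
    return TruthTable(classes, beta_a, beta_b)


def _peak_at(chrom: str, center: int, width: int, L: int, name: str) -> Peak:
    start = center - (width - 1) // 2
    start = max(0, min(start, L - width))
    return Peak(chrom, start, start + width, name=name)


def generate_peaks(
    truth: TruthTable,
    genes: Sequence[GeneModel],
    genome: GenomeBuild,
    config: SimulationConfig,
) -> PeakSetPair:
    """Planted peaks near regulated genes' TSSs plus uniform background.

    Co-bound genes get an A and a B peak whose centroids differ by at most
    the co-bound offset; since the offset is smaller than the minimum peak
    width the pair overlaps by construction.  Exclusive genes get one
    factor's peak.  Background peaks are uniform over chromosomes
    (length-weighted) and independent between the two sets.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "peaks"))
    missing = [g.gene_id for g in genes if g.gene_id not in truth.classes]
    if missing:
        raise ValueError(f"genes absent from truth table: {missing[:5]}")

    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    jitter = config.tss_jitter - config.co_bound_offset  # keep both in window

    def width() -> int:
        return int(rng.integers(config.peak_width_min, config.peak_width_max + 1))

    for g in genes:
        cls = truth.classes[g.gene_id]
        if cls is RegulatoryClass.NULL:
            continue
        L = genome[g.chrom]
        center = g.tss + int(rng.integers(-jitter, jitter + 1))
        center = max(0, min(center, L - 1))
        if cls in _HAS_A_PEAK:
            peaks_a.append(_peak_at(g.chrom, center, width(), L,
                                    f"{g.gene_id}:A"))
        if cls in _HAS_B_PEAK:
            off = int(rng.integers(-config.co_bound_offset,
                                   config.co_bound_offset + 1))
            b_center = center + off if cls in _HAS_A_PEAK else center
            b_center = max(0, min(b_center, L - 1))
            peaks_b.append(_peak_at(g.chrom, b_center, width(), L,
                                    f"{g.gene_id}:B"))

    chroms = genome.chromosomes
    probs = np.asarray([genome[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    for label, count, sink in (("bgA", config.background_a, peaks_a),
                               ("bgB", config.background_b, peaks_b)):
        picks = rng.choice(len(chroms), size=count, p=probs)
        for i, ci in enumerate(picks):
            chrom = chroms[ci]
            w = width()
            start = int(rng.integers(0, genome[chrom] - w + 1))
            sink.append(Peak(chrom, start, start + w, name=f"{label}_{i:05d}"))

    # non-functional co-bound pairs: A and B peaks sharing a locus without a
    # nearby regulated gene in truth (may collide with gene windows by
    # chance; such collisions are a documented property of the null)
    picks = rng.choice(len(chroms), size=config.background_co_bound, p=probs)
    for i, ci in enumerate(picks):
        chrom = chroms[ci]
        L = genome[chrom]
        center = int(rng.integers(0, L))
        peaks_a.append(_peak_at(chrom, center, width(), L, f"bgAB_{i:05d}:A"))
        off = int(rng.integers(-config.co_bound_offset,
                               config.co_bound_offset + 1))
        b_center = max(0, min(center + off, L - 1))
        peaks_b.append(_peak_at(chrom, b_center, width(), L,
                                f"bgAB_{i:05d}:B"))

    return PeakSetPair(tuple(peaks_a), tuple(peaks_b), genome)


def generate_deg_tables(
    truth: TruthTable,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[dict[str, DEGRecord], dict[str, DEGRecord]]:
    """Summary-statistic DEG tables for the two contrasts.

    Per gene and contrast: observed log2FC ~ Normal(true beta, sigma),
    p = 2 * Phi(-|obs| / sigma), FDR by Benjamini–Hochberg over all genes
    in that contrast.
    """
    if config.sigma <= 0:
        raise ValueError("sigma must be > 0")
    if seed is None:
        seed = derive_seed(config.seed, "deg")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(truth.classes)
    out = []
    for betas in (truth.beta_a, truth.beta_b):
        beta = np.asarray([betas[g] for g in gene_ids])
        obs = beta + rng.normal(0.0, config.sigma, size=beta.size)
        p = 2.0 * stats.norm.sf(np.abs(obs) / config.sigma)
        fdr = multipletests(p, method="fdr_bh")[1]
        out.append(
            {
                g: DEGRecord(g, float(fc), float(pv), float(q))
                for g, fc, pv, q in zip(gene_ids, obs, p, fdr)
            }
        )
    return out[0], out[1]


def generate_body_lengths(
    delta_true: Mapping[str, float],
    config: SimulationConfig,
    seed: int | None = None,
    control_label: str = "control",
    n_per_group: int = 50,
    mu_control: float = 1000.0,
    sd: float = 50.0,
    background: str = "wild-type",
) -> list[PhenotypeGroup]:
    """Per-genotype body lengths (microns) ~ Normal(mu_g, sd).

    ``delta_true`` maps each test genotype to its planted Glass' delta;
    "small" genotypes have mu_g = mu_control - delta_true * sd.  A control
    group is always included.  Raises ``ValueError`` when n per group < 2.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if seed is None:
        seed = derive_seed(config.seed, "phenotype")
    rng = np.random.default_rng(seed)
    groups = [
        PhenotypeGroup(
            label=control_label,
            lengths=rng.normal(mu_control, sd, size=n_per_group),
            background=background,
        )
    ]
    for label in sorted(delta_true):
        mu = mu_control - delta_true[label] * sd
        groups.append(
            PhenotypeGroup(
                label=label,
                lengths=rng.normal(mu, sd, size=n_per_group),
                background=background,
            )
        )
    return groups
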
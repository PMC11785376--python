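"""Direct-target inference from one peak set plus one DEG contrast, and
conditional-FDR overlap of two contrasts.

Direct-target calling integrates binding and expression in the style of
binding-and-expression target analysis ("BETA basic"):

* each gene receives a **regulatory potential** ``S_g = sum_k
  exp(-(0.5 + 4 * delta_k))`` over peaks whose centroid lies within the TSS
  window ``d`` (``delta_k = |centroid_k - TSS| / d <= 1``).  The
  exponential distance decay is the published form used by that method; a
  flat (no-decay) kernel is available for sensitivity checks.
* genes are ranked on binding (``S_g`` descending) and on expression (FDR
  ascending, ties by |log2FC| descending then gene id) and scored by the
  **rank product** ``RP = (r_S / n) * (r_E / n)`` — smaller is stronger.
* a gene is *called* a direct target iff its contrast FDR passes the cutoff
  (default 0.05) AND at least one peak lies within the window.  Direction
  comes from the mutant-contrast log2FC sign: a target down-regulated in
  the mutant is activated by the factor.

A one-tailed Kolmogorov–Smirnov function test asks whether up-regulated
(and separately down-regulated) DEGs have systematically better (smaller)
rank products than non-DEG background genes, yielding an
activator/repressor/both/neither verdict.

The conditional-overlap procedure ("LOA-style") avoids the double-cutoff
underestimate when intersecting two DEG lists: the second contrast's genes
are partitioned by the first contrast's DEG status, Benjamini–Hochberg
adjustment is recomputed *within each partition* from the second contrast's
raw p-values, and shared DEGs are first-contrast DEGs whose
partition-conditional adjusted value passes the same cutoff (default 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from cotarget.io_core import DEGRecord, GeneModel, Peak
from cotarget.peak_geometry import centroid


@dataclass(frozen=True)
class TargetScore:
    """Per-gene binding/expression integration score."""

    gene_id: str
    regulatory_potential: float
    peak_count: int
    binding_rank: float      # r_S / n, in (0, 1]
    expression_rank: float   # r_E / n, in (0, 1]
    rank_product: float      # RP = binding_rank * expression_rank


@dataclass(frozen=True)
class DirectTargetCall:
    """Verdict for one gene: called iff DEG at the configured FDR cutoff and
    >= 1 peak within the TSS window."""

    gene_id: str
    called: bool
    direction: Literal["activated-by-factor", "repressed-by-factor", "none"]
    score: TargetScore
    log2fc: float
    fdr: float


@dataclass(frozen=True)
class FunctionTestResult:
    """One-tailed KS comparison of DEG rank products vs background."""

    d_up: float
    p_up: float
    n_up: int
    d_down: float
    p_down: float
    n_down: int
    n_background: int
    verdict: Literal["activator", "repressor", "both", "neither"]
    alpha: float


def regulatory_potential(
    gene: GeneModel,
    peaks: Sequence[Peak],
    window: int = 3000,
    decay: bool = True,
) -> tuple[float, int]:
    """Distance-decayed binding score of ``gene`` and the count of peaks
    within the window.

    Each peak with centroid within ``window`` bp of the TSS contributes
    ``exp(-(0.5 + 4 * delta))`` with ``delta = |centroid - TSS| / window``
    (or a flat 1.0 when ``decay`` is off).  Peaks on other chromosomes or
    beyond the window contribute nothing.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    score = 0.0
    count = 0
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        delta = abs(centroid(p) - gene.tss) / window
        if delta > 1.0:
            continue
        count += 1
        score += math.exp(-(0.5 + 4.0 * delta)) if decay else 1.0
    return score, count


def _peaks_by_chrom(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, list[Peak]]]:
    by: dict[str, list[Peak]] = {}
    for p in peaks:
        by.setdefault(p.chrom, []).append(p)
    out = {}
    for chrom, plist in by.items():
        plist.sort(key=lambda p: (centroid(p), p.start))
        out[chrom] = (np.asarray([centroid(p) for p in plist]), plist)
    return out


def peaks_near_tss(
    gene: GeneModel,
    indexed: Mapping[str, tuple[np.ndarray, list[Peak]]],
    window: int,
) -> list[Peak]:
    """Peaks whose centroid lies within ``window`` bp of the gene's TSS."""
    entry = indexed.get(gene.chrom)
    if entry is None:
        return []
    cents, plist = entry
    lo = int(np.searchsorted(cents, gene.tss - window, side="left"))
    hi = int(np.searchsorted(cents, gene.tss + window, side="right"))
    return plist[lo:hi]


def call_direct_targets(
    deg: Mapping[str, DEGRecord],
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = 3000,
    deg_fdr: float = 0.05,
    decay: bool = True,
) -> list[DirectTargetCall]:
    """Integrate one factor's peaks with one mutant contrast.

    Returns one call per annotated gene, ordered by rank product ascending
    (best first).  Genes absent from the DEG table are treated as measured
    non-DEGs only if absent — here every annotated gene must have a DEG
    record, mirroring a complete contrast table.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    missing = [g.gene_id for g in genes if g.gene_id not in deg]
    if missing:
        raise ValueError(
            f"{len(missing)} annotated genes missing from the DEG table "
            f"(first: {missing[:5]})"
        )
    n = len(genes)
    indexed = _peaks_by_chrom(peaks)

    rows = []
    for g in genes:
        near = peaks_near_tss(g, indexed, window)
        s_g, k = 0.0, 0
        for p in near:
            delta = abs(centroid(p) - g.tss) / window
            if delta <= 1.0:
                k += 1
                s_g += math.exp(-(0.5 + 4.0 * delta)) if decay else 1.0
        r = deg[g.gene_id]
        rows.append((g.gene_id, s_g, k, r.log2fc, r.pvalue, r.fdr))

    df = pd.DataFrame(
        rows, columns=["gene_id", "s_g", "peak_count", "log2fc", "pvalue", "fdr"]
    )
    # binding rank: S_g descending, ties by gene id (deterministic)
    df = df.sort_values(["s_g", "gene_id"], ascending=[False, True])
    df["r_s"] = np.arange(1, n + 1)
    # expression rank: FDR ascending, ties by |log2FC| descending then gene id
    df["abs_fc"] = df["log2fc"].abs()
    df = df.sort_values(["fdr", "abs_fc", "gene_id"], ascending=[True, False, True])
    df["r_e"] = np.arange(1, n + 1)
    df["rp"] = (df["r_s"] / n) * (df["r_e"] / n)

    df = df.sort_values(["rp", "gene_id"], ascending=[True, True])
    calls: list[DirectTargetCall] = []
    for row in df.itertuples():
        called = (row.fdr <= deg_fdr) and (row.peak_count >= 1)
        if not called:
            direction = "none"
        elif row.log2fc < 0:
            direction = "activated-by-factor"
        else:
            direction = "repressed-by-factor"
        calls.append(
            DirectTargetCall(
                gene_id=row.gene_id,
                called=called,
                direction=direction,
                score=TargetScore(
                    gene_id=row.gene_id,
                    regulatory_potential=float(row.s_g),
                    peak_count=int(row.peak_count),
                    binding_rank=float(row.r_s) / n,
                    expression_rank=float(row.r_e) / n,
                    rank_product=float(row.rp),
                ),
                log2fc=float(row.log2fc),
                fdr=float(row.fdr),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[DirectTargetCall]) -> pd.DataFrame:
    """Flat per-gene table (gene_id, s_g, peak_count, rp, called, direction,
    log2fc, fdr) in call order."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "s_g": [c.score.regulatory_potential for c in calls],
            "peak_count": [c.score.peak_count for c in calls],
            "rp": [c.score.rank_product for c in calls],
            "called": [c.called for c in calls],
            "direction": [c.direction for c in calls],
            "log2fc": [c.log2fc for c in calls],
            "fdr": [c.fdr for c in calls],
        }
    )


def _ks_one_sided(target: np.ndarray, background: np.ndarray) -> tuple[float, float]:
    """One-tailed KS: D = max over x of (ECDF_target(x) - ECDF_background(x)),
    i.e. evidence that targets are skewed toward smaller values; p by the
    one-sided asymptotic formula exp(-2*m*n/(m+n) * D^2)."""
    m, n = target.size, background.size
    grid = np.concatenate([target, background])
    grid.sort(kind="stable")
    ecdf_t = np.searchsorted(np.sort(target), grid, side="right") / m
    ecdf_b = np.searchsorted(np.sort(background), grid, side="right") / n
    d = float(np.max(ecdf_t - ecdf_b))
    d = max(d, 0.0)
    p = math.exp(-2.0 * m * n / (m + n) * d * d)
    return d, min(p, 1.0)


def ks_function_test(
    calls: Sequence[DirectTargetCall],
    deg: Mapping[str, DEGRecord],
    alpha: float = 0.05,
    deg_fdr: float = 0.05,
    min_set_size: int = 5,
) -> FunctionTestResult:
    """Does the factor activate, repress, both, or neither?

    Compares rank products of up-regulated DEGs, and separately of
    down-regulated DEGs, against non-DEG background genes, one-tailed
    alternative "target set skewed toward smaller RP".  Down-regulated DEGs
    skewed toward strong binding indicate activation by the factor (the
    mutant lost it), up-regulated ones indicate repression.
    """
    rp = {c.gene_id: c.score.rank_product for c in calls}
    up, down, bg = [], [], []
    for gene_id, r in deg.items():
        if gene_id not in rp:
            continue
        if r.fdr <= deg_fdr:
            (up if r.log2fc > 0 else down).append(rp[gene_id])
        else:
            bg.append(rp[gene_id])
    for label, vals in (("up-regulated", up), ("down-regulated", down),
                        ("background", bg)):
        if len(vals) < min_set_size:
            raise ValueError(
                f"{label} set too small for the KS test "
                f"({len(vals)} < {min_set_size})"
            )
    bg_arr = np.asarray(bg)
    d_up, p_up = _ks_one_sided(np.asarray(up), bg_arr)
    d_down, p_down = _ks_one_sided(np.asarray(down), bg_arr)
    act = p_down <= alpha
    rep = p_up <= alpha
    verdict = ("both" if act and rep else
               "activator" if act else
               "repressor" if rep else "neither")
    return FunctionTestResult(
        d_up=d_up, p_up=p_up, n_up=len(up),
        d_down=d_down, p_down=p_down, n_down=len(down),
        n_background=len(bg), verdict=verdict, alpha=alpha,
    )


def loa_conditional_overlap(
    deg_a: Mapping[str, DEGRecord],
    deg_b: Mapping[str, DEGRecord],
    loa_fdr: float = 0.01,
) -> pd.DataFrame:
    """Shared DEGs between two contrasts by conditional FDR re-adjustment.

    Genes of contrast B are split into two partitions by contrast A's DEG
    status at ``loa_fdr``; Benjamini–Hochberg adjustment is recomputed from
    B's raw p-values within each partition; shared DEGs are A-DEGs whose
    partition-conditional adjusted value is <= ``loa_fdr``.

    Returns a DataFrame indexed by gene id with columns log2fc_a, fdr_a,
    log2fc_b, pvalue_b, cond_fdr_b, shared (bool), sorted by gene id.
    Raises ``ValueError`` when the two gene universes differ.
    """
    genes_a, genes_b = set(deg_a), set(deg_b)
    if genes_a != genes_b:
        only_a = sorted(genes_a - genes_b)[:5]
        only_b = sorted(genes_b - genes_a)[:5]
        raise ValueError(
            f"gene universes differ: only-in-A {only_a}, only-in-B {only_b}"
        )
    gene_ids = sorted(genes_a)
    fdr_a = np.asarray([deg_a[g].fdr for g in gene_ids])
    p_b = np.asarray([deg_b[g].pvalue for g in gene_ids])

    in_a = fdr_a <= loa_fdr
    cond_fdr = np.empty_like(p_b)
    for mask in (in_a, ~in_a):
        if mask.any():
            cond_fdr[mask] = multipletests(p_b[mask], method="fdr_bh")[1]

    df = pd.DataFrame(
        {
            "log2fc_a": [deg_a[g].log2fc for g in gene_ids],
            "fdr_a": fdr_a,
            "log2fc_b": [deg_b[g].log2fc for g in gene_ids],
            "pvalue_b": p_b,
            "cond_fdr_b": cond_fdr,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    df["shared"] = in_a & (df["cond_fdr_b"] <= loa_fdr)
    return df
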
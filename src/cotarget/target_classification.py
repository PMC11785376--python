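"""Combine two factors' direct-target calls into regulatory categories, and
screen peaks against high-occupancy target (HOT) regions.

Category semantics
------------------
A gene is **co-regulated** when (1) it is in the shared DEG set produced by
the conditional-overlap procedure AND (2) an A peak and a B peak near its
TSS (within the target window) overlap each other by at least one base.
Co-regulated genes split into same-sign (both contrasts move the same way)
and antagonistic (opposite log2FC signs).  A gene called for factor A but
not co-regulated is **A-exclusive**; likewise for B, with B-exclusive genes
further split by the B contrast's direction (down-regulated in the mutant
=> activated by the factor).

These definitions make the bookkeeping identities exact:

* |A-exclusive| + |co-regulated| = |A direct-target total|
* |B-exclusive activated| + |B-exclusive repressed| = |B-exclusive|
* |co-regulated same-sign| + |co-regulated antagonistic| = |co-regulated|

HOT regions
-----------
Genomic compendia of many factors' ChIP peaks contain regions bound by a
large number of distinct factors ("HOT" sites, threshold 15 by default),
often interpreted as non-specific.  ``call_hot_regions`` sweeps all peak
boundaries counting *distinct factors* covering each base and merges the
maximal intervals at or above threshold; ``hot_overlap_fraction`` reports
what fraction of a query peak set touches any HOT region.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from cotarget.io_core import GeneModel, Peak, PeakSetPair
from cotarget.target_inference import DirectTargetCall, _peaks_by_chrom, peaks_near_tss


class TargetCategory(str, Enum):
    CO_REGULATED_SAME_SIGN = "co_regulated_same_sign"
    CO_REGULATED_ANTAGONISTIC = "co_regulated_antagonistic"
    A_EXCLUSIVE = "a_exclusive"
    B_EXCLUSIVE_ACTIVATED = "b_exclusive_activated"
    B_EXCLUSIVE_REPRESSED = "b_exclusive_repressed"
    NONE = "none"


@dataclass(frozen=True)
class TargetCategoryTable:
    """Per-gene category assignments plus the derived count table."""

    table: pd.DataFrame  # index gene_id; columns category, called_a, called_b,
                         # shared_deg, peaks_overlap, log2fc_a, log2fc_b

    @property
    def counts(self) -> dict[str, int]:
        cat = self.table["category"]
        n = {c.value: int((cat == c.value).sum()) for c in TargetCategory}
        co = (n[TargetCategory.CO_REGULATED_SAME_SIGN.value]
              + n[TargetCategory.CO_REGULATED_ANTAGONISTIC.value])
        b_excl = (n[TargetCategory.B_EXCLUSIVE_ACTIVATED.value]
                  + n[TargetCategory.B_EXCLUSIVE_REPRESSED.value])
        return {
            **n,
            "co_regulated": co,
            "b_exclusive": b_excl,
            "a_total": n[TargetCategory.A_EXCLUSIVE.value] + co,
            "b_total": b_excl + co,
        }


def _overlapping_pair_near_tss(
    gene: GeneModel,
    indexed_a: Mapping,
    indexed_b: Mapping,
    window: int,
) -> bool:
    """Does any A peak within the gene's window overlap any B peak within it?"""
    near_a = peaks_near_tss(gene, indexed_a, window)
    near_b = peaks_near_tss(gene, indexed_b, window)
    for pa in near_a:
        for pb in near_b:
            if pa.start < pb.end and pb.start < pa.end:
                return True
    return False


def classify_targets(
    calls_a: Sequence[DirectTargetCall],
    calls_b: Sequence[DirectTargetCall],
    shared: pd.DataFrame,
    pair: PeakSetPair,
    genes: Sequence[GeneModel],
    window: int = 3000,
) -> TargetCategoryTable:
    """Assign every annotated gene one regulatory category.

    ``shared`` is the conditional-overlap output (indexed by gene id, with a
    boolean ``shared`` column and both contrasts' log2FC).  Raises
    ``ValueError`` on inconsistent gene universes.
    """
    ids_a = {c.gene_id for c in calls_a}
    ids_b = {c.gene_id for c in calls_b}
    ids_g = {g.gene_id for g in genes}
    if not (ids_a == ids_b == ids_g == set(shared.index)):
        raise ValueError("gene universes of calls, annotation and shared "
                         "DEG table are inconsistent")

    called_a = {c.gene_id for c in calls_a if c.called}
    called_b = {c.gene_id for c in calls_b if c.called}
    dir_b = {c.gene_id: c.direction for c in calls_b}
    indexed_a = _peaks_by_chrom(list(pair.peaks_a))
    indexed_b = _peaks_by_chrom(list(pair.peaks_b))

    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        gid = g.gene_id
        is_shared = bool(shared.loc[gid, "shared"])
        fc_a = float(shared.loc[gid, "log2fc_a"])
        fc_b = float(shared.loc[gid, "log2fc_b"])
        overlap = (
            _overlapping_pair_near_tss(g, indexed_a, indexed_b, window)
            if is_shared else False
        )
        if is_shared and overlap:
            if fc_a * fc_b > 0:
                category = TargetCategory.CO_REGULATED_SAME_SIGN
            else:
                category = TargetCategory.CO_REGULATED_ANTAGONISTIC
        elif gid in called_a:
            category = TargetCategory.A_EXCLUSIVE
        elif gid in called_b:
            if dir_b[gid] == "activated-by-factor":
                category = TargetCategory.B_EXCLUSIVE_ACTIVATED
            else:
                category = TargetCategory.B_EXCLUSIVE_REPRESSED
        else:
            category = TargetCategory.NONE
        rows.append(
            (gid, category.value, gid in called_a, gid in called_b,
             is_shared, overlap, fc_a, fc_b)
        )

    table = pd.DataFrame(
        rows,
        columns=["gene_id", "category", "called_a", "called_b",
                 "shared_deg", "peaks_overlap", "log2fc_a", "log2fc_b"],
    ).set_index("gene_id")
    return TargetCategoryTable(table)


# ---------------------------------------------------------------------------
# HOT regions


@dataclass(frozen=True)
class HotRegion:
    chrom: str
    start: int
    end: int
    max_factors: int


@dataclass(frozen=True)
class HotRegionSet:
    """Merged maximal intervals covered by >= threshold distinct factors."""

    regions: tuple[HotRegion, ...]
    threshold: int

    def __len__(self) -> int:
        return len(self.regions)


def _merge_factor(peaks: Sequence[Peak]) -> list[tuple[str, int, int]]:
    """Union a single factor's peaks so stacked peaks of one factor count
    once in the occupancy sweep (touching intervals may merge here: factor
    presence, not overlap, is what the sweep tracks)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def call_hot_regions(
    factor_peaks: Mapping[str, Sequence[Peak]],
    threshold: int = 15,
) -> HotRegionSet:
    """Sweep-line occupancy over all factors' merged peaks.

    Returns maximal merged intervals where the count of distinct factors
    with a covering peak is >= ``threshold``.  Invariant to the order in
    which factor collections are supplied.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if not factor_peaks:
        raise ValueError("at least one factor collection is required")

    events: dict[str, list[tuple[int, int]]] = {}  # pos, +1/-1
    for factor in sorted(factor_peaks):
        for chrom, s, e in _merge_factor(factor_peaks[factor]):
            events.setdefault(chrom, []).append((s, +1))
            events[chrom].append((e, -1))

    regions: list[HotRegion] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        run_start: int | None = None
        run_max = 0
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= threshold and run_start is None:
                run_start = pos
                run_max = depth
            elif run_start is not None:
                if depth >= threshold:
                    run_max = max(run_max, depth)
                else:
                    regions.append(HotRegion(chrom, run_start, pos, run_max))
                    run_start = None
    return HotRegionSet(tuple(regions), threshold)


def hot_overlap_fraction(
    query: Sequence[Peak], hot: HotRegionSet
) -> float:
    """Fraction of query peaks sharing >= 1 bp with any HOT region."""
    if not query:
        raise ValueError("empty query peak set")
    by_chrom: dict[str, list[HotRegion]] = {}
    for r in hot.regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    n_hit = 0
    for p in query:
        for r in by_chrom.get(p.chrom, ()):
            if p.start < r.end and r.start < p.end:
                n_hit += 1
                break
    return n_hit / len(query)
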
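"""Peak co-occupancy geometry.

Two factors that bind DNA as a complex (or in tight adjacency) leave peak
sets whose centroids sit much closer to each other than chance placement
would put them.  This module quantifies that:

* every peak is reduced to its **centroid**, the midpoint between its two
  border coordinates (using the inclusive last base, so a peak [start, end)
  has centroid ``floor((start + end - 1) / 2)``);
* for each query peak the distance to the nearest centroid of the other
  factor's set *on the same chromosome* is recorded, pooled over
  chromosomes;
* a **randomization null** reassigns each peak to a uniform random position
  on its own chromosome (width and per-chromosome counts preserved) and
  recomputes the same distances;
* the ECDF midpoint (interpolated empirical median) and the fraction of
  distances under a threshold summarize each distribution;
* interval-overlap bookkeeping counts, per direction, how many peaks of one
  set share at least one base with the other set, plus the number of merged
  peak clusters containing both labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from cotarget.io_core import GenomeBuild, Peak, PeakSetPair, sort_peaks

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    """Which set supplies the query peaks in a nearest-neighbor scan."""

    A_TO_B = "A->B"
    B_TO_A = "B->A"


class PairingMode(str, Enum):
    """How query peaks are matched to target centroids.

    DIRECTIONAL: every query peak reports its nearest target centroid
    (a target centroid may be re-used).  GREEDY_MUTUAL: globally smallest
    distances are matched first and each peak participates in at most one
    pair, emulating picking the shortest entry out of a full distance
    matrix repeatedly.
    """

    DIRECTIONAL = "directional"
    GREEDY_MUTUAL = "greedy-mutual"


@dataclass(frozen=True)
class DistanceDistribution:
    """Pooled inter-centroid distances with provenance.

    ``provenance`` is ``"observed"`` or ``"randomized"``; randomized
    distributions also carry their replicate index and seed.
    """

    distances: np.ndarray
    provenance: str = "observed"
    replicate: int = 0
    seed: int | None = None
    skipped_queries: int = 0
    query_ids: tuple[str, ...] | None = None
    query_chroms: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.size and d.min() < 0:
            raise ValueError("inter-centroid distances must be non-negative")
        object.__setattr__(self, "distances", d)

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class OverlapSummary:
    """Directional overlap counts for a pair of peak sets.

    ``n_a_overlapping`` counts A peaks sharing >= 1 bp with any B peak (and
    vice versa); ``n_clusters_mixed`` counts merged peak clusters that
    contain at least one peak of each label.  Percentages derive exactly
    from the counts.
    """

    n_a: int
    n_b: int
    n_a_overlapping: int
    n_b_overlapping: int
    n_clusters_mixed: int

    def __post_init__(self) -> None:
        if self.n_a_overlapping > self.n_a or self.n_b_overlapping > self.n_b:
            raise ValueError("directional overlap count exceeds set size")
        if (self.n_clusters_mixed > self.n_a_overlapping
                or self.n_clusters_mixed > self.n_b_overlapping):
            raise ValueError("mixed-cluster count exceeds a directional count")

    @property
    def pct_a_overlapping(self) -> float:
        """Percent of A peaks overlapping B, reported to 0.1%."""
        return round(100.0 * self.n_a_overlapping / self.n_a, 1) if self.n_a else 0.0

    @property
    def pct_b_overlapping(self) -> float:
        return round(100.0 * self.n_b_overlapping / self.n_b, 1) if self.n_b else 0.0

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_a_overlapping": self.n_a_overlapping,
            "n_b_overlapping": self.n_b_overlapping,
            "n_clusters_mixed": self.n_clusters_mixed,
            "pct_a_overlapping": self.pct_a_overlapping,
            "pct_b_overlapping": self.pct_b_overlapping,
        }


def centroid(peak: Peak) -> int:
    """Midpoint between the two border coordinates, inclusive last base."""
    return (peak.start + peak.end - 1) // 2


def centroids_by_chrom(peaks: list[Peak]) -> dict[str, np.ndarray]:
    """Sorted centroid positions per chromosome (one centroid per peak)."""
    out: dict[str, list[int]] = {}
    for p in peaks:
        out.setdefault(p.chrom, []).append(centroid(p))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


def _nearest_distances(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """|query - nearest target| for sorted target; ties go to the leftmost
    target centroid (both candidates are equidistant, so the distance is
    unaffected)."""
    idx = np.searchsorted(target, query)
    left = np.clip(idx - 1, 0, target.size - 1)
    right = np.clip(idx, 0, target.size - 1)
    d_left = np.abs(query - target[left])
    d_right = np.abs(query - target[right])
    return np.minimum(d_left, d_right)


def nearest_neighbor_distances(
    pair: PeakSetPair,
    direction: Direction | str = Direction.A_TO_B,
    mode: PairingMode | str = PairingMode.DIRECTIONAL,
    provenance: str = "observed",
    replicate: int = 0,
    seed: int | None = None,
) -> DistanceDistribution:
    """Nearest-neighbor inter-centroid distances, pooled over chromosomes.

    For each query peak (set A under ``A->B``, set B under ``B->A``) the
    absolute bp distance to the nearest target-set centroid on the same
    chromosome is recorded.  Query peaks on chromosomes with no target
    centroid are skipped and counted.  Under ``GREEDY_MUTUAL`` pairing the
    smallest distances are matched first and each peak is used at most once;
    unmatched surplus peaks on a chromosome contribute nothing.

    Raises ``ValueError`` if the two sets share no chromosome.
    """
    direction = Direction(direction)
    mode = PairingMode(mode)
    if direction is Direction.A_TO_B:
        query_peaks, target_peaks = pair.peaks_a, pair.peaks_b
    else:
        query_peaks, target_peaks = pair.peaks_b, pair.peaks_a

    query_by_chrom: dict[str, list[Peak]] = {}
    for p in sort_peaks(list(query_peaks)):
        query_by_chrom.setdefault(p.chrom, []).append(p)
    target_by_chrom = centroids_by_chrom(list(target_peaks))

    shared = set(query_by_chrom) & set(target_by_chrom)
    if not shared:
        raise ValueError("no shared chromosome between query and target peak sets")

    skipped = sum(
        len(v) for c, v in query_by_chrom.items() if c not in shared
    )
    if skipped:
        logger.info(
            "%d query peaks skipped: chromosome has no target centroid", skipped
        )

    chunks: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    for chrom in sorted(shared):
        qpeaks = query_by_chrom[chrom]
        q = np.asarray([centroid(p) for p in qpeaks], dtype=np.int64)
        t = target_by_chrom[chrom]
        if mode is PairingMode.DIRECTIONAL:
            chunks.append(_nearest_distances(q, t))
            kept = range(len(qpeaks))
        else:
            d, kept = _greedy_mutual_distances(q, t)
            chunks.append(d)
        for i in kept:
            p = qpeaks[i]
            ids.append(p.name or f"{p.chrom}:{p.start}-{p.end}")
            chroms.append(chrom)
    distances = np.concatenate(chunks) if chunks else np.empty(0)
    return DistanceDistribution(
        distances=distances.astype(float),
        provenance=provenance,
        replicate=replicate,
        seed=seed,
        skipped_queries=skipped,
        query_ids=tuple(ids),
        query_chroms=tuple(chroms),
    )


def _greedy_mutual_distances(
    q: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Repeatedly take the globally smallest query-target distance on one
    chromosome, removing both partners.  O(n*m) — intended for the matrix
    reading of 'nearest neighboring pair', not for huge sets.  Returns the
    matched distances and the matched query indices, in matching order."""
    dm = np.abs(q[:, None].astype(float) - t[None, :].astype(float))
    out: list[float] = []
    kept: list[int] = []
    n_pairs = min(q.size, t.size)
    for _ in range(n_pairs):
        i, j = np.unravel_index(np.argmin(dm), dm.shape)
        out.append(dm[i, j])
        kept.append(int(i))
        dm[i, :] = np.inf
        dm[:, j] = np.inf
    return np.asarray(out), kept


def randomize_peaks(
    peaks: list[Peak], genome: GenomeBuild, seed: int
) -> list[Peak]:
    """Reassign each peak to a uniform random position on its own chromosome.

    Per-chromosome peak counts and every peak's width are preserved; the new
    start is drawn uniformly from [0, L - width].  Reproducible given seed.
    """
    rng = np.random.default_rng(seed)
    out: list[Peak] = []
    for p in sort_peaks(peaks):  # fixed iteration order => reproducible draws
        L = genome[p.chrom]
        if p.width > L:
            raise ValueError(
                f"peak width {p.width} exceeds chromosome {p.chrom} length {L}"
            )
        start = int(rng.integers(0, L - p.width + 1))
        out.append(Peak(p.chrom, start, start + p.width, name=p.name))
    return out


def ecdf_midpoint(dist: DistanceDistribution) -> float:
    """Linearly interpolated empirical median of the distances — the point
    at which half of the peak pairs fall."""
    if len(dist) == 0:
        raise ValueError("empty distance distribution")
    return float(np.median(dist.distances))


def fraction_within(dist: DistanceDistribution, threshold: float) -> float:
    """Proportion of distances <= threshold bp."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(dist) == 0:
        raise ValueError("empty distance distribution")
    return float(np.mean(dist.distances <= threshold))


# ---------------------------------------------------------------------------
# overlap classification


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted; touching intervals (a.end ==
    b.start) are NOT merged — adjacency is not overlap."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s < le:  # strict: half-open overlap requires shared base
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _overlap_flags(peaks: list[Peak], merged_by_chrom: dict) -> list[bool]:
    flags = []
    for p in peaks:
        merged = merged_by_chrom.get(p.chrom)
        if not merged:
            flags.append(False)
            continue
        starts = merged["starts"]
        ends = merged["ends"]
        # first merged interval with end > p.start; overlap iff its start < p.end
        i = int(np.searchsorted(ends, p.start, side="right"))
        flags.append(bool(i < starts.size and starts[i] < p.end))
    return flags


def _merged_lookup(peaks: list[Peak]) -> dict:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        m = _merge_intervals(ivs)
        out[chrom] = {
            "starts": np.asarray([s for s, _ in m]),
            "ends": np.asarray([e for _, e in m]),
        }
    return out


def overlap_flags(pair: PeakSetPair) -> tuple[list[bool], list[bool]]:
    """Per-peak flags: does this A (resp. B) peak share >= 1 bp with the
    other set?  Order follows pair.peaks_a / pair.peaks_b."""
    a, b = list(pair.peaks_a), list(pair.peaks_b)
    return (_overlap_flags(a, _merged_lookup(b)),
            _overlap_flags(b, _merged_lookup(a)))


def classify_overlap(pair: PeakSetPair) -> OverlapSummary:
    """Count overlapping vs independent peaks in each direction.

    Overlap means sharing >= 1 bp under half-open arithmetic (``A.start <
    B.end and B.start < A.end``).  Also reports the number of merged
    clusters (connected components of the union of both sets under the same
    overlap relation) containing both labels — a candidate single "shared"
    count when the directional counts differ.
    """
    a, b = list(pair.peaks_a), list(pair.peaks_b)
    flags_a, flags_b = overlap_flags(pair)
    n_a_overlapping = sum(flags_a)
    n_b_overlapping = sum(flags_b)

    # mixed clusters: sweep over both sets together
    events: dict[str, list[tuple[int, int, str]]] = {}
    for label, peaks in (("A", a), ("B", b)):
        for p in peaks:
            events.setdefault(p.chrom, []).append((p.start, p.end, label))
    n_mixed = 0
    for chrom, ivs in events.items():
        ivs.sort()
        cluster_end = -1
        labels: set[str] = set()
        for s, e, lab in ivs:
            if s >= cluster_end:  # new cluster
                if labels >= {"A", "B"}:
                    n_mixed += 1
                labels = set()
                cluster_end = e
            else:
                cluster_end = max(cluster_end, e)
            labels.add(lab)
        if labels >= {"A", "B"}:
            n_mixed += 1

    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_a_overlapping=n_a_overlapping,
        n_b_overlapping=n_b_overlapping,
        n_clusters_mixed=n_mixed,
    )
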
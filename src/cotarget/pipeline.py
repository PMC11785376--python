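"""End-to-end orchestration: simulate -> geometry -> targets -> conditional
overlap -> classification -> HOT -> phenotype screen.

Every stage writes its outputs under the run directory with stable
filenames, and a manifest (config snapshot, input digests, per-stage seeds
and row counts) is written last, so a run is reproducible from the manifest
alone.  Stage seeds derive from the master seed by indexed hashing
(:func:`cotarget.seeds.derive_seed`) — inserting a stage never shifts the
randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from cotarget import __version__
from cotarget.io_core import (
    PeakSetPair,
    read_bed,
    read_chrom_sizes,
    read_deg_table,
    read_gene_table,
    write_bed,
    write_chrom_sizes,
    write_deg_table,
    write_gene_table,
)
from cotarget.peak_geometry import (
    Direction,
    PairingMode,
    classify_overlap,
    ecdf_midpoint,
    fraction_within,
    nearest_neighbor_distances,
    overlap_flags,
    randomize_peaks,
)
from cotarget.phenotype_screen import (
    read_phenotype_table,
    run_screen,
    write_screen_table,
)
from cotarget.seeds import derive_seed
from cotarget.synthetic_data import (
    SimulationConfig,
    assign_truth,
    generate_body_lengths,
    generate_deg_tables,
    generate_genome,
    generate_peaks,
)
from cotarget.target_classification import (
    call_hot_regions,
    classify_targets,
    hot_overlap_fraction,
)
from cotarget.target_inference import (
    calls_to_frame,
    call_direct_targets,
    ks_function_test,
    loa_conditional_overlap,
)

logger = logging.getLogger("cotarget.pipeline")


@dataclass
class PipelineConfig:
    """All pipeline tunables.  Defaults are the analysis' operating point:
    3 kb TSS window, DEG FDR 0.05, conditional-overlap FDR 0.01, KS alpha
    0.05, HOT threshold 15 factors, one randomization replicate."""

    window: int = 3000
    deg_fdr: float = 0.05
    loa_fdr: float = 0.01
    ks_alpha: float = 0.05
    hot_threshold: int = 15
    randomization_replicates: int = 1
    pairing_mode: str = PairingMode.DIRECTIONAL.value
    seed: int = 0
    out_dir: str = "cotarget_out"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def add_input(self, label: str, path: Path) -> None:
        self.inputs[label] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_distances(dists, path: Path) -> None:
    rows = []
    for d in dists:
        ids = d.query_ids or [""] * len(d)
        chroms = d.query_chroms or [""] * len(d)
        for qid, chrom, dist in zip(ids, chroms, d.distances):
            rows.append((qid, chrom, int(dist), d.provenance, d.replicate))
    pd.DataFrame(
        rows,
        columns=["query_peak_id", "chrom", "distance_bp", "provenance",
                 "replicate"],
    ).to_csv(path, sep="\t", index=False)


def stage_simulate(sim: SimulationConfig, out_dir: Path) -> dict:
    """Generate the full synthetic input bundle and write it as the same
    flat files a real run would read."""
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_genome(sim)
    truth = assign_truth(genes, sim)
    pair = generate_peaks(truth, genes, genome, sim)
    deg_a, deg_b = generate_deg_tables(truth, sim)

    write_chrom_sizes(genome, out_dir / "chrom.sizes")
    write_gene_table(genes, out_dir / "genes.tsv")
    write_bed(pair.peaks_a, out_dir / "peaks_a.bed")
    write_bed(pair.peaks_b, out_dir / "peaks_b.bed")
    write_deg_table(deg_a, out_dir / "deg_a.tsv")
    write_deg_table(deg_b, out_dir / "deg_b.tsv")
    truth.write_tsv(out_dir / "truth.tsv")

    # body lengths: planted small genotypes + nulls, against one control
    delta_true = {f"small_{i}": 2.0 for i in range(1, 6)}
    delta_true.update({f"null_{i}": 0.0 for i in range(1, 6)})
    groups = generate_body_lengths(delta_true, sim)
    rows = []
    for g in groups:
        for i, length in enumerate(g.lengths):
            rows.append((g.label, g.background, f"rep{i % 3 + 1}", length))
    pd.DataFrame(
        rows, columns=["condition", "background", "replicate", "length_um"]
    ).to_csv(out_dir / "body_lengths.tsv", sep="\t", index=False,
             float_format="%.6g")

    return {
        "genome": genome, "genes": genes, "truth": truth, "pair": pair,
        "deg_a": deg_a, "deg_b": deg_b, "groups": groups,
    }


def stage_geometry(pair: PeakSetPair, config: PipelineConfig,
                   out_dir: Path) -> dict:
    """Observed + randomized nearest-neighbor distances, summary statistics
    and overlap classification."""
    observed = nearest_neighbor_distances(
        pair, Direction.A_TO_B, mode=config.pairing_mode
    )
    randomized = []
    for rep in range(config.randomization_replicates):
        seed = derive_seed(config.seed, f"randomize:{rep}")
        rpair = PeakSetPair(
            tuple(randomize_peaks(list(pair.peaks_a), pair.genome, seed)),
            tuple(randomize_peaks(list(pair.peaks_b), pair.genome,
                                  derive_seed(seed, "b"))),
            pair.genome,
        )
        randomized.append(
            nearest_neighbor_distances(
                rpair, Direction.A_TO_B, mode=config.pairing_mode,
                provenance="randomized", replicate=rep, seed=seed,
            )
        )
    overlap = classify_overlap(pair)

    flags_a, flags_b = overlap_flags(pair)
    for label, peaks, flags in (("a", pair.peaks_a, flags_a),
                                ("b", pair.peaks_b, flags_b)):
        with open(out_dir / f"overlap_flags_{label}.bed", "w",
                  encoding="utf-8") as fh:
            for p, flag in zip(peaks, flags):
                name = p.name or f"{p.chrom}:{p.start}-{p.end}"
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t"
                         f"{int(flag)}\n")

    _write_distances([observed, *randomized], out_dir / "distances.tsv")
    summary = {
        "observed_midpoint_bp": ecdf_midpoint(observed),
        "observed_fraction_within_100bp": fraction_within(observed, 100),
        "observed_fraction_within_500bp": fraction_within(observed, 500),
        "randomized_midpoint_bp": [ecdf_midpoint(d) for d in randomized],
        "randomization_seeds": [d.seed for d in randomized],
        "overlap": overlap.as_dict(),
    }
    _write_json(summary, out_dir / "overlap_summary.json")
    return {"observed": observed, "randomized": randomized,
            "overlap": overlap, "summary": summary}


def stage_targets(deg, pair_peaks, genes, config: PipelineConfig,
                  label: str, out_dir: Path) -> dict:
    calls = call_direct_targets(
        deg, pair_peaks, genes, window=config.window, deg_fdr=config.deg_fdr
    )
    frame = calls_to_frame(calls)
    frame.to_csv(out_dir / f"targets_{label}.tsv", sep="\t", index=False,
                 float_format="%.6g")
    try:
        ks = ks_function_test(calls, deg, alpha=config.ks_alpha,
                              deg_fdr=config.deg_fdr)
        _write_json(dataclasses.asdict(ks), out_dir / f"function_test_{label}.json")
    except ValueError as exc:
        logger.warning("[targets:%s] KS function test skipped: %s", label, exc)
        ks = None
    return {"calls": calls, "ks": ks}


def run_all(
    config: PipelineConfig,
    simulate: SimulationConfig | None = None,
    inputs: dict | None = None,
    hot_factor_dir: Path | None = None,
    phenotype_table: Path | None = None,
) -> RunManifest:
    """Execute the full pipeline and write all stage outputs.

    Either ``simulate`` (a SimulationConfig) or ``inputs`` (paths with keys
    chrom_sizes, peaks_a, peaks_b, genes, deg_a, deg_b) must be given.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.as_dict())

    if simulate is not None:
        logger.info("[simulate] generating synthetic inputs")
        sim_dir = out_dir / "simulated_inputs"
        bundle = stage_simulate(simulate, sim_dir)
        genome, genes = bundle["genome"], bundle["genes"]
        pair = bundle["pair"]
        deg_a, deg_b = bundle["deg_a"], bundle["deg_b"]
        phenotype_groups = bundle["groups"]
        manifest.seeds["simulate"] = simulate.seed
        for f in sorted(sim_dir.iterdir()):
            manifest.add_input(f"simulated:{f.name}", f)
    elif inputs is not None:
        logger.info("[load] reading user inputs")
        genome = read_chrom_sizes(inputs["chrom_sizes"])
        genes = read_gene_table(inputs["genes"], genome)
        pair = PeakSetPair(
            tuple(read_bed(inputs["peaks_a"], genome)),
            tuple(read_bed(inputs["peaks_b"], genome)),
            genome,
        )
        deg_a = read_deg_table(inputs["deg_a"])
        deg_b = read_deg_table(inputs["deg_b"])
        phenotype_groups = (
            read_phenotype_table(phenotype_table) if phenotype_table else None
        )
        for label, path in inputs.items():
            manifest.add_input(label, Path(path))
    else:
        raise ValueError("either simulate or inputs must be provided")

    manifest.row_counts.update(
        n_genes=len(genes), n_peaks_a=len(pair.peaks_a),
        n_peaks_b=len(pair.peaks_b),
    )

    logger.info("[geometry] nearest-neighbor distances and overlap")
    geo = stage_geometry(pair, config, out_dir)
    manifest.seeds["randomization"] = geo["summary"]["randomization_seeds"]

    logger.info("[targets] direct-target calling, factors A and B")
    tgt_a = stage_targets(deg_a, list(pair.peaks_a), genes, config, "a", out_dir)
    tgt_b = stage_targets(deg_b, list(pair.peaks_b), genes, config, "b", out_dir)
    manifest.row_counts["n_called_a"] = sum(c.called for c in tgt_a["calls"])
    manifest.row_counts["n_called_b"] = sum(c.called for c in tgt_b["calls"])

    logger.info("[loa] conditional DEG overlap")
    shared = loa_conditional_overlap(deg_a, deg_b, loa_fdr=config.loa_fdr)
    shared.to_csv(out_dir / "shared_degs.tsv", sep="\t", float_format="%.6g")
    manifest.row_counts["n_shared_degs"] = int(shared["shared"].sum())

    logger.info("[classify] regulatory categories")
    categories = classify_targets(
        tgt_a["calls"], tgt_b["calls"], shared, pair, genes,
        window=config.window,
    )
    categories.table.to_csv(out_dir / "categories.tsv", sep="\t",
                            float_format="%.6g")
    _write_json(categories.counts, out_dir / "category_counts.json")
    manifest.row_counts.update(categories.counts)

    if hot_factor_dir is not None:
        logger.info("[hot] HOT-region calling from %s", hot_factor_dir)
        factor_peaks = {
            bed.stem: read_bed(bed, genome)
            for bed in sorted(Path(hot_factor_dir).glob("*.bed"))
        }
        hot = call_hot_regions(factor_peaks, threshold=config.hot_threshold)
        with open(out_dir / "hot_regions.bed", "w", encoding="utf-8") as fh:
            for r in hot.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tHOT\t{r.max_factors}\n")
        hot_summary = {
            "n_hot_regions": len(hot),
            "threshold": hot.threshold,
            "fraction_a_in_hot": hot_overlap_fraction(list(pair.peaks_a), hot),
            "fraction_b_in_hot": hot_overlap_fraction(list(pair.peaks_b), hot),
        }
        _write_json(hot_summary, out_dir / "hot_summary.json")
        manifest.row_counts["n_hot_regions"] = len(hot)

    if phenotype_groups:
        logger.info("[screen] Glass' effect-size phenotype screen")
        results = run_screen(phenotype_groups, control_label="control")
        write_screen_table(results, out_dir / "screen.tsv")
        manifest.row_counts["n_screen_hits"] = sum(r.hit for r in results)

    manifest.write(out_dir / "manifest.json")
    logger.info("[done] outputs in %s", out_dir)
    return manifest
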
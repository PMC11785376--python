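import numpy as np
import pytest
from scipy import stats

from cotarget.peak_geometry import centroid
from cotarget.phenotype_screen import glass_delta
from cotarget.synthetic_data import (
    RegulatoryClass,
    SimulationConfig,
    TruthTable,
    assign_truth,
    generate_body_lengths,
    generate_deg_tables,
    generate_genome,
    generate_peaks,
)


def small_config(seed=1, **kw):
    defaults = dict(
        seed=seed,
        chrom_lengths={"chrI": 1_000_000},
        n_genes=50,
        background_a=0,
        background_b=0,
        background_co_bound=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="proportions"):
            small_config(class_proportions={"co_activated": 0.5})

    def test_jitter_must_be_inside_window(self):
        with pytest.raises(ValueError, match="jitter"):
            small_config(tss_jitter=3000, window=3000)

    def test_sigma_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            small_config(sigma=0.0)

    def test_co_bound_offset_below_min_width(self):
        with pytest.raises(ValueError, match="offset"):
            small_config(co_bound_offset=250, peak_width_min=200)


class TestGenerateGenome:
    def test_spacing_postcondition_exhaustive(self):
        config = small_config()
        _, genes = generate_genome(config)
        assert len(genes) == 50
        tss = [g.tss for g in genes]
        for i in range(len(tss)):
            for j in range(i + 1, len(tss)):
                assert abs(tss[i] - tss[j]) >= 2 * config.window

    def test_same_seed_identical(self):
        assert generate_genome(small_config()) == generate_genome(small_config())

    def test_overfull_chromosome_errors(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_genome(small_config(chrom_lengths={"chrI": 100_000}))


class TestGeneratePeaks:
    def test_co_bound_genes_get_overlapping_pair(self):
        config = small_config(
            n_genes=10,
            class_proportions={RegulatoryClass.CO_ACTIVATED.value: 1.0},
        )
        genome, genes = generate_genome(config)
        truth = assign_truth(genes, config)
        pair = generate_peaks(truth, genes, genome, config)
        assert len(pair.peaks_a) == len(pair.peaks_b) == 10
        by_gene_a = {p.name.split(":")[0]: p for p in pair.peaks_a}
        by_gene_b = {p.name.split(":")[0]: p for p in pair.peaks_b}
        for g in genes:
            pa, pb = by_gene_a[g.gene_id], by_gene_b[g.gene_id]
            assert pa.start < pb.end and pb.start < pa.end  # >= 1 shared bp
            assert abs(centroid(pa) - g.tss) <= config.tss_jitter
            assert abs(centroid(pa) - centroid(pb)) <= config.co_bound_offset

    def test_a_exclusive_only_yields_empty_b(self):
        config = small_config(
            n_genes=10,
            class_proportions={RegulatoryClass.A_EXCLUSIVE_ACTIVATED.value: 1.0},
        )
        genome, genes = generate_genome(config)
        truth = assign_truth(genes, config)
        pair = generate_peaks(truth, genes, genome, config)
        assert len(pair.peaks_a) == 10
        assert len(pair.peaks_b) == 0

    def test_planted_overlap_count_arithmetic(self):
        # overlapping A peaks = co-bound gene peaks + co-bound background
        config = small_config(
            seed=3,
            n_genes=40,
            class_proportions={
                RegulatoryClass.CO_ACTIVATED.value: 0.5,
                RegulatoryClass.A_EXCLUSIVE_ACTIVATED.value: 0.5,
            },
            background_co_bound=7,
        )
        genome, genes = generate_genome(config)
        truth = assign_truth(genes, config)
        pair = generate_peaks(truth, genes, genome, config)
        n_co = sum(
            1 for c in truth.classes.values()
            if c is RegulatoryClass.CO_ACTIVATED
        )
        assert len(pair.peaks_a) == 40 + 7
        from cotarget.peak_geometry import classify_overlap
        s = classify_overlap(pair)
        # exclusive peaks sit >= 2*window - 2*jitter apart from any B peak,
        # so the planted count is exact here
        assert s.n_a_overlapping == n_co + 7

    def test_determinism(self):
        config = small_config(n_genes=20, background_a=5, background_b=5,
                              background_co_bound=5)
        genome, genes = generate_genome(config)
        truth = assign_truth(genes, config)
        p1 = generate_peaks(truth, genes, genome, config)
        p2 = generate_peaks(truth, genes, genome, config)
        assert p1 == p2


class TestGenerateDEG:
    def test_null_pvalues_uniform(self):
        # beta = 0, sigma = 0.25: p ~ U(0,1) by construction of the 2-sided tail
        config = small_config()  # gene count irrelevant; truth built directly
        gene_ids = [f"g{i:04d}" for i in range(1000)]
        truth = TruthTable(
            {g: RegulatoryClass.NULL for g in gene_ids},
            {g: 0.0 for g in gene_ids},
            {g: 0.0 for g in gene_ids},
        )
        deg_a, _ = generate_deg_tables(truth, config, seed=11)
        pvals = np.asarray([deg_a[g].pvalue for g in gene_ids])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_effect_always_significant(self):
        # beta = -2, sigma = 0.25 => |z| >= 4 with probability ~ 1
        gene_ids = [f"g{i:04d}" for i in range(1000)]
        classes = {
            g: (RegulatoryClass.CO_ACTIVATED if i < 50 else RegulatoryClass.NULL)
            for i, g in enumerate(gene_ids)
        }
        beta = {g: (-2.0 if i < 50 else 0.0) for i, g in enumerate(gene_ids)}
        truth = TruthTable(classes, beta, beta)
        config = small_config()
        deg_a, _ = generate_deg_tables(truth, config, seed=13)
        for g in gene_ids[:50]:
            assert abs(deg_a[g].log2fc) / config.sigma >= 4
            assert deg_a[g].fdr <= 0.05

    def test_sign_structure_matches_truth_in_expectation(self):
        config = small_config(n_genes=20)
        genome, genes = generate_genome(config)
        truth = assign_truth(genes, config)
        R = 30
        obs_a = {g.gene_id: [] for g in genes}
        obs_b = {g.gene_id: [] for g in genes}
        for rep in range(R):
            da, db = generate_deg_tables(truth, config, seed=100 + rep)
            for g in genes:
                obs_a[g.gene_id].append(da[g.gene_id].log2fc)
                obs_b[g.gene_id].append(db[g.gene_id].log2fc)
        bound = 3 * config.sigma / np.sqrt(R)
        for g in genes:
            assert abs(np.mean(obs_a[g.gene_id]) - truth.beta_a[g.gene_id]) < bound
            assert abs(np.mean(obs_b[g.gene_id]) - truth.beta_b[g.gene_id]) < bound

    def test_zero_sigma_errors(self):
        with pytest.raises(ValueError):
            small_config(sigma=0.0)


class TestBodyLengths:
    def test_null_genotype_recovers_zero_delta(self):
        # sd(delta-hat) at n = 50 under delta_true = 0 is ~0.17, so per-seed
        # estimates stay inside a 3.5-sigma band and the 10-seed mean is
        # close to zero
        config = small_config()
        deltas = []
        for seed in range(10):
            groups = generate_body_lengths({"geno": 0.0}, config, seed=seed)
            control = next(g for g in groups if g.label == "control")
            test = next(g for g in groups if g.label == "geno")
            deltas.append(glass_delta(control, test))
        assert all(abs(d) < 0.6 for d in deltas)
        assert abs(np.mean(deltas)) < 0.2

    def test_planted_delta_recovered(self):
        # sd(delta-hat) at n = 50 under delta_true = 2 is ~0.25
        config = small_config()
        deltas = []
        for seed in range(10):
            groups = generate_body_lengths({"small": 2.0}, config, seed=seed)
            control = next(g for g in groups if g.label == "control")
            test = next(g for g in groups if g.label == "small")
            deltas.append(glass_delta(control, test))
        assert all(1.1 <= d <= 2.9 for d in deltas)
        assert 1.8 <= np.mean(deltas) <= 2.2

    def test_single_measurement_group_errors(self):
        with pytest.raises(ValueError):
            generate_body_lengths({"g": 1.0}, small_config(), n_per_group=1)

    def test_determinism(self):
        config = small_config()
        g1 = generate_body_lengths({"x": 1.0}, config)
        g2 = generate_body_lengths({"x": 1.0}, config)
        for a, b in zip(g1, g2):
            assert np.array_equal(a.lengths, b.lengths)


def test_truth_table_sign_structure():
    config = small_config(n_genes=50, class_proportions={
        RegulatoryClass.CO_ACTIVATED.value: 0.2,
        RegulatoryClass.ANTAGONISTIC.value: 0.2,
        RegulatoryClass.A_EXCLUSIVE_ACTIVATED.value: 0.2,
        RegulatoryClass.B_EXCLUSIVE_REPRESSED.value: 0.2,
        RegulatoryClass.NULL.value: 0.2,
    })
    genome, genes = generate_genome(config)
    truth = assign_truth(genes, config)
    for gid, cls in truth.classes.items():
        ba, bb = truth.beta_a[gid], truth.beta_b[gid]
        if cls is RegulatoryClass.CO_ACTIVATED:
            assert ba < 0 and bb < 0
        elif cls is RegulatoryClass.ANTAGONISTIC:
            assert ba < 0 and bb > 0
        elif cls is RegulatoryClass.A_EXCLUSIVE_ACTIVATED:
            assert ba < 0 and bb == 0
        elif cls is RegulatoryClass.B_EXCLUSIVE_REPRESSED:
            assert ba == 0 and bb > 0
        else:
            assert ba == 0 and bb == 0
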
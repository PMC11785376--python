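import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cotarget.io_core import DEGRecord, GenomeBuild, GeneModel, Peak
from cotarget.target_inference import (
    _ks_one_sided,
    call_direct_targets,
    ks_function_test,
    loa_conditional_overlap,
    regulatory_potential,
)


def peak_at_centroid(pos, chrom="chrI", width=101):
    start = pos - (width - 1) // 2
    return Peak(chrom, start, start + width)


GENE = GeneModel("g1", "chrI", "+", 50_000)


class TestRegulatoryPotential:
    def test_peak_at_tss(self):
        s, k = regulatory_potential(GENE, [peak_at_centroid(50_000)], 3000)
        assert s == pytest.approx(math.exp(-0.5))
        assert k == 1

    def test_peak_at_window_boundary(self):
        s, _ = regulatory_potential(GENE, [peak_at_centroid(53_000)], 3000)
        assert s == pytest.approx(math.exp(-4.5))

    def test_two_peaks_sum(self):
        peaks = [peak_at_centroid(50_000), peak_at_centroid(47_000)]
        s, k = regulatory_potential(GENE, peaks, 3000)
        assert s == pytest.approx(math.exp(-0.5) + math.exp(-4.5))
        assert k == 2

    def test_peak_outside_window_ignored(self):
        s, k = regulatory_potential(GENE, [peak_at_centroid(54_000)], 3000)
        assert (s, k) == (0.0, 0)

    @given(
        d1=st.integers(min_value=0, max_value=3000),
        d2=st.integers(min_value=0, max_value=3000),
    )
    @settings(max_examples=50, deadline=None)
    def test_closer_peak_never_scores_less(self, d1, d2):
        near, far = sorted((d1, d2))
        s_near, _ = regulatory_potential(GENE, [peak_at_centroid(50_000 + near)], 3000)
        s_far, _ = regulatory_potential(GENE, [peak_at_centroid(50_000 + far)], 3000)
        assert s_near >= s_far

    def test_adding_a_peak_never_decreases(self):
        base = [peak_at_centroid(51_000)]
        s0, _ = regulatory_potential(GENE, base, 3000)
        s1, _ = regulatory_potential(GENE, base + [peak_at_centroid(52_500)], 3000)
        assert s1 >= s0


def make_universe():
    """3-gene universe on one chromosome, TSSs far apart."""
    genome = GenomeBuild({"chrI": 1_000_000})
    genes = [
        GeneModel("g1", "chrI", "+", 100_000),
        GeneModel("g2", "chrI", "+", 200_000),
        GeneModel("g3", "chrI", "+", 300_000),
    ]
    return genome, genes


class TestCallDirectTargets:
    def test_call_requires_both_conditions(self):
        _, genes = make_universe()
        peaks = [peak_at_centroid(101_000),  # 1 kb from g1
                 peak_at_centroid(200_000)]  # at g2 TSS
        deg = {
            "g1": DEGRecord("g1", -2.0, 1e-4, 0.04),   # DEG + peak -> called
            "g2": DEGRecord("g2", -2.0, 0.02, 0.06),   # peak, FDR 0.06 -> no
            "g3": DEGRecord("g3", -2.0, 1e-4, 0.01),   # DEG, no peak -> no
        }
        calls = {c.gene_id: c for c in call_direct_targets(deg, peaks, genes)}
        assert calls["g1"].called
        assert calls["g1"].direction == "activated-by-factor"
        assert not calls["g2"].called
        assert not calls["g3"].called
        assert calls["g3"].score.regulatory_potential == 0.0

    def test_repressed_direction_from_positive_log2fc(self):
        _, genes = make_universe()
        peaks = [peak_at_centroid(100_000)]
        deg = {
            "g1": DEGRecord("g1", +1.5, 1e-4, 0.01),
            "g2": DEGRecord("g2", 0.0, 0.9, 0.95),
            "g3": DEGRecord("g3", 0.0, 0.8, 0.95),
        }
        calls = {c.gene_id: c for c in call_direct_targets(deg, peaks, genes)}
        assert calls["g1"].direction == "repressed-by-factor"

    def test_rank_product_ordering_and_range(self):
        _, genes = make_universe()
        peaks = [peak_at_centroid(100_000), peak_at_centroid(201_000)]
        deg = {
            "g1": DEGRecord("g1", -2.0, 1e-4, 0.001),
            "g2": DEGRecord("g2", -1.0, 0.01, 0.02),
            "g3": DEGRecord("g3", 0.1, 0.9, 0.95),
        }
        calls = call_direct_targets(deg, peaks, genes)
        rps = [c.score.rank_product for c in calls]
        assert rps == sorted(rps)
        assert all(0 < rp <= 1 for rp in rps)
        assert calls[0].gene_id == "g1"  # best binding + best DEG

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError):
            call_direct_targets({}, [], [])


class TestKSFunctionTest:
    def test_identical_distributions_not_significant(self, rng):
        d, p = _ks_one_sided(rng.random(200), rng.random(200))
        assert p > 0.05

    def test_perfect_separation_d_is_one(self):
        d, p = _ks_one_sided(np.linspace(0, 0.1, 20), np.linspace(0.5, 1, 20))
        assert d == pytest.approx(1.0)
        assert p < 1e-6

    def test_statistic_matches_exhaustive_ecdf_scan(self, rng):
        t, b = rng.random(20), rng.random(20)
        d, _ = _ks_one_sided(t, b)
        grid = np.concatenate([t, b])
        d_brute = max(
            np.mean(t <= x) - np.mean(b <= x) for x in grid
        )
        assert d == pytest.approx(max(d_brute, 0.0))

    def test_statistic_matches_scipy_one_sided(self, rng):
        t, b = rng.random(40), rng.random(60)
        d, _ = _ks_one_sided(t, b)
        assert d == pytest.approx(
            stats.ks_2samp(t, b, alternative="greater").statistic
        )

    def test_activator_verdict_on_constructed_rank_products(self, rng):
        # down-regulated DEGs carry systematically small RPs; up-regulated
        # DEGs look like background => verdict "activator"
        from cotarget.target_inference import DirectTargetCall, TargetScore

        deg, calls = {}, []
        def add(gid, log2fc, fdr, rp):
            deg[gid] = DEGRecord(gid, log2fc, min(fdr, 1.0), fdr)
            calls.append(DirectTargetCall(
                gene_id=gid, called=False, direction="none",
                score=TargetScore(gid, 0.0, 0, rp, rp, rp),
                log2fc=log2fc, fdr=fdr,
            ))

        for i in range(20):   # down DEGs, strong RP
            add(f"d{i:02d}", -2.0, 1e-4, float(rng.uniform(0, 0.1)))
        for i in range(20):   # up DEGs, background-like RP
            add(f"u{i:02d}", +2.0, 1e-4, float(rng.uniform(0, 1)))
        for i in range(200):  # non-DEG background
            add(f"b{i:03d}", 0.0, 0.9, float(rng.uniform(0, 1)))

        res = ks_function_test(calls, deg)
        assert res.verdict == "activator"
        assert res.p_down <= 0.05 < res.p_up

    def test_small_set_errors(self):
        genome, genes = make_universe()
        deg = {g.gene_id: DEGRecord(g.gene_id, 0.0, 0.9, 0.95) for g in genes}
        calls = call_direct_targets(deg, [], genes)
        with pytest.raises(ValueError, match="too small"):
            ks_function_test(calls, deg)


def bh_adjust(pvals):
    """Independent Benjamini-Hochberg: step-up with cumulative minimum."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


class TestConditionalOverlap:
    def make_contrasts(self, rng, n=20, n_sig_a=8):
        ids = [f"g{i:02d}" for i in range(n)]
        deg_a, deg_b = {}, {}
        for i, gid in enumerate(ids):
            if i < n_sig_a:
                deg_a[gid] = DEGRecord(gid, -2.0, 1e-6, 1e-4)
            else:
                deg_a[gid] = DEGRecord(gid, 0.1, 0.5, 0.7)
            p_b = float(rng.uniform(1e-6, 0.2))
            deg_b[gid] = DEGRecord(gid, float(rng.normal()), p_b, min(1, p_b * 3))
        return deg_a, deg_b

    def test_gate_on_first_contrast(self, rng):
        deg_a, deg_b = self.make_contrasts(rng)
        out = loa_conditional_overlap(deg_a, deg_b)
        # genes non-significant in A never shared, regardless of B
        assert not out.loc[out["fdr_a"] > 0.01, "shared"].any()

    def test_partition_of_size_one(self):
        deg_a = {"g1": DEGRecord("g1", -2.0, 1e-5, 0.001),
                 "g2": DEGRecord("g2", 0.0, 0.9, 0.95)}
        deg_b = {"g1": DEGRecord("g1", -1.0, 0.001, 0.2),
                 "g2": DEGRecord("g2", 0.0, 0.9, 0.95)}
        out = loa_conditional_overlap(deg_a, deg_b)
        # BH on a single p leaves it unchanged: 0.001 <= 0.01 -> shared
        assert bool(out.loc["g1", "shared"])
        assert out.loc["g1", "cond_fdr_b"] == pytest.approx(0.001)

    def test_conditional_bh_matches_manual_per_partition(self, rng):
        deg_a, deg_b = self.make_contrasts(rng, n=20, n_sig_a=8)
        out = loa_conditional_overlap(deg_a, deg_b)
        in_a = out["fdr_a"] <= 0.01
        for mask in (in_a, ~in_a):
            sub = out.loc[mask]
            expected = bh_adjust(sub["pvalue_b"].to_numpy())
            assert np.allclose(sub["cond_fdr_b"].to_numpy(), expected)

    def test_mismatched_universes_error(self):
        deg_a = {"g1": DEGRecord("g1", 0.0, 0.5, 0.5)}
        deg_b = {"g2": DEGRecord("g2", 0.0, 0.5, 0.5)}
        with pytest.raises(ValueError, match="universes differ"):
            loa_conditional_overlap(deg_a, deg_b)

    def test_conditioning_recovers_marginal_misses(self):
        """A gene with moderate p in B passes inside the small A-DEG
        partition but would fail global BH — the motivation for the
        conditional procedure."""
        n = 200
        deg_a, deg_b = {}, {}
        for i in range(n):
            gid = f"g{i:03d}"
            if i < 5:
                deg_a[gid] = DEGRecord(gid, -2.0, 1e-8, 1e-6)
                deg_b[gid] = DEGRecord(gid, -1.0, 0.004, 0.5)
            else:
                deg_a[gid] = DEGRecord(gid, 0.0, 0.6, 0.8)
                deg_b[gid] = DEGRecord(gid, 0.0, 0.6, 0.8)
        out = loa_conditional_overlap(deg_a, deg_b)
        assert out["shared"].sum() == 5
        # global BH over all 200 genes would give 0.004 * 200 / 5 = 0.16 > 0.01
        assert bh_adjust([deg_b[g].pvalue for g in sorted(deg_b)]).min() > 0.01
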
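"""Cline function identities, SNP selection rules, MCMC recovery, and the
enrichment / region tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from hybridzone import ancestry as anc
from hybridzone import clines as cl
from hybridzone import popstats as ps
from hybridzone import simzone as sz


class TestClinePhi:
    def test_genome_average_is_identity(self):
        assert cl.cline_phi(0.5, 1.0, 0.0) == pytest.approx(0.5, abs=1e-15)
        h = np.linspace(0, 1, 11)
        assert np.allclose(cl.cline_phi(h, 1.0, 0.0), h, atol=1e-12)

    def test_boundaries_for_all_parameters(self):
        for v, u in [(0.3, -2.0), (1.0, 0.0), (5.0, 3.0)]:
            assert cl.cline_phi(0.0, v, u) == 0.0
            assert cl.cline_phi(1.0, v, u) == 1.0

    def test_phi_at_center_is_half(self):
        for v, u in [(1, 0), (2, 1), (0.5, -2), (3, -4), (0.2, 0.3)]:
            c = cl.cline_center(v, u)
            assert cl.cline_phi(c, v, u) == pytest.approx(0.5, abs=1e-10)

    def test_ratio_form_matches_logit_form(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h = rng.uniform(0.01, 0.99)
            v = rng.uniform(0.1, 5.0)
            u = rng.normal(0, 2)
            ratio = h ** v / (h ** v + (1 - h) ** v * np.exp(u))
            assert cl.cline_phi(h, v, u) == pytest.approx(ratio, abs=1e-12)
        # the spec'd spot value
        assert cl.cline_phi(0.3, 2.0, 1.0) == pytest.approx(0.0633, abs=5e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="v must be"):
            cl.cline_phi(0.5, 0.0, 0.0)
        with pytest.raises(ValueError, match="h must lie"):
            cl.cline_phi(1.5, 1.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(v=st.floats(0.05, 10), u=st.floats(-5, 5))
    def test_monotone_increasing_in_h(self, v, u):
        """phi is non-decreasing everywhere and strictly increasing wherever
        it is not saturated at the floating-point boundaries."""
        h = np.linspace(0.001, 0.999, 101)
        phi = cl.cline_phi(h, v, u)
        assert np.all(np.diff(phi) >= 0)
        interior = (phi > 1e-9) & (phi < 1 - 1e-9)
        assert np.all(np.diff(phi[interior]) > 0)

    def test_cline_params_center_identity(self):
        p = cl.ClineParams(v=2.0, u=1.0)
        assert logit(p.c) == pytest.approx(p.u / p.v, abs=1e-9)
        with pytest.raises(ValueError):
            cl.ClineParams(v=-1.0, u=0.0)


class TestReporting:
    def test_percent_of_three_significant_figures(self):
        assert cl.percent_of(6917, 49019) == 14.1
        assert cl.percent_of(4251, 49019) == 8.67
        assert cl.percent_of(1, 3) == 33.3


def fits_table(categories, chrom=None, pos=None, v=None, c=None):
    n = len(categories)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "chrom": chrom if chrom is not None else ["c1"] * n,
        "pos": pos if pos is not None else (np.arange(n) + 1) * 1000,
        "v_median": v if v is not None else rng.lognormal(0, 0.2, n),
        "c_median": c if c is not None else expit(rng.normal(0, 0.5, n)),
        "category": categories,
    })


class TestWindowProportions:
    def test_counts_and_sum(self):
        cats = ["steep"] * 4 + ["neutral"] * 6
        t = fits_table(cats)
        w = cl.window_category_proportions(t, window_bp=500_000, smooth_k=1)
        assert len(w) == 1
        assert w.steep[0] == pytest.approx(0.4)
        assert (w.steep + w.shallow + w.neutral)[0] == pytest.approx(1.0)

    def test_smoothing_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        cats = rng.choice(["steep", "shallow", "neutral"], size=200)
        pos = np.arange(200) * 100_000 + 1
        t = fits_table(cats, pos=pos)
        raw = cl.window_category_proportions(t, 500_000, smooth_k=1)
        sm = cl.window_category_proportions(t, 500_000, smooth_k=5)
        x = raw["steep"].to_numpy()
        for i in range(len(x)):
            lo, hi = max(0, i - 2), min(len(x), i + 3)
            assert sm["steep"][i] == pytest.approx(np.mean(x[lo:hi]))


class TestChromosomeEnrichment:
    def test_extreme_concentration(self):
        """All 50 steep loci on one of five equal chromosomes -> p = 1/1000."""
        chrom = np.repeat([f"c{i}" for i in range(5)], 50)
        cats = np.where(chrom == "c0", "steep", "neutral")
        t = fits_table(cats, chrom=chrom, pos=np.tile(np.arange(50) + 1, 5))
        res = cl.chromosome_enrichment(t, n_perm=999, seed=0)
        p = res.set_index(["chrom", "category"]).loc[("c0", "steep"),
                                                     "p_value"]
        assert p == pytest.approx(1 / 1000)

    def test_zero_permutations_error(self):
        t = fits_table(["steep", "neutral"])
        with pytest.raises(ValueError, match="n_perm"):
            cl.chromosome_enrichment(t, n_perm=0)

    def test_low_power_flag(self):
        t = fits_table(["steep"] * 5, chrom=["c1"] * 5)
        res = cl.chromosome_enrichment(t, n_perm=9, seed=1)
        assert res.low_power.all()


class TestRegionVsBackground:
    def test_extreme_separation(self):
        v = np.r_[np.full(50, 0.1), np.full(50, 2.0)]
        pos = np.arange(100) * 1000 + 1
        t = fits_table(["neutral"] * 100, pos=pos, v=v)
        res = cl.region_vs_background(t, "c1", 1, 50_000)
        assert res.set_index("parameter").loc["v", "p_value"] < 1e-6

    def test_empty_region_error(self):
        t = fits_table(["neutral"] * 10)
        with pytest.raises(ValueError, match="no fitted loci"):
            cl.region_vs_background(t, "c1", 10 ** 9, 2 * 10 ** 9)


class TestSelectClineSnps:
    def _variants(self, n, chrom="c1"):
        return pd.DataFrame({"chrom": chrom, "pos": (np.arange(n) + 1) * 1000,
                             "ref": "A", "alt": "G"})

    def test_background_rate_floor(self):
        var = self._variants(1000)
        maf = np.full(1000, 0.3)
        idx = cl.select_cline_snps(var, maf, peaks=None, background_rate=0.02,
                                   seed=1)
        assert len(idx) == 20

    def test_distance_rule_strictly_greater_than_20kb(self):
        var = pd.DataFrame({"chrom": "c1",
                            "pos": [100_000, 119_999, 120_001, 500_000],
                            "ref": "A", "alt": "G"})
        maf = np.full(4, 0.3)
        sig = pd.DataFrame({"chrom": ["c1"], "pos": [100_000]})
        idx = cl.select_cline_snps(var, maf, peaks=None, sig_snps=sig,
                                   background_rate=1.0, seed=0)
        pos = set(var.pos[idx])
        assert 119_999 not in pos and 120_001 in pos

    def test_peak_maf_strictly_above_floor(self):
        var = self._variants(10)
        maf = np.full(10, 0.05)
        peaks = pd.DataFrame({"chrom": ["c1"], "min_bp": [1],
                              "max_bp": [20_000]})
        with pytest.raises(ValueError, match="empty"):
            cl.select_cline_snps(var, maf, peaks, background_rate=0.0, seed=0)

    def test_dense_chromosome_subsampling(self):
        var = self._variants(100)
        maf = np.full(100, 0.4)
        peaks = pd.DataFrame({"chrom": ["c1"], "min_bp": [1],
                              "max_bp": [200_000]})
        idx = cl.select_cline_snps(var, maf, peaks, peak_subsample=0.1,
                                   dense_chroms=("c1",), background_rate=0.0,
                                   seed=3)
        assert len(idx) == 10


def simulate_cline_zone(blocks, n_hybrids=150, loci_per_chrom=100,
                        n_chromosomes=3, seed=17):
    """Zone with an extra final chromosome of background loci reserved for
    hybrid-index estimation (kept disjoint from cline loci)."""
    cfg = sz.SimConfig(n_parent1=25, n_parent2=25, n_hybrids=n_hybrids,
                       n_chromosomes=n_chromosomes,
                       loci_per_chromosome=loci_per_chrom,
                       fraction_fixed_diff=1.0, fraction_high_afd=0.0,
                       cline_architecture=blocks, seed=seed)
    gm, truth, meta = sz.simulate_hybrid_zone(cfg)
    freqs = ps.allele_freqs(gm, meta)
    chrom = gm.variants["chrom"].to_numpy()
    last = f"chr{n_chromosomes:02d}"
    bg = np.flatnonzero(chrom == last)
    focal = np.flatnonzero(chrom != last)
    hyb = meta.loc[meta.group == "hybrid", "sample"]
    hi = anc.HybridIndexModel(gm, freqs).fit(n_snps=None, loci=bg,
                                             samples=list(hyb))
    return gm, truth, meta, freqs, hi.h_series(), focal


class TestMCMC:
    def test_deterministic_under_seed(self):
        gm, truth, meta, freqs, h, focal = simulate_cline_zone(
            (), n_hybrids=40, loci_per_chrom=30, n_chromosomes=2)
        model = cl.GenomicClineModel(gm, freqs, h)
        mcmc = cl.MCMCConfig(iterations=300, burnin=150, chains=2, seed=5)
        sds = cl.HierarchicalSDs(0.5, 0.5)
        t1 = model.fit(sds, loci=focal, mcmc=mcmc).table
        t2 = model.fit(sds, loci=focal, mcmc=mcmc).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_steep_locus_recovered(self):
        """v_true = 3 at 150 hybrids with fixed differences -> steep call."""
        blocks = (sz.ClineBlock("barrier", 0, 0, 20, 3.0),)
        gm, truth, meta, freqs, h, focal = simulate_cline_zone(blocks)
        model = cl.GenomicClineModel(gm, freqs, h)
        res = model.fit(cl.HierarchicalSDs(0.6, 0.5), loci=focal,
                        mcmc=cl.MCMCConfig(iterations=1500, burnin=750,
                                           seed=2))
        vt = truth.loci["v_true"].to_numpy()[focal]
        steep_frac = (res.table.loc[vt == 3.0, "category"] == "steep").mean()
        assert steep_frac > 0.9

    def test_category_partition(self):
        gm, truth, meta, freqs, h, focal = simulate_cline_zone(
            (), n_hybrids=60, loci_per_chrom=40, n_chromosomes=2)
        model = cl.GenomicClineModel(gm, freqs, h)
        res = model.fit(cl.HierarchicalSDs(0.5, 0.5), loci=focal,
                        mcmc=cl.MCMCConfig(iterations=600, burnin=300, seed=3))
        t = res.table
        assert set(t.category) <= {"steep", "shallow", "neutral"}
        assert ((t.category == "steep") == (t.v_lo > 1)).all()
        assert ((t.category == "shallow") == (t.v_hi < 1)).all()

    def test_center_distribution_symmetric_under_u_zero(self):
        gm, truth, meta, freqs, h, focal = simulate_cline_zone(
            (), n_hybrids=120, loci_per_chrom=100, n_chromosomes=2, seed=29)
        model = cl.GenomicClineModel(gm, freqs, h)
        res = model.fit(cl.HierarchicalSDs(0.5, 0.5), loci=focal,
                        mcmc=cl.MCMCConfig(iterations=1500, burnin=750,
                                           seed=6))
        assert res.table.c_mean.mean() == pytest.approx(0.5, abs=0.05)

    def test_label_swap_equivariance(self):
        """Swapping parent designations keeps v and maps c -> 1 - c."""
        blocks = (sz.ClineBlock("steep", 0, 0, 10, 2.5, c=0.4),)
        gm, truth, meta, freqs, h, focal = simulate_cline_zone(
            blocks, n_hybrids=80, loci_per_chrom=40, n_chromosomes=2, seed=21)
        mcmc = cl.MCMCConfig(iterations=1200, burnin=600, seed=8)
        sds = cl.HierarchicalSDs(0.6, 0.6)
        res = cl.GenomicClineModel(gm, freqs, h).fit(sds, loci=focal,
                                                     mcmc=mcmc)
        swapped = ps.ParentalAlleleFreqs(freqs.p2, freqs.p1, freqs.n2,
                                         freqs.n1)
        res2 = cl.GenomicClineModel(gm, swapped, 1.0 - h).fit(sds, loci=focal,
                                                              mcmc=mcmc)
        dv = res.table.v_median - res2.table.v_median
        dc = res.table.c_median - (1.0 - res2.table.c_median)
        assert np.abs(dv).mean() < 0.15
        assert np.abs(dc).mean() < 0.05

    def test_hierarchical_sd_recovery(self):
        """sd_logv = sd_logitc = 0.5 truth recovered within +-30%."""
        rng = np.random.default_rng(77)
        L = 300
        v = np.exp(rng.normal(0, 0.5, L))
        c = expit(rng.normal(0, 0.5, L))
        blocks = tuple(sz.ClineBlock(f"b{i}", 0, i, 1, float(v[i]),
                                     float(c[i])) for i in range(L))
        cfg = sz.SimConfig(n_parent1=20, n_parent2=20, n_hybrids=150,
                           n_chromosomes=2, loci_per_chromosome=L,
                           fraction_fixed_diff=1.0, fraction_high_afd=0.0,
                           cline_architecture=blocks, seed=13)
        gm, truth, meta = sz.simulate_hybrid_zone(cfg)
        freqs = ps.allele_freqs(gm, meta)
        chrom = gm.variants["chrom"].to_numpy()
        bg = np.flatnonzero(chrom == "chr02")
        focal = np.flatnonzero(chrom == "chr01")
        hyb = meta.loc[meta.group == "hybrid", "sample"]
        h = anc.HybridIndexModel(gm, freqs).fit(
            n_snps=None, loci=bg, samples=list(hyb)).h_series()
        model = cl.GenomicClineModel(gm, freqs, h)
        sds = model.fit_sds(loci=focal,
                            mcmc=cl.MCMCConfig(iterations=2000, burnin=1000,
                                               seed=4))
        assert sds.sd_logv == pytest.approx(0.5, rel=0.3)
        assert sds.sd_logitc == pytest.approx(0.5, rel=0.3)

    def test_null_sd_concentrates_near_zero(self):
        """All loci at v=1, c=0.5: sd_logv posterior median < 0.15."""
        gm, truth, meta, freqs, h, focal = simulate_cline_zone(
            (), n_hybrids=120, loci_per_chrom=120, n_chromosomes=2, seed=19)
        model = cl.GenomicClineModel(gm, freqs, h)
        sds = model.fit_sds(loci=focal,
                            mcmc=cl.MCMCConfig(iterations=2000, burnin=1000,
                                               seed=5))
        assert sds.sd_logv < 0.15
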
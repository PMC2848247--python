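"""Density, spacing, sliding-window and gene-relative statistics."""

import numpy as np
import pytest

from dccmotif import (
    Anchor,
    DensityConfig,
    GeneModel,
    GenomicRegion,
    MotifSite,
    gene_relative_positions,
    random_anchors,
    region_centers,
    site_density,
    sliding_density_profile,
    spacing_distribution,
    uniformity_test,
)


def sites_at(starts, chrom="chrX", width=12):
    return [MotifSite(chrom, s, s + width, "+", 1.0) for s in starts]


class TestSiteDensity:
    def test_ten_sites_in_2mb(self):
        sites = sites_at(range(1000, 1000 + 10 * 5000, 5000))
        regions = [GenomicRegion("chrX", 0, 2_000_000)]
        d, se = site_density(sites, regions)
        assert d == pytest.approx(5.0)

    def test_trojan_horse_region_density(self):
        """4 sites in a 3633 bp interval -> 1101 sites/Mb (rounded)."""
        sites = sites_at([10, 800, 2000, 3500])
        regions = [GenomicRegion("chrX", 0, 3633)]
        d, _ = site_density(sites, regions)
        assert round(d) == 1101

    def test_no_sites(self):
        d, se = site_density([], [GenomicRegion("chrX", 0, 10_000)])
        assert d == 0.0 and se == 0.0

    def test_empty_region_set_raises(self):
        with pytest.raises(ValueError, match="zero base pairs"):
            site_density(sites_at([5]), [])

    def test_invariant_under_region_splitting(self, rng):
        starts = np.sort(rng.choice(100_000, size=200, replace=False))
        sites = sites_at(starts.tolist())
        whole = [GenomicRegion("chrX", 0, 100_012)]
        split = [
            GenomicRegion("chrX", s, s + 4) for s in range(0, 100_012, 4)
        ]
        d1, _ = site_density(sites, whole)
        d2, _ = site_density(sites, split)
        assert d1 == pytest.approx(d2)

    def test_fragment_se_positive_for_uneven_distribution(self):
        sites = sites_at(range(0, 5000, 100))  # all in the first 5 kb
        regions = [GenomicRegion("chrX", 0, 100_000)]
        _, se = site_density(sites, regions, DensityConfig(fragment_length=10_000))
        assert se > 0


class TestSpacing:
    def test_gap_examples(self):
        sites = sites_at([0, 112, 324])
        s = spacing_distribution(sites)
        assert s.gaps.tolist() == [100, 200]
        assert s.median == pytest.approx(150.0)

    def test_single_site_empty(self):
        s = spacing_distribution(sites_at([5]))
        assert s.gaps.size == 0

    def test_gaps_never_cross_chromosomes(self):
        sites = sites_at([0, 100]) + sites_at([50], chrom="chr2L")
        s = spacing_distribution(sites)
        assert s.gaps.size == 1

    def test_matches_naive_oracle(self, rng):
        starts = np.sort(rng.choice(500_000, size=800, replace=False))
        sites = sites_at(starts.tolist())
        s = spacing_distribution(sites, threshold=1000)
        expected = sorted(
            b.start - a.end for a, b in zip(sites, sites[1:])
        )
        assert s.gaps.tolist() == expected
        assert s.median == pytest.approx(float(np.median(expected)))
        assert s.fraction_below == pytest.approx(
            np.mean([g < 1000 for g in expected])
        )


class TestSlidingProfile:
    def test_no_sites_gives_zero_profile(self):
        prof = sliding_density_profile(
            [], [Anchor("chrX", 5000)], DensityConfig(max_offset=200)
        )
        assert np.all(prof.mean_density == 0)

    def test_single_site_at_anchor(self):
        cfg = DensityConfig(window=500, max_offset=1500)
        site = MotifSite("chrX", 4994, 5006, "+", 1.0)  # center 5000
        prof = sliding_density_profile([site], [Anchor("chrX", 5000)], cfg)
        d = dict(zip(prof.offsets.tolist(), prof.mean_density.tolist()))
        assert d[0] == pytest.approx(2000.0)  # 1 site / 500 bp
        assert d[1500] == 0.0 and d[-1500] == 0.0

    def test_orientation_flips_offsets(self):
        cfg = DensityConfig(window=100, max_offset=500)
        site = MotifSite("chrX", 5294, 5306, "+", 1.0)  # center 5300
        fwd = sliding_density_profile([site], [Anchor("chrX", 5000, 1)], cfg)
        rev = sliding_density_profile([site], [Anchor("chrX", 5000, -1)], cfg)
        assert np.array_equal(fwd.mean_density, rev.mean_density[::-1])

    def test_flat_for_uniform_sites(self):
        cfg = DensityConfig(window=500, max_offset=2000)
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            starts = np.sort(rng.choice(200_000, size=400, replace=False))
            sites = sites_at(starts.tolist())
            anchors = [
                Anchor("chrX", int(p))
                for p in rng.integers(10_000, 190_000, size=50)
            ]
            prof = sliding_density_profile(sites, anchors, cfg)
            means.append(prof.mean_density.mean())
        # 400 sites / 200 kb = 2000 sites/Mb
        assert np.mean(means) == pytest.approx(2000.0, rel=0.05)

    def test_offset_zero_crosschecks_site_density(self):
        cfg = DensityConfig(window=500, max_offset=10)
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(50_000, size=150, replace=False))
        sites = sites_at(starts.tolist())
        regions = [GenomicRegion("chrX", s, s + 1000) for s in (5000, 20_000)]
        anchors = region_centers(regions)
        prof = sliding_density_profile(sites, anchors, cfg)
        windows = [
            GenomicRegion("chrX", a.position, a.position + 500) for a in anchors
        ]
        manual = np.mean(
            [site_density(sites, [w])[0] for w in windows]
        )
        at_zero = prof.mean_density[prof.offsets.tolist().index(0)]
        assert at_zero == pytest.approx(manual)

    def test_windows_past_chromosome_end_dropped(self):
        cfg = DensityConfig(window=500, max_offset=1000)
        prof = sliding_density_profile(
            [], [Anchor("chrX", 800)], cfg, chrom_lengths={"chrX": 2000}
        )
        d = dict(zip(prof.offsets.tolist(), prof.n_anchors.tolist()))
        assert d[0] == 1
        assert d[-900] == 0  # upstream window would start below 0
        assert d[900] == 0  # downstream window would pass position 2000


class TestAnchors:
    def test_region_center(self):
        assert region_centers([GenomicRegion("chrX", 0, 10)])[0].position == 5

    def test_random_anchors_deterministic(self):
        lengths = {"chr2L": 100_000, "chr2R": 100_000}
        a = random_anchors(lengths, 100, seed=5)
        b = random_anchors(lengths, 100, seed=5)
        assert a == b

    def test_anchor_counts_per_arm(self):
        lengths = {f"chr{n}": 50_000 for n in ("2L", "2R", "3L", "3R")}
        anchors = random_anchors(lengths, 1000, seed=1)
        assert len(anchors) == 4000


class TestGeneRelativePositions:
    def make_gene(self, start, end, strand="+", score=None):
        return GeneModel("g", "chrX", strand, start, end,
                         [(start, end - (end - start) % 3)], score)

    def test_site_at_five_prime_end(self):
        gene = GeneModel("g", "chrX", "+", 1000, 4000, [(1000, 4000)])
        site = MotifSite("chrX", 994, 1006, "+", 1.0)  # center 1000
        assert gene_relative_positions([site], [gene]) == [0.0]

    def test_site_at_midpoint(self):
        gene = GeneModel("g", "chrX", "+", 0, 3000, [(0, 3000)])
        site = MotifSite("chrX", 1494, 1506, "+", 1.0)  # center 1500
        assert gene_relative_positions([site], [gene]) == [0.5]

    def test_strand_mirror_symmetry(self):
        L = 3000
        plus = GeneModel("gp", "chrX", "+", 0, L, [(0, L)])
        minus = GeneModel("gm", "chrX", "-", 0, L, [(0, L)])
        centers = [300, 1200, 2800]
        plus_sites = [MotifSite("chrX", c - 6, c + 6, "+", 1.0) for c in centers]
        minus_sites = [
            MotifSite("chrX", (L - 1 - c) - 6, (L - 1 - c) + 6, "+", 1.0)
            for c in centers
        ]
        v_plus = gene_relative_positions(plus_sites, [plus])
        v_minus = gene_relative_positions(minus_sites, [minus])
        assert sorted(v_plus) == pytest.approx(sorted(v_minus))

    def test_short_genes_and_low_signal_filtered(self):
        short = GeneModel("g1", "chrX", "+", 0, 1500, [(0, 1500)])
        weak = GeneModel("g2", "chrX", "+", 2000, 6200, [(2000, 6200)], 0.2)
        site1 = MotifSite("chrX", 700, 712, "+", 1.0)
        site2 = MotifSite("chrX", 4000, 4012, "+", 1.0)
        assert gene_relative_positions([site1, site2], [short, weak],
                                       min_signal=0.5) == []


class TestUniformityTest:
    def test_uniform_grid_is_not_rejected(self):
        values = np.linspace(0.06, 0.94, 200)
        stat, p = uniformity_test(values.tolist())
        assert stat < 0.05
        assert p > 0.9

    def test_degenerate_mass_rejected(self):
        stat, p = uniformity_test([0.5] * 100)
        assert p < 1e-3

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match="at least 5"):
            uniformity_test([0.1, 0.5, 0.9])

    def test_calibrated_under_uniform_null(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            _, p = uniformity_test(rng.uniform(0, 1, size=500).tolist())
            pvals.append(p)
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
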
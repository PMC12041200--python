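"""Community generation, minimum-distance sampling, and per-species GEV fits."""

import numpy as np
import pytest
from scipy import stats

import evtsar as e
from evtsar.simulator import _species_rng


def small_cfg(**kw):
    base = dict(n_species=100, n_individuals=50, sigma_kernel=1.0,
                region_radius=10.0, seed=3)
    base.update(kw)
    return e.CommunityConfig(**base)


class TestGenerateCommunity:
    def test_centres_inside_region(self):
        c = e.generate_community(small_cfg(n_species=500))
        assert np.all(c.upsilon_p <= c.config.region_radius + 1e-12)

    def test_seed_reproducibility(self):
        c1 = e.generate_community(small_cfg())
        c2 = e.generate_community(small_cfg())
        assert np.array_equal(c1.centres, c2.centres)

    def test_uniform_in_disc_radial_law(self):
        c = e.generate_community(small_cfg(n_species=10000, region_radius=7.0))
        res = stats.kstest(c.upsilon_p, lambda r: (r / 7.0) ** 2)
        assert res.pvalue > 0.01

    def test_legacy_centre_law_differs(self):
        c1 = e.generate_community(small_cfg(centre_law="uniform_disc", region_radius=9.0))
        c2 = e.generate_community(small_cfg(centre_law="legacy_sqrt_unif", region_radius=9.0))
        assert not np.array_equal(c1.centres, c2.centres)
        assert np.all(c2.upsilon_p <= 3.0)  # sqrt(unif[0, 9])

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            small_cfg(n_species=0)
        with pytest.raises(ValueError):
            small_cfg(kernel="levy")
        with pytest.raises(ValueError):
            small_cfg(sigma_kernel=-1.0)
        with pytest.raises(ValueError):
            small_cfg(centre_law="hexagonal")

    def test_per_species_sigma_vector(self):
        sig = np.linspace(0.5, 2.0, 100)
        c = e.generate_community(small_cfg(sigma_kernel=sig))
        assert np.array_equal(c.sigma_p, sig)


class TestSampleMinDistance:
    def test_single_draw_is_rice(self, rng):
        sp = e.SpeciesRange(centre=(1.5, 0.0), sigma_p=1.0)
        draws = np.array([e.sample_min_distance(sp, 1, rng) for _ in range(10000)])
        p = e.RiceParams(1.5, 1.0)
        assert stats.kstest(draws, lambda r: e.rice_cdf(r, p)).pvalue > 0.01

    def test_minimum_decreases_with_n(self, rng):
        sp = e.SpeciesRange(centre=(2.0, 1.0), sigma_p=1.0)
        m10 = np.mean([e.sample_min_distance(sp, 10, rng) for _ in range(300)])
        m1000 = np.mean([e.sample_min_distance(sp, 1000, rng) for _ in range(300)])
        assert m1000 < m10

    def test_minima_match_order_statistic_law(self):
        # minima over n=1000 individuals of a focal-centred species follow
        # 1 - (1 - F_Rayleigh)**n
        cfg = small_cfg(n_species=1, n_individuals=1000, region_radius=1e-9)
        community = e.generate_community(cfg)
        reps = e.replicate_minima(community, n=1000, N=4000, seed=11)
        law = e.MinimaLaw(
            parent_cdf=lambda r: e.rayleigh_cdf(r, e.RayleighParams(1.0)), n=1000)
        assert stats.kstest(reps.minima[0], law.cdf).pvalue > 0.01


class TestReplicateMinima:
    def test_shape_and_determinism(self):
        community = e.generate_community(small_cfg(n_species=20))
        r1 = e.replicate_minima(community, n=50, N=40, seed=1)
        r2 = e.replicate_minima(community, n=50, N=40, seed=1)
        assert r1.minima.shape == (20, 40)
        assert np.array_equal(r1.minima, r2.minima)

    def test_substreams_independent_of_community_size(self):
        # species i's minima do not change when more species are added
        cfg_small = small_cfg(n_species=5)
        community = e.generate_community(cfg_small)
        big = e.Community(centres=np.vstack([community.centres, community.centres + 3.0]),
                          sigma_p=np.repeat(1.0, 10), kernel="normal", config=cfg_small)
        m5 = e.replicate_minima(community, n=30, N=20, seed=2).minima
        m10 = e.replicate_minima(big, n=30, N=20, seed=2).minima
        assert np.array_equal(m5, m10[:5])

    def test_stochastic_ordering_in_n(self):
        community = e.generate_community(small_cfg(n_species=30))
        m10 = e.replicate_minima(community, n=10, N=200, seed=4).minima.mean(axis=1)
        m1000 = e.replicate_minima(community, n=1000, N=200, seed=4).minima.mean(axis=1)
        assert np.all(m1000 < m10)


class TestEstimateGEV:
    def test_near_and_far_shape_regimes(self):
        # near species: Weibull-type (xi ~ -0.5); far species: xi <= 0
        radii = np.concatenate([np.linspace(0.1, 1.5, 8), np.linspace(6.0, 10.0, 8)])
        cfg = small_cfg(n_species=16, centre_law=lambda rng, n: radii)
        community = e.generate_community(cfg)
        reps = e.replicate_minima(community, n=1000, N=500, seed=13)
        table = e.estimate_gev_per_species(reps)
        near = table[table.ratio < 2]
        far = table[table.ratio > 5]
        assert near.xi.mean() == pytest.approx(-0.5, abs=0.12)
        assert far.xi.mean() <= 0.0
        assert table.converged.all()

    def test_requires_enough_replicates(self):
        community = e.generate_community(small_cfg(n_species=3))
        reps = e.replicate_minima(community, n=20, N=10, seed=1)
        with pytest.raises(ValueError):
            e.estimate_gev_per_species(reps)


class TestSARRealisation:
    def test_counts_reach_community_size(self, triphasic_community, triphasic_curve):
        assert triphasic_curve.s_obs == triphasic_community.n_species
        assert triphasic_curve.counts[-1] == triphasic_community.n_species

    def test_curve_nondecreasing(self, triphasic_curve):
        assert np.all(np.diff(triphasic_curve.areas) >= 0)

    def test_ratio_banding(self, triphasic_community, triphasic_curve):
        """Species entering the curve early sit nearer the focal point (in
        units of range scale) than those entering late."""
        community = triphasic_community
        reps = e.replicate_minima(community, n=200, N=1, seed=6)
        order = np.argsort(reps.minima[:, 0], kind="stable")
        ratios = community.ratio[order]
        third = len(ratios) // 3
        assert np.median(ratios[:third]) < np.median(ratios[-third:])


class TestOccurrenceFixture:
    def test_row_count(self):
        cfg = small_cfg(n_species=12, n_individuals=25)
        df = e.generate_occurrence_fixture(cfg)
        assert len(df) == 12 * 25
        assert set(df.columns) == {"species", "x", "y"}

    def test_moment_recovery(self, gaussian_fixture_table):
        cfg_sigma, cfg_seed = 2.0, 9
        stats_df = e.species_range_stats(gaussian_fixture_table)
        cfg = e.CommunityConfig(n_species=30, n_individuals=1000, sigma_kernel=cfg_sigma,
                                region_radius=15.0, seed=cfg_seed)
        community = e.generate_community(cfg)
        # sigma_p (sd of distances to centre) estimates the Rice sd at upsilon=0
        target = e.rice_moments(e.RiceParams(0.0, cfg_sigma)).sd
        assert np.allclose(stats_df["sigma_p"], target, rtol=0.05)
        # centres of gravity recover the kernel centres
        got = stats_df[["centre_x", "centre_y"]].to_numpy()
        order = np.argsort([f"sp{i:05d}" for i in range(30)])
        assert np.allclose(got, community.centres[order], atol=0.25)

    def test_aggregation_artefact(self):
        cfg = small_cfg(n_species=10, n_individuals=40)
        df = e.generate_occurrence_fixture(cfg, aggregation_fraction=0.3)
        shared = df.groupby(["x", "y"])["species"].nunique()
        assert (shared >= 2).any()

    def test_aggregation_fraction_validated(self):
        with pytest.raises(ValueError):
            e.generate_occurrence_fixture(small_cfg(), aggregation_fraction=1.5)


class TestCauchyKernel:
    def test_phase_two_spans_more_area_than_normal(self):
        """Heavy-tailed kernels stretch the intermediate power-law phase: the
        sub-unit-slope regime covers more log-area than with normal kernels,
        because the steep large-area phase is postponed."""
        from evtsar.sar_curves import loglog_slope

        def shallow_width(kernel):
            cfg = e.CommunityConfig(n_species=3000, n_individuals=1000,
                                    sigma_kernel=1.0, region_radius=60.0,
                                    kernel=kernel, seed=21)
            curve = e.simulate_sar_realisation(e.generate_community(cfg), 1000, 22)
            cs = np.unique(np.round(np.geomspace(20, int(0.95 * curve.s_obs), 40)).astype(int))
            slopes = np.array([
                loglog_slope(curve, count_window=(int(c / 1.4), int(c * 1.4)),
                             min_points=5).slope
                for c in cs])
            below = slopes < 0.85
            i0 = int(np.nanargmin(slopes))
            lo = i0
            while lo > 0 and below[lo - 1]:
                lo -= 1
            hi = i0
            while hi < len(cs) - 1 and below[hi + 1]:
                hi += 1
            return np.log10(curve.areas[cs[hi] - 1] / curve.areas[cs[lo] - 1])

        assert shallow_width("cauchy") > shallow_width("normal")
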
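"""Coalescent engine: moments, demography, fixed-S conditioning, sweeps."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from sweepkit._util import harmonic
from sweepkit.coalsim import (
    DemographyModel,
    SimulationConfig,
    _batch_interval_times,
    _coalescent_intervals,
    empirical_pvalue,
    simulate_fixed_S,
    simulate_neutral,
    simulate_sweep,
    write_ms,
)


class TestConfigValidation:
    def test_bad_prior(self):
        with pytest.raises(ValueError):
            SimulationConfig(n=10, L=100, theta_prior=(0.06, 0.001))

    def test_single_window_without_recombination(self):
        cfg = SimulationConfig(n=10, L=5000, theta=0.01)
        assert len(cfg.windows()) == 1

    def test_windows_scale_with_recombination(self):
        cfg = SimulationConfig(n=10, L=5000, theta=0.01, rho_per_site=0.02)
        assert len(cfg.windows()) > 1

    def test_demography_validation(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=[(0.1, 1.0)])
        with pytest.raises(ValueError):
            DemographyModel(epochs=[(0.0, 1.0), (0.0, 0.5)])


class TestNeutralMoments:
    def test_pairwise_sample_mean_S(self):
        # E[S] = theta * a_2 = theta for n = 2
        cfg = SimulationConfig(n=2, L=100, theta=0.05, reps=20000, seed=1)
        rs = simulate_neutral(cfg)
        assert rs.S.mean() == pytest.approx(5.0, rel=0.05)

    def test_mean_tmrca(self):
        cfg = SimulationConfig(n=10, L=10, theta=0.0, reps=20000, seed=2)
        rs = simulate_neutral(cfg)
        assert rs.tmrcas.mean() == pytest.approx(0.9, rel=0.02)

    def test_mean_pi_matches_theta(self):
        cfg = SimulationConfig(n=10, L=1000, theta=0.01, reps=5000, seed=3)
        rs = simulate_neutral(cfg)
        assert rs.pi_counts().mean() / 1000 == pytest.approx(0.01, rel=0.05)

    def test_sfs_proportional_to_one_over_i(self):
        # per-class z-scores with empirical standard errors (sites within a
        # replicate share one genealogy, so pooled counts are overdispersed
        # relative to multinomial)
        n = 10
        theta_locus = 0.01 * 1000
        cfg = SimulationConfig(n=n, L=1000, theta=0.01, reps=10000, seed=4)
        rs = simulate_neutral(cfg)
        mat = rs.sfs_matrix().astype(float)
        expected = theta_locus / np.arange(1, n)
        z = (mat.mean(axis=0) - expected) / (
            mat.std(axis=0) / np.sqrt(mat.shape[0])
        )
        chi2 = float(np.sum(z**2))
        assert sps.chi2.sf(chi2, n - 1) > 0.01


class TestDemography:
    def test_flat_bottleneck_indistinguishable_from_snm(self):
        flat = DemographyModel(
            epochs=[(0.0, 1.0), (0.05, 1.0), (0.1, 1.0)], label="BN"
        )
        cfg1 = SimulationConfig(n=10, L=1000, theta=0.01, reps=3000, seed=5)
        cfg2 = SimulationConfig(n=10, L=1000, theta=0.01, reps=3000, seed=6)
        s_flat = simulate_neutral(cfg1, flat).S
        s_snm = simulate_neutral(cfg2).S
        assert sps.ks_2samp(s_flat, s_snm).pvalue > 0.01

    def test_crash_reduces_variation(self):
        crash = DemographyModel.bottleneck(0.01, 0.05, 0.01)
        cfg = SimulationConfig(n=10, L=1000, theta=0.01, reps=2000, seed=7)
        s_bn = simulate_neutral(cfg, crash).S.mean()
        s_snm = simulate_neutral(cfg).S.mean()
        assert s_bn < 0.7 * s_snm

    def test_vectorized_times_match_scalar_path(self):
        bn = DemographyModel.bottleneck(0.05, 0.05, 0.05, ancestral_ratio=2.0)
        _, lengths = _batch_interval_times(np.random.default_rng(1), 10, bn, 20000, 1)
        r = np.random.default_rng(2)
        scalar = [_coalescent_intervals(r, 10, bn)[1] for _ in range(20000)]
        assert lengths.mean() == pytest.approx(np.mean(scalar), rel=0.03)
        assert lengths.std() == pytest.approx(np.std(scalar), rel=0.05)

    def test_inheritance_factor_scales_tree_length(self):
        x = DemographyModel.snm(inheritance_factor=0.75)
        _, l = _batch_interval_times(np.random.default_rng(3), 12, x, 20000, 1)
        assert l.mean() == pytest.approx(0.75 * harmonic(12), rel=0.02)


class TestFixedS:
    def test_every_replicate_hits_target_exactly(self):
        cfg = SimulationConfig(
            n=10, L=2000, theta_prior=(0.001, 0.06), fixed_S=25, reps=100, seed=8
        )
        rs = simulate_fixed_S(cfg)
        assert all(len(c) == 25 for c in rs.counts)
        assert 0 < rs.acceptance_rate < 1

    def test_accepted_theta_shifts_up_with_target(self):
        kw = dict(n=10, L=2000, theta_prior=(0.001, 0.06), reps=150)
        lo = simulate_fixed_S(SimulationConfig(fixed_S=20, seed=9, **kw))
        hi = simulate_fixed_S(SimulationConfig(fixed_S=40, seed=9, **kw))
        assert hi.thetas.mean() > lo.thetas.mean()

    def test_unreachable_target_aborts(self):
        cfg = SimulationConfig(
            n=10, L=100, theta_prior=(0.0001, 0.0002), fixed_S=500, reps=10,
            seed=10, min_acceptance=1e-4,
        )
        with pytest.raises(RuntimeError, match="acceptance"):
            simulate_fixed_S(cfg)

    def test_works_with_recombination_and_bottleneck(self):
        bn = DemographyModel.bottleneck(0.02, 0.01, 0.05)
        cfg = SimulationConfig(
            n=10, L=2000, theta_prior=(0.001, 0.06), fixed_S=30,
            rho_per_site=0.02, reps=50, seed=11, n_windows=8,
        )
        rs = simulate_fixed_S(cfg, bn)
        assert all(len(c) == 30 for c in rs.counts)


class TestSweepSimulation:
    def test_full_escape_matches_neutral(self):
        cfg = SimulationConfig(n=10, L=1000, theta=0.01, reps=3000, seed=12)
        s_sweep = simulate_sweep(cfg, p_esc=1.0).S
        cfg2 = SimulationConfig(n=10, L=1000, theta=0.01, reps=3000, seed=13)
        s_neut = simulate_neutral(cfg2).S
        assert sps.ks_2samp(s_sweep, s_neut).pvalue > 0.01

    def test_complete_sweep_removes_variation(self):
        cfg = SimulationConfig(n=10, L=1000, theta=0.01, reps=200, seed=14)
        rs = simulate_sweep(cfg, p_esc=0.0)
        assert all(len(c) == 0 for c in rs.counts)

    def test_strong_sweep_monomorphic_at_target(self):
        # alpha large, site at the target: every lineage is swept
        cfg = SimulationConfig(
            n=10, L=100, theta=0.02, rho_per_site=0.02, reps=300, seed=15,
            n_windows=1,
        )
        rs = simulate_sweep(cfg, alpha=1e9, X=50.0)
        assert all(len(c) == 0 for c in rs.counts)

    def test_partial_sweep_excess_high_frequency_derived(self):
        n = 10
        cfg = SimulationConfig(n=n, L=200, theta=0.05, reps=8000, seed=16)
        sw = simulate_sweep(cfg, p_esc=0.5).sfs_matrix().sum(axis=0).astype(float)
        cfg2 = SimulationConfig(n=n, L=200, theta=0.05, reps=8000, seed=17)
        ne = simulate_neutral(cfg2).sfs_matrix().sum(axis=0).astype(float)
        high = slice(n - 3, n - 1)
        assert sw[high].sum() / sw.sum() > ne[high].sum() / ne.sum()

    def test_older_sweep_allows_recovery_singletons(self):
        cfg = SimulationConfig(n=10, L=500, theta=0.02, reps=2000, seed=18)
        rs = simulate_sweep(cfg, p_esc=0.0, time_since_sweep=0.1)
        xi = rs.sfs_matrix().sum(axis=0)
        # post-sweep mutations are recent: spectrum dominated by singletons
        assert xi[0] > 0.7 * xi.sum()


class TestDeterminismAndIO:
    def test_identical_seeds_bitwise_identical(self):
        cfg = SimulationConfig(n=8, L=500, theta=0.02, rho_per_site=0.01,
                               reps=50, seed=42)
        a = simulate_neutral(cfg)
        b = simulate_neutral(cfg)
        for pa, pb in zip(a.positions, b.positions):
            assert np.array_equal(pa, pb)
        for ca, cb in zip(a.counts, b.counts):
            assert np.array_equal(ca, cb)

    def test_finite_sites_discrete_positions(self):
        cfg = SimulationConfig(n=6, L=20, theta=0.5, reps=200, seed=43,
                               finite_sites=True)
        rs = simulate_neutral(cfg)
        for pos in rs.positions:
            assert np.array_equal(pos, np.round(pos))

    def test_ms_output_parses(self):
        cfg = SimulationConfig(n=5, L=100, theta=0.05, reps=3, seed=44)
        rs = simulate_neutral(cfg)
        buf = io.StringIO()
        write_ms(rs, buf)
        text = buf.getvalue()
        assert text.count("//") == 3
        assert "segsites:" in text


class TestEmpiricalPValue:
    def test_more_extreme_than_all_is_bound(self):
        p = empirical_pvalue(-10.0, np.random.default_rng(0).normal(size=1000))
        assert p.bound and str(p) == "<0.001"

    def test_median_is_half(self):
        sims = np.arange(1000, dtype=float)
        p = empirical_pvalue(499.5, sims, "lower")
        assert p.value == pytest.approx(0.5)

    def test_above_all_lower_tail_is_one(self):
        p = empirical_pvalue(10.0, np.zeros(100), "lower")
        assert p.value == 1.0 and not p.bound
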
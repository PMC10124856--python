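import numpy as np
import pytest

from stdpnet.model_core import (
    NetworkConfig,
    RateModulationSchedule,
    StimulusProtocol,
    build_homogeneous_assembly,
)
from stdpnet import hawkes_engine as he
from stdpnet import theory


def count_sd(W, lam0, tau_s, T):
    """Asymptotic SD of per-neuron spike counts from the zero-frequency
    spectrum (accounts for spike clustering in the network)."""
    C0 = theory.correlation_spectrum(W, lam0, tau_s, np.array([0.0]))[0].real
    return np.sqrt(np.diag(C0) * T)


class TestPoissonBaseline:
    def test_pure_poisson_counts(self):
        cfg = NetworkConfig(N=10, w_max=0.04, tau_s=0.01, lambda0=0.15, seed=1)
        res = he.simulate(cfg, np.zeros((10, 10)), duration=1e4, seed=3)
        assert res.status == "ok"
        counts = he.empirical_rates(res.record) * 1e4
        z = (counts - 1500) / np.sqrt(1500)
        assert np.all(np.abs(z) < 4)

    def test_count_linearity_in_rate(self):
        cfg1 = NetworkConfig(N=4, w_max=0.04, tau_s=0.01, lambda0=0.2, seed=2)
        cfg2 = NetworkConfig(N=4, w_max=0.04, tau_s=0.01, lambda0=0.4, seed=2)
        n1 = len(he.simulate(cfg1, np.zeros((4, 4)), duration=5e3, seed=5).record)
        n2 = len(he.simulate(cfg2, np.zeros((4, 4)), duration=5e3, seed=5).record)
        assert n2 / n1 == pytest.approx(2.0, abs=0.15)

    def test_reproducibility_bit_identical(self, small_config):
        W = build_homogeneous_assembly(10, small_config)
        a = he.simulate(small_config, W, duration=200.0, seed=11)
        b = he.simulate(small_config, W, duration=200.0, seed=11)
        assert np.array_equal(a.record.times, b.record.times)
        assert np.array_equal(a.record.ids, b.record.ids)
        c = he.simulate(small_config, W, duration=200.0, seed=12)
        assert not np.array_equal(a.record.times, c.record.times)


class TestFixedWeightRates:
    def test_homogeneous_assembly_rate_matches_branching_formula(self, small_config):
        """Empirical rates on a frozen assembly agree with lam0/(1-rho)."""
        W = build_homogeneous_assembly(10, small_config)
        T = 2e4
        res = he.simulate(small_config, W, duration=T, seed=21)
        counts = he.empirical_rates(res.record) * T
        expected = 0.15 / (1 - 0.36) * T
        sd = count_sd(W, small_config.lambda0, 0.01, T)
        assert np.all(np.abs(counts - expected) < 4 * sd)

    def test_random_network_rates_match_linear_response(self, rng):
        from conftest import substochastic_weights

        N = 12
        W = substochastic_weights(rng, N, 0.05)
        cfg = NetworkConfig(N=N, w_max=0.1, tau_s=0.01, lambda0=0.3, seed=4)
        T = 2e4
        res = he.simulate(cfg, W, duration=T, seed=31)
        counts = he.empirical_rates(res.record) * T
        expected = theory.stationary_rates(W, cfg.lambda0) * T
        sd = count_sd(W, cfg.lambda0, 0.01, T)
        assert np.all(np.abs(counts - expected) < 4 * sd)


class TestDivergenceGuard:
    def test_supercritical_network_flagged_pathological(self):
        N = 30
        cfg = NetworkConfig(N=N, w_max=0.05, tau_s=0.01, lambda0=0.5, seed=6)
        W = np.full((N, N), 0.05)  # rho = 1.45
        np.fill_diagonal(W, 0.0)
        res = he.simulate(cfg, W, duration=500.0, seed=41, ceiling_factor=100.0)
        assert res.status == "pathological"
        with pytest.raises(he.PathologicalActivityError):
            he.simulate(cfg, W, duration=500.0, seed=41, ceiling_factor=100.0,
                        raise_on_divergence=True)


class TestTrackedDrift:
    def test_unconnected_pair_drift_is_rate_rate_term(self, fig2_window):
        """Two unconnected neurons: drift = f0 * lam0^2 (uncorrelated spiking)."""
        cfg = NetworkConfig(N=2, w_max=0.04, tau_s=0.01, lambda0=0.15, seed=8)
        est = he.track_mean_drift(cfg, np.zeros((2, 2)), fig2_window, 4e4, seed=51)
        expected = fig2_window.f0 * 0.15**2
        off = ~np.eye(2, dtype=bool)
        emp, se = est.average(off)
        assert abs(emp - expected) < 3 * se

    def test_homogeneous_assembly_matches_closed_form(self, fig2_window, small_config):
        W = build_homogeneous_assembly(10, small_config)
        est = he.track_mean_drift(small_config, W, fig2_window, 2e4, seed=61)
        th = theory.drift_homogeneous(10, 0.04, 0.15, fig2_window, 0.01)
        off = ~np.eye(10, dtype=bool)
        emp, se = est.average(off)
        assert abs(emp - th) < 3 * se

    def test_drift_linear_in_mu(self, fig2_window, small_config):
        W = build_homogeneous_assembly(6, small_config)
        cfg = NetworkConfig(N=6, w_max=0.04, tau_s=0.01, lambda0=0.15, seed=9)
        a = he.track_mean_drift(cfg, W[:6, :6], fig2_window.with_mu(0.5), 2e3, seed=71)
        b = he.track_mean_drift(cfg, W[:6, :6], fig2_window.with_mu(1.0), 2e3, seed=71)
        np.testing.assert_allclose(b.mean, 2.0 * a.mean, rtol=1e-10)

    def test_too_few_batches_rejected(self, fig2_window, small_config):
        W = build_homogeneous_assembly(5, small_config)
        with pytest.raises(ValueError):
            he.track_mean_drift(small_config, W, fig2_window, 1e3, n_batches=3)


class TestEmpiricalEstimators:
    def test_rates_trivial_cases(self):
        rec = he.SpikeRecord(np.array([]), np.array([], dtype=int), N=3, t_end=100.0)
        np.testing.assert_array_equal(he.empirical_rates(rec), np.zeros(3))
        rec = he.SpikeRecord(np.linspace(0, 999, 150), np.zeros(150, dtype=int),
                             N=2, t_end=1000.0)
        assert he.empirical_rates(rec)[0] == pytest.approx(0.15)
        with pytest.raises(ValueError):
            he.empirical_rates(rec, (50.0, 50.0))

    def test_independent_poisson_correlogram_is_flat(self):
        cfg = NetworkConfig(N=2, w_max=0.04, tau_s=0.01, lambda0=1.0, seed=10)
        res = he.simulate(cfg, np.zeros((2, 2)), duration=5e4, seed=81)
        lags, C = he.empirical_cross_correlation(res.record, (0, 1), 0.05, 0.01)
        # product of rates = 1.0 Hz^2; each bin count ~ Poisson(T*bin*r1*r2)
        sd = np.sqrt(5e4 * 0.01 * 1.0) / (5e4 * 0.01)
        assert np.all(np.abs(C - 1.0) < 4 * sd)

    def test_two_neuron_network_matches_spectral_theory(self):
        """Correlogram of a reciprocal pair matches the inverse transform of
        the analytic cross-spectrum."""
        cfg = NetworkConfig(N=2, w_max=0.05, tau_s=0.01, lambda0=0.5, seed=11)
        W = np.array([[0.0, 0.04], [0.04, 0.0]])
        T = 2e5
        res = he.simulate(cfg, W, duration=T, seed=91)
        lags, C = he.empirical_cross_correlation(res.record, (0, 1), 0.05, 0.005,
                                                warmup=1.0)
        C_th = theory.correlation_function(W, 0.5, 0.01, lags, 0, 1)
        sd = np.sqrt(C_th / (T * 0.005))  # Poisson count error per bin
        assert np.all(np.abs(C - C_th) < 5 * sd)

    def test_autocorrelogram_central_bin_finite(self):
        cfg = NetworkConfig(N=1, w_max=0.04, tau_s=0.01, lambda0=2.0, seed=12)
        res = he.simulate(cfg, np.zeros((1, 1)), duration=1e4, seed=101)
        lags, C = he.empirical_cross_correlation(res.record, (0, 0), 0.02, 0.004)
        center = np.argmin(np.abs(lags))
        assert np.isfinite(C[center])
        assert C[center] == pytest.approx(4.0, rel=0.5)  # r^2, self-pairs excluded

    def test_bin_wider_than_window_rejected(self):
        rec = he.SpikeRecord(np.array([0.1]), np.array([0]), N=1, t_end=1.0)
        with pytest.raises(ValueError):
            he.empirical_cross_correlation(rec, (0, 0), max_lag=0.01, bin_width=0.02)


class TestStimulationAndSchedules:
    def test_source_drives_target_rate(self):
        """A Poisson source with weight w_in raises the target rate by
        rate * w_in (unit-integral kernel)."""
        cfg = NetworkConfig(N=2, w_max=0.04, tau_s=0.01, lambda0=0.1, seed=13)
        stim = StimulusProtocol(sources=[dict(rate=5.0, targets=[0], w_in=0.3,
                                              t_on=0.0, t_off=1e4)])
        res = he.simulate(cfg, np.zeros((2, 2)), protocol=stim, duration=1e4, seed=111)
        rates = he.empirical_rates(res.record)
        assert rates[0] == pytest.approx(0.1 + 5.0 * 0.3, rel=0.1)
        assert rates[1] == pytest.approx(0.1, abs=4 * np.sqrt(0.1 / 1e4))
        # source spikes are tagged beyond N
        assert np.any(res.record.ids >= 2)
        assert np.sum(res.record.ids == 2) == pytest.approx(5.0 * 1e4, rel=0.1)

    def test_source_window_respected(self):
        cfg = NetworkConfig(N=1, w_max=0.04, tau_s=0.01, lambda0=0.05, seed=14)
        stim = StimulusProtocol(sources=[dict(rate=20.0, targets=[0], w_in=0.5,
                                              t_on=100.0, t_off=200.0)])
        res = he.simulate(cfg, np.zeros((1, 1)), protocol=stim, duration=300.0, seed=121)
        src = res.record.times[res.record.ids == 1]
        assert len(src) > 0
        assert src.min() >= 100.0 and src.max() < 200.0

    def test_rate_schedule_changes_rates(self):
        cfg = NetworkConfig(N=2, w_max=0.04, tau_s=0.01, lambda0=1.0, seed=15)
        sched = RateModulationSchedule(
            epochs=[dict(t_start=0.0, t_end=5e3, overrides={0: 0.0})]
        )
        res = he.simulate(cfg, np.zeros((2, 2)), schedule=sched, duration=1e4, seed=131)
        early = he.empirical_rates(res.record, (0.0, 5e3))
        late = he.empirical_rates(res.record, (5e3, 1e4))
        assert early[0] == 0.0
        assert late[0] == pytest.approx(1.0, rel=0.2)
        assert early[1] == pytest.approx(1.0, rel=0.2)


class TestPlasticRun:
    def test_plastic_weights_stay_in_bounds_and_snapshots_consistent(self, fig2_window):
        cfg = NetworkConfig(N=12, w_max=0.04, tau_s=0.01, lambda0=0.3, seed=16)
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0, 0.01, (12, 12))
        np.fill_diagonal(W0, 0.0)
        res = he.simulate(cfg, W0, window=fig2_window.with_mu(0.1), duration=2e3,
                          snapshot_every=1e3, seed=141)
        assert res.status == "ok"
        assert [t for t, _ in res.snapshots] == [0.0, 1e3, 2e3]
        for _, W in res.snapshots:
            assert np.all(W >= 0) and np.all(W <= 0.04)
            assert np.all(np.diag(W) == 0)
        np.testing.assert_array_equal(res.snapshots[-1][1], res.W_final)
        assert res.clip_floor > 0  # depression-dominated rule hits the floor

    def test_mask_respected_under_plasticity(self, fig2_window):
        N = 8
        mask = np.ones((N, N), dtype=bool)
        np.fill_diagonal(mask, False)
        mask[0, 1] = mask[1, 0] = False
        cfg = NetworkConfig(N=N, w_max=0.04, tau_s=0.01, lambda0=1.0, mask=mask, seed=17)
        W0 = np.full((N, N), 0.02) * mask
        res = he.simulate(cfg, W0, window=fig2_window.with_mu(0.5), duration=2e3, seed=151)
        assert res.W_final[0, 1] == 0.0 and res.W_final[1, 0] == 0.0
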
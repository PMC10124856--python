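import numpy as np
import pytest

from stdpnet.model_core import NetworkConfig, STDPWindow, build_intertwined
from stdpnet import theory
from conftest import substochastic_weights


class TestTransferFunctions:
    def test_kernel_at_zero_and_decay(self):
        assert theory.kernel_transform(0.01, 0.0) == 1.0
        assert abs(theory.kernel_transform(0.01, 1e6)) < 1e-2

    def test_window_transform_at_zero_is_f0(self, fig2_window):
        assert theory.window_transform(fig2_window, 0.0) == pytest.approx(-0.00133)
        assert theory.window_transform(fig2_window, 1e7) == pytest.approx(0.0, abs=1e-12)

    def test_window_transform_is_fourier_transform(self, fig2_window):
        """Check F~(omega) against direct numeric integration of F."""
        from scipy.integrate import quad
        from stdpnet.stdp_rule import window_value

        for om in (0.0, 10.0, 57.0):
            direct = quad(
                lambda t: window_value(fig2_window, t) * np.cos(om * t), 0, 2.0,
                epsabs=1e-14,
            )[0] * 2.0
            assert theory.window_transform(fig2_window, om) == pytest.approx(direct, rel=1e-6)


class TestRates:
    def test_zero_weights(self):
        r = theory.stationary_rates(np.zeros((3, 3)), [0.1, 0.2, 0.3])
        np.testing.assert_allclose(r, [0.1, 0.2, 0.3])

    def test_homogeneous_matches_branching_formula(self, fig2_window):
        # N=11, w=0.04: rho=0.4, r = 0.15/0.6 = 0.25 Hz
        W = np.full((11, 11), 0.04)
        np.fill_diagonal(W, 0.0)
        r = theory.stationary_rates(W, 0.15)
        np.testing.assert_allclose(r, 0.25, rtol=1e-12)
        ra, rho = theory.assembly_rate(11, 0.04, 0.15)
        assert rho == pytest.approx(0.4)
        assert ra == pytest.approx(0.25)

    def test_assembly_rate_examples(self):
        r, rho = theory.assembly_rate(1, 0.04, 0.15)
        assert (r, rho) == (0.15, 0.0)
        r, rho = theory.assembly_rate(10, 0.04, 0.15)
        assert rho == pytest.approx(0.36)
        assert r == pytest.approx(0.15 / 0.64)

    def test_supercritical_raises(self):
        # N = 26 at w=0.04 sits exactly at the stationarity limit
        with pytest.raises(theory.NoStationaryStateError):
            theory.assembly_rate(26, 0.04, 0.15)
        W = np.full((30, 30), 0.04)
        np.fill_diagonal(W, 0.0)
        with pytest.raises(theory.NoStationaryStateError):
            theory.stationary_rates(W, 0.15)

    def test_rates_at_least_baseline(self, rng):
        W = substochastic_weights(rng, 8)
        r = theory.stationary_rates(W, 0.15)
        assert np.all(r >= 0.15 - 1e-12)


class TestCorrelationSpectrum:
    def test_zero_weights_gives_rate_diagonal(self):
        C = theory.correlation_spectrum(np.zeros((3, 3)), [0.1, 0.2, 0.3], 0.01,
                                        np.array([0.0, 5.0]))
        for k in range(2):
            np.testing.assert_allclose(C[k], np.diag([0.1, 0.2, 0.3]), atol=1e-14)

    def test_hermitian_symmetry(self, rng):
        W = substochastic_weights(rng, 4)
        om = np.array([3.0])
        C_plus = theory.correlation_spectrum(W, 0.2, 0.01, om)[0]
        C_minus = theory.correlation_spectrum(W, 0.2, 0.01, -om)[0]
        np.testing.assert_allclose(C_minus, np.conj(C_plus), rtol=1e-12)


class TestDriftMatrix:
    def test_zero_weights_pure_rate_term(self, fig2_window):
        lam = np.array([0.1, 0.2, 0.3])
        dm = theory.drift_matrix(np.zeros((3, 3)), lam, fig2_window, 0.01)
        expected = fig2_window.f0 * np.outer(lam, lam)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(dm, expected, rtol=1e-7)

    def test_symmetric_for_random_weights(self, fig2_window, rng):
        """The even window makes the drift matrix symmetric for any W."""
        W = substochastic_weights(rng, 6)
        dm = theory.drift_matrix(W, 0.15, fig2_window, 0.01)
        np.testing.assert_allclose(dm, dm.T, atol=1e-12)

    def test_matches_closed_form_on_homogeneous_assembly(self, fig2_window):
        N, w = 8, 0.05
        W = np.full((N, N), w)
        np.fill_diagonal(W, 0.0)
        dm = theory.drift_matrix(W, 0.15, fig2_window, 0.01)
        off = ~np.eye(N, dtype=bool)
        cf = theory.drift_homogeneous(N, w, 0.15, fig2_window, 0.01)
        assert np.max(np.abs(dm[off] - cf) / abs(cf)) < 1e-6

    def test_scales_linearly_with_mu(self, fig2_window, rng):
        W = substochastic_weights(rng, 4)
        a = theory.drift_matrix(W, 0.15, fig2_window.with_mu(0.5), 0.01)
        b = theory.drift_matrix(W, 0.15, fig2_window.with_mu(1.0), 0.01)
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-9)


class TestMotifCoefficients:
    def test_f00_is_window_at_zero(self, fig2_window):
        mc = theory.motif_coefficients(fig2_window, 0.01, 2)
        # f_00 = (1/2pi) int F~ = F(0) = A_p + A_d
        assert mc.f_ab[0, 0] == pytest.approx(0.0267, rel=1e-6)

    def test_f10_closed_form(self, fig2_window):
        # f_10 = int F(t) a(t) dt = A_p tau_p/(tau_s+tau_p) + A_d tau_d/(tau_s+tau_d)
        mc = theory.motif_coefficients(fig2_window, 0.01, 2)
        closed = (
            0.08 * 0.025 / (0.01 + 0.025) + (-0.0533) * 0.05 / (0.01 + 0.05)
        )
        assert mc.f_ab[1, 0] == pytest.approx(closed, rel=1e-6)
        assert mc.f_ab[0, 1] == pytest.approx(closed, rel=1e-6)

    def test_f_ab_symmetry(self, fig2_window):
        mc = theory.motif_coefficients(fig2_window, 0.01, 4)
        for a in range(5):
            for b in range(5 - a):
                assert mc.f_ab[a, b] == pytest.approx(mc.f_ab[b, a], rel=1e-8)

    def test_limit_value(self, fig2_window):
        mc = theory.motif_coefficients(fig2_window, 0.01, 2)
        assert mc.limit == pytest.approx(-0.0665, rel=1e-6)


class TestHomogeneousDrift:
    def test_small_N_value_and_condition(self, fig2_window):
        # growth condition sides: 5.17e-5 > 4.35e-5
        d = theory.drift_small_N(0.04, 0.15, fig2_window, 0.01)
        assert d == pytest.approx(1.2279e-4, rel=1e-3)
        assert theory.growth_condition(0.04, 0.15, fig2_window, 0.01)

    def test_closed_form_agrees_with_small_N_at_N2(self, fig2_window):
        full = theory.drift_homogeneous(2, 0.04, 0.15, fig2_window, 0.01)
        approx = theory.drift_small_N(0.04, 0.15, fig2_window, 0.01)
        assert full == pytest.approx(approx, rel=0.05)

    def test_growth_condition_equals_small_N_sign(self, fig2_window):
        for w in (1e-4, 1e-3, 0.01, 0.04, 0.1):
            cond = theory.growth_condition(w, 0.15, fig2_window, 0.01)
            assert cond == (theory.drift_small_N(w, 0.15, fig2_window, 0.01) > 0)

    def test_vanishing_weight_limit_negative(self, fig2_window):
        # w -> 0: rate-rate term dominates, f0 lam^2 < 0, no assembly growth
        assert theory.drift_small_N(0.0, 0.15, fig2_window, 0.01) < 0

    def test_divergence_near_size_limit(self, fig2_window):
        n_lim = 1 + 1 / 0.04
        vals = [
            theory.drift_homogeneous(n_lim - eps, 0.04, 0.15, fig2_window, 0.01)
            for eps in (0.1, 0.01, 0.001)
        ]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < -1.0

    def test_out_of_range_raises(self, fig2_window):
        with pytest.raises(theory.NoStationaryStateError):
            theory.drift_homogeneous(26.0, 0.04, 0.15, fig2_window, 0.01)

    def test_asymptote_matches_near_limit(self, fig2_window):
        n = 1 + 1 / 0.04 - 0.01
        full = theory.drift_homogeneous(n, 0.04, 0.15, fig2_window, 0.01)
        asym = theory.drift_asymptote(n, 0.04, 0.15, fig2_window, 0.01)
        assert full / asym == pytest.approx(1.0, abs=0.1)
        assert asym < 0  # sign(f0)

    def test_series_converges_to_closed_form(self, fig2_window):
        for N, w in ((5, 0.04), (10, 0.04), (13, 0.04), (9, 0.06)):
            rho = (N - 1) * w
            assert rho <= 0.5
            s, tail = theory.drift_series_homogeneous(N, w, 0.15, fig2_window, 0.01, 50)
            cf = theory.drift_homogeneous(N, w, 0.15, fig2_window, 0.01)
            assert abs(s - cf) / abs(cf) < 1e-4

    def test_truncated_low_order_has_zero_crossing(self, fig2_window):
        vals = [
            theory.drift_truncated_low_order(n, 0.04, 0.15, fig2_window, 0.01)
            for n in (2.0, 10.0, 25.9)
        ]
        assert vals[0] > 0 and vals[-1] < 0


class TestSizePrediction:
    def test_ordering_and_monotonicity(self, fig2_window):
        zeros = []
        for w in (0.03, 0.04, 0.05, 0.06):
            pred = theory.predicted_assembly_size(w, 0.15, fig2_window, 0.01)
            assert pred.has_positive_max
            assert pred.N_max < pred.N_zero < pred.N_limit
            zeros.append(pred.N_zero)
        assert all(a > b for a, b in zip(zeros, zeros[1:]))

    def test_tiny_weight_no_positive_maximum(self, fig2_window):
        pred = theory.predicted_assembly_size(1e-4, 0.15, fig2_window, 0.01)
        assert not pred.has_positive_max
        assert pred.N_max is None and pred.N_zero is None

    def test_zero_is_a_root(self, fig2_window):
        pred = theory.predicted_assembly_size(0.04, 0.15, fig2_window, 0.01)
        val = theory.drift_homogeneous(pred.N_zero, 0.04, 0.15, fig2_window, 0.01)
        assert abs(val) < 1e-10


class TestSparseAssemblyDrift:
    def test_dilution_shifts_zero_to_larger_sizes(self, fig2_window):
        """At a size just past the full-connectivity zero crossing the drift
        is already negative, but with intra-assembly connection probability
        0.7 it is still positive: sparsity moves the predicted size up."""
        w = 0.058
        pred = theory.predicted_assembly_size(w, 0.15, fig2_window, 0.01)
        N = int(np.ceil(pred.N_zero)) + 1
        full = theory.drift_homogeneous(N, w, 0.15, fig2_window, 0.01)
        sparse, se = theory.drift_sparse_homogeneous(
            N, w, 0.15, fig2_window, 0.01, p=0.7, n_samples=10, seed=2
        )
        assert full < 0
        assert sparse - 3 * se > 0


class TestMotifLimitGenerality:
    @pytest.mark.parametrize(
        "win",
        [
            STDPWindow(0.05, -0.02, 0.01, 0.08),
            STDPWindow(0.2, -0.12, 0.03, 0.04),
        ],
    )
    def test_f_k_limit_for_arbitrary_valid_windows(self, win):
        mc = theory.motif_coefficients(win, 0.012, 40)
        rel = abs(mc.f_k[40] - mc.limit) / abs(mc.limit)
        assert rel < 0.10


class TestOverlapRule:
    def test_published_operating_point(self):
        # N=20 assemblies at w=0.0158: prescribed overlap-neuron rate ~0.086 Hz
        lam_x = theory.overlap_rate_rule(0.15, 20, 0.0158)
        assert lam_x == pytest.approx(0.0857, abs=5e-4)

    def test_round_trip_identity(self):
        for N, w in ((20, 0.0158), (10, 0.03), (15, 0.02)):
            lam_x = theory.overlap_rate_rule(0.15, N, w)
            r_x = theory.overlap_neuron_rate(lam_x, 0.15, N, w)
            assert r_x == pytest.approx(0.15 / (1 - (N - 1) * w), rel=1e-12)

    def test_zero_weight_limit(self):
        assert theory.overlap_rate_rule(0.15, 20, 0.0) == pytest.approx(0.15)

    def test_infeasible_branching(self):
        with pytest.raises(theory.NoStationaryStateError):
            theory.overlap_rate_rule(0.15, 20, 0.03)  # rho = 0.57 > 1/2


class TestIntertwinedDriftSigns:
    def test_published_pattern_is_stable_in_mean_field(self):
        """At the published operating point the intra-assembly drift is
        positive (weights restored) and the extra-pair drift negative."""
        win = STDPWindow(A_p=0.08, A_d=-0.042, tau_p=0.026, tau_d=0.065)
        n_A, w = 7, 0.015  # scaled-down pattern, same sign structure
        N = n_A * (n_A + 1) // 2
        cfg = NetworkConfig(N=N, w_max=w, tau_s=0.01, lambda0=0.15)
        W0, _ = build_intertwined(n_A, cfg)
        dm = theory.drift_matrix(W0, 0.15, win, 0.01, epsrel=1e-6)
        off = ~np.eye(N, dtype=bool)
        assert dm[W0 > 0].mean() > 0
        assert dm[(W0 == 0) & off].mean() < 0


class TestMinInputWeight:
    def test_bound_exists_at_published_stimulation(self, fig2_window):
        """At the published input rate the required weight is far below the
        10*w_max actually used for stimulation."""
        win = STDPWindow(A_p=0.08, A_d=-0.066, tau_p=0.035, tau_d=0.05)
        cfg = NetworkConfig(N=20, w_max=0.026, tau_s=0.01, lambda0=0.15)
        bound = theory.min_input_weight(cfg, win, group_size=20, input_rate=4.18)
        assert bound is not None
        assert bound <= 10 * 0.026

    def test_monotone_at_low_rates(self):
        """Below the rate where quadratic rate-rate depression takes over,
        stronger input rates need weaker input weights."""
        win = STDPWindow(A_p=0.08, A_d=-0.066, tau_p=0.035, tau_d=0.05)
        cfg = NetworkConfig(N=10, w_max=0.026, tau_s=0.01, lambda0=0.15)
        b_hi = theory.min_input_weight(cfg, win, group_size=10, input_rate=2.0)
        b_lo = theory.min_input_weight(cfg, win, group_size=10, input_rate=0.5)
        assert b_hi is not None and b_lo is not None
        assert b_hi <= b_lo * 1.01

    def test_vanishing_rate_gives_no_bound(self):
        win = STDPWindow(A_p=0.08, A_d=-0.066, tau_p=0.035, tau_d=0.05)
        cfg = NetworkConfig(N=10, w_max=0.026, tau_s=0.01, lambda0=0.15)
        assert theory.min_input_weight(cfg, win, group_size=10, input_rate=1e-4,
                                       w_cap_factor=50) is None
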
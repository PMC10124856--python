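"""Mean-field theory of time-averaged weight drift in Hawkes networks.

For a network of linear Poisson neurons with weight matrix W, spontaneous
rates lambda0 and unit-integral synaptic kernel a(t) = Theta(t)/tau_s *
exp(-t/tau_s), the stationary rates are r = (1-W)^{-1} lambda0 and the
spike-train cross-spectrum is

    C~(omega) = 2 pi delta(omega) r r^T
                + (1 - a~(omega) W)^{-1} D (1 - a~(-omega) W^T)^{-1},

with D = diag(r) and a~(omega) = 1/(1 + i omega tau_s).  Under quasistationary
weight dynamics the time-averaged drift of W[i, j] is the overlap of C_ij with
the STDP window,

    dW~_ij = f0 r_i r_j + (1/2pi) integral of M_ij(omega) F~(omega),

where M is the smooth spectral term and f0 = F~(0) = 2 (A_p tau_p + A_d tau_d)
is the window integral.  Expanding M in powers of W yields the motif series
with coefficients f_ab; for a homogeneous all-to-one-weight assembly of size N
the drift collapses to a closed form dW~(N) whose positive maximum and zero
crossing predict the preferred and the attained assembly size, and which
diverges to -inf as N -> 1 + 1/w_max when f0 < 0.

All drift values carry the window's learning-rate factor mu and have units of
1/s (weights are dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, quad_vec
from scipy.optimize import brentq, minimize_scalar

from .model_core import NetworkConfig, STDPWindow


class NoStationaryStateError(RuntimeError):
    """Spectral radius of W >= 1: firing rates diverge."""


# ---------------------------------------------------------------------------
# transfer functions


def kernel_transform(tau_s: float, omega: np.ndarray | float) -> np.ndarray | complex:
    """Fourier transform of the unit-integral synaptic kernel: 1/(1+i omega tau_s)."""
    return 1.0 / (1.0 + 1j * np.asarray(omega) * tau_s)


def window_transform(window: STDPWindow, omega: np.ndarray | float) -> np.ndarray | float:
    """Fourier transform of the STDP window (real and even):

    F~(omega) = mu * [2 A_p tau_p/(1+omega^2 tau_p^2) + 2 A_d tau_d/(1+omega^2 tau_d^2)].
    """
    w2 = np.asarray(omega) ** 2
    return window.mu * (
        2.0 * window.A_p * window.tau_p / (1.0 + w2 * window.tau_p**2)
        + 2.0 * window.A_d * window.tau_d / (1.0 + w2 * window.tau_d**2)
    )


def transfer_functions(window: STDPWindow, tau_s: float, omega):
    """(a~(omega), F~(omega)) on the given frequencies."""
    return kernel_transform(tau_s, omega), window_transform(window, omega)


def f0(window: STDPWindow) -> float:
    """Window integral including mu: F~(0)."""
    return window.mu * window.f0


def _window_tail_integral(window: STDPWindow, Omega: float) -> float:
    """Exact integral over [Omega, inf) of F~(omega) domega (arctan closed form)."""
    return window.mu * (
        2.0 * window.A_p * (np.pi / 2 - np.arctan(Omega * window.tau_p))
        + 2.0 * window.A_d * (np.pi / 2 - np.arctan(Omega * window.tau_d))
    )


# ---------------------------------------------------------------------------
# rates and correlations


def spectral_radius(W: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(W, dtype=float)))))


def stationary_rates(W: np.ndarray, lambda0: np.ndarray | float) -> np.ndarray:
    """Stationary trial-averaged rates r = (1-W)^{-1} lambda0 (Hz)."""
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    lam = np.broadcast_to(np.asarray(lambda0, dtype=float), (N,))
    if spectral_radius(W) >= 1.0:
        raise NoStationaryStateError(
            "spectral radius >= 1: no stationary network state, firing rates diverge"
        )
    return np.linalg.solve(np.eye(N) - W, lam)


def assembly_rate(N: float, w_max: float, lambda0: float) -> tuple[float, float]:
    """Rate and branching parameter of a homogeneous assembly.

    r = lambda0 / (1 - rho) with rho = (N-1) * w_max, the mean number of
    spikes directly triggered by one spike inside the assembly.
    """
    rho = (N - 1.0) * w_max
    if rho >= 1.0:
        raise NoStationaryStateError(f"branching parameter rho={rho:.3f} >= 1")
    return lambda0 / (1.0 - rho), rho


def correlation_spectrum(
    W: np.ndarray, lambda0: np.ndarray | float, tau_s: float, omega: np.ndarray
) -> np.ndarray:
    """Smooth (interdependence) part of the cross-spectrum on an omega grid:
    (1-a~(omega)W)^{-1} D (1-a~(-omega)W^T)^{-1} per frequency.

    Returns an array of shape (len(omega), N, N); the delta-function
    rate-outer-product term at omega=0 is left to the caller.
    """
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    r = stationary_rates(W, lambda0)
    D = np.diag(r)
    I = np.eye(N)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    out = np.empty((len(omega), N, N), dtype=complex)
    for k, om in enumerate(omega):
        a = kernel_transform(tau_s, om)
        L = np.linalg.inv(I - a * W)
        R = np.linalg.inv(I - np.conj(a) * W.T)
        out[k] = L @ D @ R
    return out


def correlation_function(
    W: np.ndarray,
    lambda0: np.ndarray | float,
    tau_s: float,
    lags: np.ndarray,
    i: int,
    j: int,
    Omega: float | None = None,
) -> np.ndarray:
    """C_ij(tau) on a lag grid by numeric inverse Fourier transform.

    Includes the constant r_i*r_j background but not the i==j Poisson
    delta-spike at zero lag.  Intended as a small-n oracle for the empirical
    correlogram estimator.
    """
    W = np.asarray(W, dtype=float)
    r = stationary_rates(W, lambda0)
    D = np.diag(r)
    I = np.eye(W.shape[0])
    if Omega is None:
        Omega = 50.0 / tau_s

    def smooth_ij(om):
        a = kernel_transform(tau_s, om)
        L = np.linalg.inv(I - a * W)
        R = np.linalg.inv(I - np.conj(a) * W.T)
        return (L @ D @ R)[i, j]

    lags = np.asarray(lags, dtype=float)
    out = np.empty_like(lags)
    base = D[i, i] if i == j else 0.0  # flat delta contribution excluded for i==j
    for k, tau in enumerate(lags):
        val = quad_vec(
            lambda om: np.real((smooth_ij(om) - base) * np.exp(1j * om * tau)) / np.pi,
            0.0,
            Omega,
            epsrel=1e-8,
            epsabs=1e-14,
        )[0]
        out[k] = val + r[i] * r[j]
    return out


# ---------------------------------------------------------------------------
# drift by quadrature (general W)


def drift_matrix(
    W: np.ndarray,
    lambda0: np.ndarray | float,
    window: STDPWindow,
    tau_s: float,
    epsrel: float = 1e-8,
) -> np.ndarray:
    """Time-averaged drift matrix dW~ (1/s) for arbitrary W by quadrature.

    dW~ = f0 r r^T + (1/pi) integral on [0, Omega] of Re[M(omega)] F~(omega) domega + tail,
    using the Hermitian symmetry M(-omega) = conj(M(omega)) and the evenness
    of F~.  The tail beyond Omega uses M(omega) -> D and the closed-form tail
    integral of F~.  Diagonal entries are zeroed (no self-interaction).
    """
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    r = stationary_rates(W, lambda0)
    D = np.diag(r)
    I = np.eye(N)
    Omega = 1e3 / min(window.tau_p, tau_s)

    def integrand(om: float) -> np.ndarray:
        a = kernel_transform(tau_s, om)
        L = np.linalg.solve(I - a * W, D)
        M = np.linalg.solve((I - np.conj(a) * W.T).T, L.T).T
        return np.real(M) * window_transform(window, om)

    integral, _err = quad_vec(integrand, 0.0, Omega, epsrel=epsrel, epsabs=1e-16)
    tail = D * _window_tail_integral(window, Omega)
    out = f0(window) * np.outer(r, r) + (integral + tail) / np.pi
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# motif expansion


@dataclass
class MotifCoefficients:
    """Motif coefficients f_ab for a + b <= K and their diagonal sums f_k.

    f_ab weighs the motif in which a common source neuron reaches the post-
    and presynaptic neuron through chains of a and b synapses; f_k sums all
    motifs of total order k and converges to f0/(2 tau_s) as k -> inf.
    """

    K: int
    f_ab: np.ndarray  # (K+1, K+1), NaN above the anti-diagonal a+b>K
    window: STDPWindow = None
    tau_s: float = None

    @property
    def f_k(self) -> np.ndarray:
        out = np.empty(self.K + 1)
        for k in range(self.K + 1):
            out[k] = sum(self.f_ab[a, k - a] for a in range(k + 1))
        return out

    @property
    def limit(self) -> float:
        """High-order limit of f_k: f0 / (2 tau_s)."""
        return f0(self.window) / (2.0 * self.tau_s)


def motif_coefficients(window: STDPWindow, tau_s: float, K: int) -> MotifCoefficients:
    """Compute f_ab = (1/2pi) integral of F~(-omega) a~(omega)^a a~(-omega)^b domega.

    Evaluated by quadrature on the folded half-line (the integrand's negative-
    frequency half is the complex conjugate).  Tail beyond the cutoff is
    negligible at the tolerances used (integrand decays at least as omega^-2
    times omega^-(a+b)); for a = b = 0 the exact tail of F~ is added.
    """
    Omega = 1e3 / min(window.tau_p, tau_s)
    f_ab = np.full((K + 1, K + 1), np.nan)
    for a in range(K + 1):
        for b in range(K + 1 - a):
            def g(om: float, a=a, b=b) -> float:
                av = kernel_transform(tau_s, om)
                return np.real(av**a * np.conj(av) ** b) * window_transform(window, om)

            val = quad(g, 0.0, Omega, epsrel=1e-10, epsabs=1e-16, limit=400)[0]
            if a == 0 and b == 0:
                val += _window_tail_integral(window, Omega)
            f_ab[a, b] = val / np.pi
    return MotifCoefficients(K=K, f_ab=f_ab, window=window, tau_s=tau_s)


def drift_series_homogeneous(
    N: float,
    w_max: float,
    lambda0: float,
    window: STDPWindow,
    tau_s: float,
    K: int,
    coeffs: MotifCoefficients | None = None,
) -> tuple[float, float]:
    """Motif-series drift for a homogeneous assembly, truncated at order K.

    dW~ = f0 r^2 + (r/N) * sum_{k=1..K} f_k ((N-1)^k - (-1)^k) w_max^k.

    Returns (partial sum, geometric tail bound on the truncation error).
    The series converges for rho = (N-1) w_max < 1; near rho = 1 convergence
    is slow and the tail estimate reflects that.
    """
    r, rho = assembly_rate(N, w_max, lambda0)
    if coeffs is None or coeffs.K < K:
        coeffs = motif_coefficients(window, tau_s, K)
    fk = coeffs.f_k
    total = f0(window) * r**2
    for k in range(1, K + 1):
        total += (r / N) * fk[k] * ((N - 1.0) ** k - (-1.0) ** k) * w_max**k
    # tail bound: |f_k| -> |f0|/(2 tau_s); terms ~ (r/N) * c * rho^k
    c = abs(f0(window)) / (2.0 * tau_s) * 2.0
    tail = (r / N) * c * rho ** (K + 1) / max(1.0 - rho, 1e-12) if rho < 1 else np.inf
    return total, tail


def drift_truncated_low_order(
    N: float, w_max: float, lambda0: float, window: STDPWindow, tau_s: float
) -> float:
    """Drift truncated to direct connections and common presynaptic inputs.

    Keeps only f0, f_10, f_01 and f_11 of the motif expansion -- the variant
    that ignores longer cascades; it still has a maximum and a zero but at
    shifted positions.
    """
    coeffs = motif_coefficients(window, tau_s, 2)
    r, _ = assembly_rate(N, w_max, lambda0)
    f10 = coeffs.f_ab[1, 0]
    f01 = coeffs.f_ab[0, 1]
    f11 = coeffs.f_ab[1, 1]
    # homogeneous assembly: sum_m r (W^a)_im (W^b)_jm with W = w_max off-diag
    # order 1: (N-1)^1 - (-1)^1 -> via generic formula at k=1,2 restricted
    out = f0(window) * r**2
    out += (r / N) * (f10 + f01) * ((N - 1.0) - (-1.0)) * w_max
    out += (r / N) * f11 * ((N - 1.0) ** 2 - 1.0) * w_max**2
    return out


# ---------------------------------------------------------------------------
# homogeneous-assembly closed forms


def _n_limit(w_max: float) -> float:
    return 1.0 + 1.0 / w_max


def drift_homogeneous(
    N: float | np.ndarray, w_max: float, lambda0: float, window: STDPWindow, tau_s: float
) -> float | np.ndarray:
    """Closed-form time-averaged drift dW~(N) inside a homogeneous assembly.

    Three terms: the rate-rate (uncorrelated spiking) term and the correlated
    potentiation and depression terms.  N may be a float (its discreteness is
    neglected) but must satisfy 1 <= N < 1 + 1/w_max.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N >= _n_limit(w_max)) or np.any(N < 1.0):
        raise NoStationaryStateError(
            f"N must lie in [1, {_n_limit(w_max):.3f}) for a stationary assembly"
        )
    w = w_max
    lam = lambda0
    Ap, Ad = window.A_p, window.A_d
    tp, td = window.tau_p, window.tau_d
    ts = tau_s
    one_minus_rho = 1.0 - (N - 1.0) * w
    rate_term = 2.0 * lam**2 * (Ap * tp + Ad * td) / one_minus_rho**2

    def corr_term(A, tx):
        num = lam * A * tx * w * (
            (2.0 - (N - 2.0) * w) * tx + (2.0 - (N - 2.0) * w - (N - 1.0) * w**2) * ts
        )
        den = (
            (1.0 + w)
            * one_minus_rho**2
            * (ts + (1.0 + w) * tx)
            * (ts + one_minus_rho * tx)
        )
        return num / den

    out = window.mu * (rate_term + corr_term(Ap, tp) + corr_term(Ad, td))
    return float(out) if out.ndim == 0 else out


def drift_small_N(w_max: float, lambda0: float, window: STDPWindow, tau_s: float) -> float:
    """Small-assembly drift approximation (N small, N*w_max << 1):

    dW~ ~= 2 lam^2 (A_p tau_p + A_d tau_d) + 2 lam A_p tau_p w/(tau_s+tau_p)
           + 2 lam A_d tau_d w/(tau_s+tau_d).
    """
    return window.mu * (
        2.0 * lambda0**2 * (window.A_p * window.tau_p + window.A_d * window.tau_d)
        + 2.0 * lambda0 * window.A_p * window.tau_p * w_max / (tau_s + window.tau_p)
        + 2.0 * lambda0 * window.A_d * window.tau_d * w_max / (tau_s + window.tau_d)
    )


def growth_condition(w_max: float, lambda0: float, window: STDPWindow, tau_s: float) -> bool:
    """Whether small assemblies grow:

    (lam tau_s + w/(1+tau_p/tau_s)) 2 A_p tau_p
        > (lam tau_s + w/(1+tau_d/tau_s)) 2 |A_d| tau_d.

    Algebraically equivalent to drift_small_N > 0.
    """
    lhs = (lambda0 * tau_s + w_max / (1.0 + window.tau_p / tau_s)) * 2.0 * window.A_p * window.tau_p
    rhs = (lambda0 * tau_s + w_max / (1.0 + window.tau_d / tau_s)) * 2.0 * abs(window.A_d) * window.tau_d
    return bool(lhs > rhs)


def drift_asymptote(
    N: float | np.ndarray, w_max: float, lambda0: float, window: STDPWindow, tau_s: float
) -> float | np.ndarray:
    """Asymptotic drift near the size limit N -> 1 + 1/w_max:

    dW~(N) ~ f0 (1 + w/(2 lam tau_s (1+w))) lam^2 / (1-(N-1)w)^2,

    which diverges to -inf when f0 < 0: imprecisely correlated spiking from
    long spike cascades dominates and depresses the weights.
    """
    N = np.asarray(N, dtype=float)
    pref = f0(window) * (1.0 + w_max / (2.0 * lambda0 * tau_s * (1.0 + w_max)))
    out = pref * lambda0**2 / (1.0 - (N - 1.0) * w_max) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class SizePrediction:
    """Characteristic assembly sizes from the drift curve dW~(N)."""

    N_max: float | None  # argmax of the drift (preferred size)
    N_zero: float | None  # zero crossing (attained size)
    N_limit: float  # stationarity bound 1 + 1/w_max
    has_positive_max: bool


def predicted_assembly_size(
    w_max: float, lambda0: float, window: STDPWindow, tau_s: float
) -> SizePrediction:
    """Locate the maximum and zero of dW~(N) on (1, 1 + 1/w_max).

    When the curve is nowhere positive, no assembly can sustain itself and
    the prediction reports has_positive_max=False with N_max = N_zero = None.
    """
    n_lim = _n_limit(w_max)
    eps = 1e-9 * n_lim

    def f(N):
        return drift_homogeneous(N, w_max, lambda0, window, tau_s)

    res = minimize_scalar(
        lambda N: -f(N), bounds=(1.0 + 1e-6, n_lim - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    N_max = float(res.x)
    if f(N_max) <= 0.0:
        return SizePrediction(None, None, n_lim, False)
    # zero crossing between the maximum and the -inf divergence
    hi = n_lim - 1e-9
    # f(hi) must be negative (guaranteed when f0 < 0); widen carefully if not
    lo = N_max
    N_zero = float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))
    return SizePrediction(N_max, N_zero, n_lim, True)


def drift_sparse_homogeneous(
    N: int,
    w_max: float,
    lambda0: float,
    window: STDPWindow,
    tau_s: float,
    p: float,
    n_samples: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean drift of existing intra-assembly weights at connection prob p.

    Averages drift_matrix over random dilution masks of a single assembly:
    each off-diagonal weight is w_max with probability p, else permanently 0.
    Returns (mean over existing entries and samples, SE over samples).  Lower
    p shifts the zero crossing to larger N.
    """
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_samples):
        keep = rng.random((N, N)) < p
        np.fill_diagonal(keep, False)
        W = np.where(keep, w_max, 0.0)
        if spectral_radius(W) >= 0.999:
            continue
        dm = drift_matrix(W, lambda0, window, tau_s, epsrel=1e-6)
        if keep.sum() == 0:
            continue
        means.append(dm[keep].mean())
    means = np.asarray(means)
    if len(means) == 0:
        raise NoStationaryStateError("all sampled sparse assemblies are unstable")
    se = means.std(ddof=1) / np.sqrt(len(means)) if len(means) > 1 else np.nan
    return float(means.mean()), float(se)


# ---------------------------------------------------------------------------
# overlap rate rule


def overlap_rate_rule(lambda0: float, N: float, w_max: float) -> float:
    """Spontaneous rate lam_x0 for a neuron shared by two size-N assemblies:

    lam_x0 = lambda0 (1 - 2(N-1)w) / (1 - (N-1)w),

    chosen so that the overlap neuron's total rate matches a single-assembly
    neuron's rate.  Requires (N-1) w_max < 1/2 for a non-negative rate.
    """
    rho = (N - 1.0) * w_max
    lam = lambda0 * (1.0 - 2.0 * rho) / (1.0 - rho)
    if lam < 0:
        raise NoStationaryStateError(
            f"no feasible overlap rate: branching parameter {rho:.3f} >= 1/2"
        )
    return lam


def overlap_neuron_rate(lambda_x0: float, lambda0: float, N: float, w_max: float) -> float:
    """Total rate of an overlap neuron with baseline lambda_x0:

    r_x = lam_x0 + 2 lambda0/(1-(N-1)w) - 2 lambda0.
    """
    rho = (N - 1.0) * w_max
    return lambda_x0 + 2.0 * lambda0 / (1.0 - rho) - 2.0 * lambda0


# ---------------------------------------------------------------------------
# input-strength bound for assembly learning


def min_input_weight(
    config: NetworkConfig,
    window: STDPWindow,
    group_size: int,
    input_rate: float,
    w_cap_factor: float = 1e3,
    rtol: float = 1e-4,
) -> float | None:
    """Smallest input weight for which common stimulation potentiates a group.

    Considers ``group_size`` initially unconnected neurons plus one external
    Poisson source node of the given rate feeding each of them with weight
    w_in, and searches the mean-field drift of the group-internal weights for
    the smallest w_in with positive drift.  The drift is not monotone in
    w_in -- both the potentiating common-input term and the depressing
    rate-rate term scale as w_in^2, so positive drift exists only on a
    bounded window of input weights (or not at all) -- hence a geometric scan
    locates the first sign change and bisection refines it.  Returns None
    when no w_in up to w_cap_factor * w_max potentiates the group.
    """
    n = group_size
    lam0 = float(np.mean(config.lambda0))

    def group_drift(w_in: float) -> float:
        W = np.zeros((n + 1, n + 1))
        W[:n, n] = w_in  # source (last node) drives every group member
        lam = np.full(n + 1, lam0)
        lam[n] = input_rate
        dm = drift_matrix(W, lam, window, config.tau_s, epsrel=1e-7)
        off = ~np.eye(n, dtype=bool)
        return float(dm[:n, :n][off].mean())

    if group_drift(0.0) > 0:
        return 0.0
    cap = w_cap_factor * config.w_max
    grid = np.geomspace(1e-3 * config.w_max, cap, 60)
    lo = 0.0
    hi = None
    for w in grid:
        if group_drift(w) > 0:
            hi = w
            break
        lo = w
    if hi is None:
        return None
    while (hi - lo) > rtol * max(hi, config.w_max):
        mid = 0.5 * (lo + hi)
        if group_drift(mid) > 0:
            hi = mid
        else:
            lo = mid
    return hi
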
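"""Event-driven simulation of the plastic Hawkes network.

The public entry points are :func:`simulate` (optionally plastic, with
external stimulation sources and spontaneous-rate schedules) and
:func:`track_mean_drift` (frozen weights, STDP increments accumulated but
never applied -- the numerical counterpart of the mean-field drift).

Sampling uses Ogata-style thinning with a bound that is exact because the
total intensity is non-increasing between events; see ``_kernel`` for the
inner loop.  Runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .model_core import (
    NetworkConfig,
    RateModulationSchedule,
    STDPWindow,
    StimulusProtocol,
    check_weight_matrix,
)


class PathologicalActivityError(RuntimeError):
    """The total network intensity exceeded the divergence ceiling."""


@dataclass
class SpikeRecord:
    """Time-sorted spike events; ids >= N tag external-source spikes."""

    times: np.ndarray
    ids: np.ndarray
    N: int
    t_start: float = 0.0
    t_end: float = 0.0

    def network(self) -> "SpikeRecord":
        sel = self.ids < self.N
        return SpikeRecord(self.times[sel], self.ids[sel], self.N, self.t_start, self.t_end)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SimResult:
    record: SpikeRecord
    snapshots: list[tuple[float, np.ndarray]]
    W_final: np.ndarray
    status: str = "ok"
    clip_floor: int = 0
    clip_ceiling: int = 0


@dataclass
class DriftEstimate:
    """Empirical time-averaged weight change (1/s) with batch standard errors.

    ``batch_means`` holds the per-batch drift matrices; use them for the
    standard error of any entry-averaged quantity (entries within a batch
    share spikes and are correlated, so per-entry SEs must not be pooled as
    if independent).
    """

    mean: np.ndarray
    se: np.ndarray
    T: float
    n_batches: int
    batch_means: np.ndarray | None = None

    def average(self, sel: np.ndarray) -> tuple[float, float]:
        """Mean drift over the boolean entry selection, with its batch SE."""
        vals = self.batch_means[:, sel].mean(axis=1)
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


@dataclass
class _EngineState:
    x: np.ndarray
    y: np.ndarray
    zp: np.ndarray
    zd: np.ndarray
    x_src: np.ndarray


def _segment_boundaries(
    duration: float,
    snapshot_every: float | None,
    protocol: StimulusProtocol | None,
    schedule: RateModulationSchedule | None,
) -> np.ndarray:
    pts = {0.0, float(duration)}
    if snapshot_every:
        pts.update(np.arange(0.0, duration, snapshot_every).tolist())
    if protocol is not None:
        for s in protocol.sources:
            for t in (s["t_on"], s["t_off"]):
                if 0.0 < t < duration:
                    pts.add(float(t))
    if schedule is not None:
        for t in schedule.breakpoints():
            if 0.0 < t < duration:
                pts.add(float(t))
    return np.asarray(sorted(pts))


def _source_arrays(protocol: StimulusProtocol | None, N: int):
    if protocol is None or not protocol.sources:
        return np.zeros((0, N)), np.zeros(0), []
    ns = len(protocol.sources)
    C = np.zeros((ns, N))
    rates = np.zeros(ns)
    windows = []
    for s_idx, s in enumerate(protocol.sources):
        idx = np.fromiter(s["targets"], dtype=int)
        C[s_idx, idx] = s["w_in"]
        rates[s_idx] = s["rate"]
        windows.append((s["t_on"], s["t_off"]))
    return C, rates, windows


def simulate(
    config: NetworkConfig,
    W0: np.ndarray,
    window: STDPWindow | None = None,
    protocol: StimulusProtocol | None = None,
    schedule: RateModulationSchedule | None = None,
    duration: float = 1e3,
    snapshot_every: float | None = None,
    seed: int | None = None,
    tracked: bool = False,
    shadow: np.ndarray | None = None,
    ceiling_factor: float = 1e4,
    raise_on_divergence: bool = False,
    buffer_size: int = 1_000_000,
) -> SimResult:
    """Simulate the network for ``duration`` seconds.

    With ``window`` given, weights evolve under the symmetric pair-based STDP
    rule with clipping to [0, w_max]; with ``tracked=True`` the increments are
    instead accumulated (unclipped) into ``shadow`` and W stays frozen.  If
    the total intensity exceeds ``ceiling_factor * sum(lambda0)`` the run is
    aborted with status ``"pathological"`` (or an exception if requested).
    """
    check_weight_matrix(W0, config)
    N = config.N
    W = np.array(W0, dtype=float, copy=True)
    mask = config.effective_mask()
    st = _EngineState(
        x=np.zeros(N), y=np.zeros(N), zp=np.zeros(N), zd=np.zeros(N),
        x_src=None,
    )
    C, src_rates, src_windows = _source_arrays(protocol, N)
    st.x_src = np.zeros(len(src_rates))
    if shadow is None:
        shadow = np.zeros((N, N))

    has_window = window is not None
    if has_window:
        mu, Ap, Ad = window.mu, window.A_p, window.A_d
        tau_p, tau_d = window.tau_p, window.tau_d
    else:
        mu = Ap = Ad = 0.0
        tau_p = tau_d = 1.0

    master = np.random.default_rng(config.seed if seed is None else seed)
    boundaries = _segment_boundaries(duration, snapshot_every, protocol, schedule)
    ceiling = ceiling_factor * max(float(np.sum(config.lambda0)), 1e-12)

    ev_t = np.empty(buffer_size)
    ev_id = np.empty(buffer_size, dtype=np.int64)
    clip_counts = np.zeros(2, dtype=np.int64)
    all_t: list[np.ndarray] = []
    all_id: list[np.ndarray] = []
    snapshots: list[tuple[float, np.ndarray]] = []

    def on_snap_grid(t: float) -> bool:
        if not snapshot_every:
            return False
        k = np.round(t / snapshot_every)
        return abs(t - k * snapshot_every) < 1e-6 * snapshot_every

    if snapshot_every:
        snapshots.append((0.0, W.copy()))

    status = "ok"
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        lam0 = (
            schedule.rates_at(t0, config.lambda0) if schedule is not None else config.lambda0
        ).astype(float)
        seg_rates = np.array(
            [r if (w[0] <= t0 < w[1]) else 0.0 for r, w in zip(src_rates, src_windows)]
        )
        t_cur = t0
        while True:
            seg_seed = int(master.integers(1, 2**31 - 1))
            stat, n, t_cur = _kernel.run_segment(
                seg_seed, t_cur, t1, lam0, W, mask,
                st.x, st.y, st.zp, st.zd,
                C, st.x_src, seg_rates,
                config.tau_s, tau_p, tau_d,
                mu, Ap, Ad, config.w_max,
                has_window, (has_window and not tracked), (has_window and tracked),
                shadow, ceiling, ev_t, ev_id, 0, clip_counts,
            )
            all_t.append(ev_t[:n].copy())
            all_id.append(ev_id[:n].copy())
            if stat == _kernel.STATUS_DIVERGED:
                status = "pathological"
                break
            if stat == _kernel.STATUS_DONE:
                break
            # buffer full: continue the same segment
        if status == "pathological":
            break
        if on_snap_grid(t1) or (snapshot_every and t1 == duration):
            snapshots.append((float(t1), W.copy()))

    if status == "pathological" and raise_on_divergence:
        raise PathologicalActivityError(
            f"total intensity exceeded ceiling {ceiling:.3g} Hz"
        )

    times = np.concatenate(all_t) if all_t else np.empty(0)
    ids = np.concatenate(all_id) if all_id else np.empty(0, dtype=np.int64)
    record = SpikeRecord(times, ids, N, 0.0, duration)
    return SimResult(
        record=record,
        snapshots=snapshots,
        W_final=W,
        status=status,
        clip_floor=int(clip_counts[0]),
        clip_ceiling=int(clip_counts[1]),
    )


def track_mean_drift(
    config: NetworkConfig,
    W_fixed: np.ndarray,
    window: STDPWindow,
    duration: float,
    n_batches: int = 10,
    seed: int | None = None,
) -> DriftEstimate:
    """Empirical time-averaged drift on frozen weights (tracked, not applied).

    The run is split into ``n_batches`` equal non-overlapping windows; the
    per-entry drift is the total tracked increment divided by the duration,
    the standard error comes from the batch-to-batch spread.
    """
    if n_batches < 5:
        raise ValueError("need at least 5 batches for a standard error")
    check_weight_matrix(W_fixed, config)
    N = config.N
    batch_T = duration / n_batches
    master = np.random.default_rng(config.seed if seed is None else seed)

    W = np.array(W_fixed, dtype=float, copy=True)
    mask = config.effective_mask()
    st = _EngineState(
        x=np.zeros(N), y=np.zeros(N), zp=np.zeros(N), zd=np.zeros(N), x_src=np.zeros(0)
    )
    C = np.zeros((0, N))
    src_rates = np.zeros(0)
    lam0 = config.lambda0.astype(float)
    ceiling = 1e4 * max(float(np.sum(lam0)), 1e-12)
    buffer_size = 1_000_000
    ev_t = np.empty(buffer_size)
    ev_id = np.empty(buffer_size, dtype=np.int64)
    clip_counts = np.zeros(2, dtype=np.int64)

    shadow = np.zeros((N, N))
    batch_means = np.empty((n_batches, N, N))
    t_cur = 0.0
    for b in range(n_batches):
        before = shadow.copy()
        t_goal = (b + 1) * batch_T
        while True:
            seg_seed = int(master.integers(1, 2**31 - 1))
            stat, n, t_cur = _kernel.run_segment(
                seg_seed, t_cur, t_goal, lam0, W, mask,
                st.x, st.y, st.zp, st.zd, C, st.x_src, src_rates,
                config.tau_s, window.tau_p, window.tau_d,
                window.mu, window.A_p, window.A_d, config.w_max,
                True, False, True,
                shadow, ceiling, ev_t, ev_id, 0, clip_counts,
            )
            if stat == _kernel.STATUS_DIVERGED:
                raise PathologicalActivityError("divergence during tracked run")
            if stat == _kernel.STATUS_DONE:
                break
        batch_means[b] = (shadow - before) / batch_T

    mean = batch_means.mean(axis=0)
    se = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return DriftEstimate(mean=mean, se=se, T=duration, n_batches=n_batches,
                         batch_means=batch_means)


def empirical_rates(record: SpikeRecord, interval: tuple[float, float] | None = None) -> np.ndarray:
    """Per-neuron spike rates (Hz) over a sub-interval of the recording."""
    t0, t1 = interval if interval is not None else (record.t_start, record.t_end)
    if not t1 > t0:
        raise ValueError("empty interval")
    net = record.network()
    sel = (net.times >= t0) & (net.times < t1)
    counts = np.bincount(net.ids[sel].astype(int), minlength=record.N)
    return counts / (t1 - t0)


def empirical_cross_correlation(
    record: SpikeRecord,
    pair: tuple[int, int],
    max_lag: float,
    bin_width: float,
    warmup: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram estimator of C_ij(tau) = <S_i(t+tau) S_j(t)>.

    Returns (lag-bin centers, estimates in Hz^2).  For i == j the zero-lag
    self-pairing of each spike with itself is excluded, so the central bin
    estimates the continuous part of the autocorrelation.
    """
    if bin_width > max_lag:
        raise ValueError("bin width larger than the maximum lag")
    i, j = pair
    net = record.network()
    sel = net.times >= record.t_start + warmup
    times, ids = net.times[sel], net.ids[sel]
    ti = times[ids == i]
    tj = times[ids == j]
    T = record.t_end - (record.t_start + warmup)
    n_bins = int(np.ceil(max_lag / bin_width))
    edges = np.linspace(-n_bins * bin_width, n_bins * bin_width, 2 * n_bins + 1)
    counts = np.zeros(2 * n_bins)
    for t in tj:
        lo = np.searchsorted(ti, t + edges[0])
        hi = np.searchsorted(ti, t + edges[-1])
        diffs = ti[lo:hi] - t
        if i == j:
            diffs = diffs[diffs != 0.0]
        counts += np.histogram(diffs, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (T * bin_width)
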
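"""Numba core of the event-driven Hawkes + STDP simulation.

Exactness argument: between events every intensity contribution decays
(synaptic activations fall with tau_s, spontaneous rates and active source
rates are constant within a segment), so the total intensity at the last
proposal time is a valid upper bound for thinning.  Each proposal -- accepted
or not -- resets the bound to the current total intensity, so rejection chains
shrink the bound monotonically and no discretisation error is introduced.

State kept incrementally:
  x[k]    per-neuron synaptic activation, sum of exp(-(t-t_spike)/tau_s)
  y[i]    total evoked drive  sum_k W[i,k] x[k] + sum_s C[s,i] x_src[s]
  zp, zd  STDP traces with time constants tau_p, tau_d
Intensities are lam0[i] + y[i]/tau_s.  y is updated incrementally at each
spike and weight change and re-synchronised from W, x, x_src periodically to
keep float drift negligible.

Status codes: 0 = segment finished, 1 = event buffer full, 2 = pathological
activity (total intensity above the divergence ceiling).
"""

import numpy as np
from numba import njit

STATUS_DONE = 0
STATUS_BUFFER_FULL = 1
STATUS_DIVERGED = 2

RESYNC_EVERY = 4096


@njit(cache=True)
def _resync_y(W, x, C, x_src, y):
    N = W.shape[0]
    ns = C.shape[0]
    for i in range(N):
        acc = 0.0
        for k in range(N):
            acc += W[i, k] * x[k]
        for s in range(ns):
            acc += C[s, i] * x_src[s]
        y[i] = acc


@njit(cache=True)
def run_segment(
    seed,
    t_start,
    t_end,
    lam0,          # (N,) spontaneous rates for this segment
    W,             # (N, N) weights, modified in place when plastic
    mask,          # (N, N) boolean, True = connection allowed
    x, y, zp, zd,  # (N,) state arrays, modified in place
    C,             # (ns, N) source -> neuron input weights
    x_src,         # (ns,) source activations
    src_rate,      # (ns,) source rates; 0 when inactive this segment
    tau_s, tau_p, tau_d,
    mu, Ap, Ad, wmax,
    has_window, apply_plastic, tracked,
    shadow,        # (N, N) tracked (unclipped, unapplied) increment accumulator
    ceiling,
    ev_t, ev_id,   # preallocated event buffers
    n0,            # number of events already in the buffers
    clip_counts,   # (2,) int64: floor hits, ceiling hits
):
    np.random.seed(seed)
    N = lam0.shape[0]
    ns = src_rate.shape[0]
    cap = ev_t.shape[0]

    L0 = 0.0
    for i in range(N):
        L0 += lam0[i]
    for s in range(ns):
        L0 += src_rate[s]

    _resync_y(W, x, C, x_src, y)
    s_cur = 0.0
    for i in range(N):
        s_cur += y[i]

    t = t_start
    t_arr = t_start  # time to which the state arrays are decayed
    n = n0
    accepted_since_resync = 0

    while True:
        B = L0 + s_cur / tau_s
        if B > ceiling:
            return STATUS_DIVERGED, n, t
        if B <= 0.0:
            # silent network with no drive: nothing can ever happen
            t = t_end
            break
        dt = -np.log(np.random.random()) / B
        t_prop = t + dt
        if t_prop >= t_end:
            t = t_end
            break
        s_new = s_cur * np.exp(-dt / tau_s)
        lam_tot = L0 + s_new / tau_s
        t = t_prop
        s_cur = s_new
        if np.random.random() * B > lam_tot:
            continue  # thinned; bound resets to current intensity

        # ---- accepted event: decay state arrays to t
        d = t - t_arr
        if d > 0.0:
            es = np.exp(-d / tau_s)
            for i in range(N):
                x[i] *= es
                y[i] *= es
            for s in range(ns):
                x_src[s] *= es
            if has_window:
                ep = np.exp(-d / tau_p)
                ed = np.exp(-d / tau_d)
                for i in range(N):
                    zp[i] *= ep
                    zd[i] *= ed
            t_arr = t

        # ---- choose the emitter proportionally to current intensities
        target = np.random.random() * lam_tot
        emitter = -1
        acc = 0.0
        for i in range(N):
            acc += lam0[i] + y[i] / tau_s
            if acc >= target:
                emitter = i
                break
        if emitter < 0:
            for s in range(ns):
                acc += src_rate[s]
                if acc >= target:
                    emitter = N + s
                    break
        if emitter < 0:
            emitter = N - 1 if ns == 0 else N + ns - 1  # float round-off guard

        if emitter < N:
            m = emitter
            if has_window:
                # all-to-all pair rule collapsed onto the traces
                for j in range(N):
                    if j == m:
                        continue
                    dw = mu * (Ap * zp[j] + Ad * zd[j])
                    if tracked:
                        if mask[m, j]:
                            shadow[m, j] += dw
                        if mask[j, m]:
                            shadow[j, m] += dw
                    elif apply_plastic:
                        if mask[m, j]:
                            w_new = W[m, j] + dw
                            if w_new < 0.0:
                                w_new = 0.0
                                clip_counts[0] += 1
                            elif w_new > wmax:
                                w_new = wmax
                                clip_counts[1] += 1
                            if w_new != W[m, j]:
                                y[m] += (w_new - W[m, j]) * x[j]
                                W[m, j] = w_new
                        if mask[j, m]:
                            w_new = W[j, m] + dw
                            if w_new < 0.0:
                                w_new = 0.0
                                clip_counts[0] += 1
                            elif w_new > wmax:
                                w_new = wmax
                                clip_counts[1] += 1
                            if w_new != W[j, m]:
                                y[j] += (w_new - W[j, m]) * x[m]
                                W[j, m] = w_new
                zp[m] += 1.0
                zd[m] += 1.0
            x[m] += 1.0
            for i in range(N):
                y[i] += W[i, m]
        else:
            s_idx = emitter - N
            x_src[s_idx] += 1.0
            for i in range(N):
                y[i] += C[s_idx, i]

        ev_t[n] = t
        ev_id[n] = emitter
        n += 1

        accepted_since_resync += 1
        if accepted_since_resync >= RESYNC_EVERY:
            _resync_y(W, x, C, x_src, y)
            accepted_since_resync = 0
        s_cur = 0.0
        for i in range(N):
            s_cur += y[i]

        if n >= cap:
            # decay arrays to current t before handing back
            return STATUS_BUFFER_FULL, n, t

    # segment end: decay arrays to t_end
    d = t - t_arr
    if d > 0.0:
        es = np.exp(-d / tau_s)
        for i in range(N):
            x[i] *= es
            y[i] *= es
        for s in range(ns):
            x_src[s] *= es
        if has_window:
            ep = np.exp(-d / tau_p)
            ed = np.exp(-d / tau_d)
            for i in range(N):
                zp[i] *= ep
                zd[i] *= ed
    return STATUS_DONE, n, t
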
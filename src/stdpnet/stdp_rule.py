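"""Pair-based symmetric STDP with all-to-all spike pairing.

The window ``F(t) = mu*(A_p e^{-|t|/tau_p} + A_d e^{-|t|/tau_d})`` is even, so
each unordered spike pair of neurons i and j contributes the same increment
F(dt) to both W[i, j] and W[j, i], applied at the later spike's time.  Because
the window is a sum of exponentials, the full all-to-all pair sum is computed
exactly with two per-neuron traces (one per time constant): no history is
stored and no approximation is made.

Weights are clipped to [0, w_max] per spike event, after summing all of that
event's pairings.  In tracked ("shadow") mode the same increments are
accumulated into a separate matrix without clipping and without being applied
-- this measures the time-averaged drift on a frozen weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import STDPWindow


def window_value(window: STDPWindow, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate F(t); even in t, -> 0 as |t| -> infinity."""
    at = np.abs(t)
    return window.mu * (
        window.A_p * np.exp(-at / window.tau_p) + window.A_d * np.exp(-at / window.tau_d)
    )


def clip(w: float | np.ndarray, w_max: float) -> float | np.ndarray:
    """Clip a weight to [0, w_max]."""
    return np.minimum(np.maximum(w, 0.0), w_max)


@dataclass
class TraceState:
    """Per-neuron STDP traces z_p, z_d at a common current time.

    z_p[j] = sum over past spikes of j of exp(-(t - t_spike)/tau_p), and
    analogously z_d with tau_d.  The pairwise increment of every weight
    touching a spiking neuron m is then mu*(A_p z_p + A_d z_d) evaluated at
    the spike time.
    """

    N: int
    window: STDPWindow
    t: float = 0.0
    z_p: np.ndarray = field(default=None)
    z_d: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.z_p is None:
            self.z_p = np.zeros(self.N)
        if self.z_d is None:
            self.z_d = np.zeros(self.N)

    def decay_to(self, t: float) -> None:
        dt = t - self.t
        if dt < 0:
            raise ValueError("time must not run backwards")
        if dt > 0:
            self.z_p *= np.exp(-dt / self.window.tau_p)
            self.z_d *= np.exp(-dt / self.window.tau_d)
            self.t = t


def process_spike(
    state: TraceState,
    m: int,
    t: float,
    W: np.ndarray,
    w_max: float,
    mask: np.ndarray | None = None,
    shadow: np.ndarray | None = None,
) -> None:
    """Apply (or track) all STDP updates caused by a spike of neuron m at t.

    Every prior spike of every other neuron j pairs with this spike; the trace
    identity collapses the pair sum to ``dw = mu*(A_p z_p + A_d z_d)``, added
    symmetrically to W[m, :] and W[:, m] and clipped to [0, w_max].  If
    ``shadow`` is given the unclipped increments are accumulated there and W
    is left untouched.  Finally the traces of m are incremented by 1.
    """
    state.decay_to(t)
    win = state.window
    dw = win.mu * (win.A_p * state.z_p + win.A_d * state.z_d)
    dw[m] = 0.0
    if mask is not None:
        row_allowed = mask[m, :]
        col_allowed = mask[:, m]
    else:
        row_allowed = col_allowed = np.ones(state.N, dtype=bool)
        row_allowed = row_allowed.copy()
        row_allowed[m] = False
        col_allowed = row_allowed
    if shadow is not None:
        shadow[m, :][row_allowed] += dw[row_allowed]
        shadow[:, m][col_allowed] += dw[col_allowed]
    else:
        W[m, :][row_allowed] = clip(W[m, :][row_allowed] + dw[row_allowed], w_max)
        W[:, m][col_allowed] = clip(W[:, m][col_allowed] + dw[col_allowed], w_max)
    state.z_p[m] += 1.0
    state.z_d[m] += 1.0


def apply_spike_train(
    times: np.ndarray,
    neurons: np.ndarray,
    N: int,
    window: STDPWindow,
    W0: np.ndarray,
    w_max: float,
    mask: np.ndarray | None = None,
    tracked: bool = False,
) -> np.ndarray:
    """Run the trace-based rule over a fixed time-sorted spike record.

    Returns the final weight matrix (clipped mode) or the accumulated shadow
    increments (tracked mode).  Mainly a reference path for validation; the
    simulation engine applies the identical updates inline.
    """
    W = np.array(W0, dtype=float, copy=True)
    shadow = np.zeros_like(W) if tracked else None
    state = TraceState(N=N, window=window, t=float(times[0]) if len(times) else 0.0)
    for t, m in zip(times, neurons):
        process_spike(state, int(m), float(t), W, w_max, mask=mask, shadow=shadow)
    return shadow if tracked else W
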
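"""Domain types and weight-matrix constructors.

The model is a network of linear Poisson (Hawkes) neurons with pair-based
symmetric STDP.  Everything downstream (simulation engine, mean-field theory,
protocols) consumes the small set of validated containers defined here:

* :class:`STDPWindow` -- the plasticity window ``F(t) = mu*(A_p e^{-|t|/tau_p}
  + A_d e^{-|t|/tau_d})`` with potentiation amplitude ``A_p > 0`` and
  depression amplitude ``A_d < 0``.
* :class:`NetworkConfig` -- network size, maximum weight, synaptic time
  constant, spontaneous rates, optional structural mask and RNG seed.
* Constructors for the weight topologies used throughout: uniform random
  background, a single homogeneous assembly, and the intertwined cover in
  which every neuron belongs to exactly two assemblies.

Convention: ``W[i, j]`` is the weight of the synapse from presynaptic neuron
``j`` onto postsynaptic neuron ``i``; the diagonal is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


class InvalidParameterError(ValueError):
    """A configuration field violates a hard model invariant."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class STDPWindow:
    """Symmetric double-exponential STDP window.

    Parameters
    ----------
    A_p : float
        Potentiation amplitude, dimensionless, > 0.
    A_d : float
        Depression amplitude, dimensionless, < 0.
    tau_p, tau_d : float
        Potentiation / depression time constants in seconds, tau_p < tau_d.
    mu : float
        Learning-rate scale factor applied multiplicatively to the window.
    """

    A_p: float
    A_d: float
    tau_p: float
    tau_d: float
    mu: float = 1.0

    def __post_init__(self):
        if not self.A_p > 0:
            raise InvalidParameterError("A_p", "potentiation amplitude must be > 0")
        if not self.A_d < 0:
            raise InvalidParameterError("A_d", "depression amplitude must be < 0")
        if not abs(self.A_p) > abs(self.A_d):
            raise InvalidParameterError("A_d", "|A_p| must exceed |A_d|")
        if not 0 < self.tau_p < self.tau_d:
            raise InvalidParameterError(
                "tau_p", "require 0 < tau_p < tau_d (narrow potentiation peak)"
            )
        if not self.mu > 0:
            raise InvalidParameterError("mu", "learning rate must be > 0")

    @property
    def f0(self) -> float:
        """Integral of the window at mu=1: f0 = 2*(A_p*tau_p + A_d*tau_d), in s."""
        return 2.0 * (self.A_p * self.tau_p + self.A_d * self.tau_d)

    @property
    def depression_dominated(self) -> bool:
        """True when the window integral is negative (the regime studied)."""
        return self.f0 < 0

    def with_mu(self, mu: float) -> "STDPWindow":
        return STDPWindow(self.A_p, self.A_d, self.tau_p, self.tau_d, mu)


@dataclass
class NetworkConfig:
    """Static description of a network of Hawkes neurons.

    ``lambda0`` may be given as a scalar (shared spontaneous rate in Hz) or a
    length-N vector.  ``mask`` is an optional boolean structural-connectivity
    indicator (True = connection allowed); its diagonal must be False.  The
    mask is separate from the weights so that dilution is permanent under
    plasticity.
    """

    N: int
    w_max: float
    tau_s: float
    lambda0: np.ndarray | float
    mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise InvalidParameterError("N", "neuron count must be an integer >= 1")
        if not self.w_max > 0:
            raise InvalidParameterError("w_max", "maximum weight must be > 0")
        if not self.tau_s > 0:
            raise InvalidParameterError("tau_s", "synaptic time constant must be > 0")
        lam = np.asarray(self.lambda0, dtype=float)
        if lam.ndim == 0:
            lam = np.full(self.N, float(lam))
        if lam.shape != (self.N,):
            raise InvalidParameterError(
                "lambda0", f"expected scalar or length-{self.N} vector, got shape {lam.shape}"
            )
        if np.any(lam < 0):
            raise InvalidParameterError("lambda0", "spontaneous rates must be >= 0")
        self.lambda0 = lam
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (self.N, self.N):
                raise InvalidParameterError("mask", f"expected ({self.N},{self.N}) boolean matrix")
            if np.any(np.diag(m)):
                raise InvalidParameterError("mask", "diagonal must be False (no self-synapses)")
            self.mask = m

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def effective_mask(self) -> np.ndarray:
        """Boolean matrix of permitted connections (diagonal always False)."""
        if self.mask is not None:
            return self.mask.copy()
        m = np.ones((self.N, self.N), dtype=bool)
        np.fill_diagonal(m, False)
        return m


@dataclass
class AssemblyCover:
    """An ordered list of (possibly overlapping) neuron-index sets."""

    assemblies: list[frozenset[int]]
    N: int | None = None

    def __post_init__(self):
        self.assemblies = [frozenset(a) for a in self.assemblies]

    @property
    def membership(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for k, a in enumerate(self.assemblies):
            for i in a:
                out.setdefault(i, set()).add(k)
        return out

    def sizes(self) -> list[int]:
        return [len(a) for a in self.assemblies]

    def __len__(self) -> int:
        return len(self.assemblies)

    def __iter__(self):
        return iter(self.assemblies)


@dataclass
class StimulusProtocol:
    """External Poisson sources driving subsets of neurons.

    Each source is a dict with keys ``rate`` (Hz), ``targets`` (iterable of
    neuron indices), ``w_in`` (input weight, >= 0), ``t_on`` and ``t_off``
    (seconds).  Input weights are non-plastic and source spikes carry no STDP
    traces: the network is stimulated, then evolves on its own.
    """

    sources: list[dict]
    plastic_inputs: bool = False

    def __post_init__(self):
        for s in self.sources:
            if not s["t_on"] < s["t_off"]:
                raise InvalidParameterError("t_on", "require t_on < t_off")
            if s["w_in"] < 0:
                raise InvalidParameterError("w_in", "input weight must be >= 0")
            if s["rate"] < 0:
                raise InvalidParameterError("rate", "source rate must be >= 0")
        if self.plastic_inputs:
            raise InvalidParameterError("plastic_inputs", "plastic input weights not supported")


@dataclass
class RateModulationSchedule:
    """Piecewise-constant overrides of spontaneous rates.

    ``epochs`` is a list of dicts ``{t_start, t_end, overrides}`` where
    ``overrides`` maps neuron index -> new spontaneous rate (Hz).  Epochs must
    not overlap for any single neuron.
    """

    epochs: list[dict]

    def __post_init__(self):
        per_neuron: dict[int, list[tuple[float, float]]] = {}
        for e in self.epochs:
            if not e["t_start"] < e["t_end"]:
                raise InvalidParameterError("t_start", "require t_start < t_end")
            for n, lam in e["overrides"].items():
                if lam < 0:
                    raise InvalidParameterError("overrides", "rates must be >= 0")
                per_neuron.setdefault(int(n), []).append((e["t_start"], e["t_end"]))
        for n, ivals in per_neuron.items():
            ivals.sort()
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1:
                    raise InvalidParameterError(
                        "epochs", f"overlapping epochs for neuron {n}"
                    )

    def breakpoints(self) -> np.ndarray:
        ts = sorted({e["t_start"] for e in self.epochs} | {e["t_end"] for e in self.epochs})
        return np.asarray(ts, dtype=float)

    def rates_at(self, t: float, base: np.ndarray) -> np.ndarray:
        lam = base.copy()
        for e in self.epochs:
            if e["t_start"] <= t < e["t_end"]:
                for n, v in e["overrides"].items():
                    lam[int(n)] = v
        return lam


# ---------------------------------------------------------------------------
# validation


@dataclass
class Diagnostics:
    f0: float
    depression_dominated: bool
    spectral_radius_limit: float
    notes: list[str] = field(default_factory=list)


def validate(config: NetworkConfig, window: STDPWindow) -> Diagnostics:
    """Validate a (config, window) pair and report derived quantities.

    Hard invariant violations raise :class:`InvalidParameterError` from the
    constructors; this function additionally reports the window integral f0,
    whether the rule is depression dominated (a warning note is attached if it
    is not -- the model's assembly-size limit relies on f0 < 0), and the
    homogeneous-assembly size limit N < 1 + 1/w_max beyond which firing rates
    diverge.
    """
    notes = []
    if not window.depression_dominated:
        notes.append(
            "window integral f0 >= 0: assemblies may grow without bound "
            "(depression-dominated rule expected)"
        )
    n_limit = 1.0 + 1.0 / config.w_max
    notes.append(
        f"homogeneous assemblies larger than N = {n_limit:.2f} have no stationary rate"
    )
    return Diagnostics(
        f0=window.f0,
        depression_dominated=window.depression_dominated,
        spectral_radius_limit=n_limit,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# weight-matrix constructors


def _apply_mask(W: np.ndarray, config: NetworkConfig) -> np.ndarray:
    np.fill_diagonal(W, 0.0)
    if config.mask is not None:
        W[~config.mask] = 0.0
    return W


def build_random_weights(config: NetworkConfig, fraction: float,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """I.i.d. uniform weights on [0, fraction*w_max], zero diagonal.

    The unstructured initial condition for spontaneous assembly formation;
    the presets use fractions of 0.15-0.25.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidParameterError("fraction", "must lie in [0, 1]")
    rng = config.rng() if rng is None else rng
    W = rng.uniform(0.0, fraction * config.w_max, size=(config.N, config.N))
    return _apply_mask(W, config)


def build_homogeneous_assembly(N_a: int, config: NetworkConfig,
                               members: np.ndarray | None = None) -> np.ndarray:
    """A single fully connected assembly block at weight w_max.

    ``members`` selects the neuron indices (default: the first N_a).
    """
    if N_a > config.N:
        raise InvalidParameterError("N_a", f"assembly size {N_a} exceeds N={config.N}")
    idx = np.arange(N_a) if members is None else np.asarray(members, dtype=int)
    W = np.zeros((config.N, config.N))
    W[np.ix_(idx, idx)] = config.w_max
    return _apply_mask(W, config)


def intertwined_cover(n_A: int) -> AssemblyCover:
    """Cover in which every neuron sits in exactly two of n_A+1 assemblies.

    Neurons are identified with unordered pairs of assembly labels
    {0, ..., n_A}; assembly k contains every neuron whose pair includes k.
    Hence there are n_A(n_A+1)/2 neurons, n_A+1 assemblies of size n_A, and
    every pair of assemblies shares exactly one neuron.
    """
    pairs = list(combinations(range(n_A + 1), 2))
    N = len(pairs)
    assemblies = [
        frozenset(i for i, p in enumerate(pairs) if k in p) for k in range(n_A + 1)
    ]
    return AssemblyCover(assemblies, N=N)


def build_intertwined(n_A: int, config: NetworkConfig) -> tuple[np.ndarray, AssemblyCover]:
    """Weight matrix + cover of the fully intertwined assembly pattern."""
    expected = n_A * (n_A + 1) // 2
    if config.N != expected:
        raise InvalidParameterError(
            "N", f"intertwined pattern with n_A={n_A} needs N={expected}, got {config.N}"
        )
    cover = intertwined_cover(n_A)
    W = np.zeros((config.N, config.N))
    for a in cover:
        idx = np.fromiter(a, dtype=int)
        W[np.ix_(idx, idx)] = config.w_max
    return _apply_mask(W, config), cover


def apply_dilution(config: NetworkConfig, p_keep: float,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Random structural mask keeping each off-diagonal entry with prob p_keep.

    Masked-out connections are permanently zero under all later plasticity
    (models the connectivity loss of the aging cortex).  Composes with any
    existing mask on the config.
    """
    if not 0.0 <= p_keep <= 1.0:
        raise InvalidParameterError("p_keep", "must lie in [0, 1]")
    rng = config.rng() if rng is None else rng
    keep = rng.random((config.N, config.N)) < p_keep
    np.fill_diagonal(keep, False)
    if config.mask is not None:
        keep &= config.mask
    return keep


def check_weight_matrix(W: np.ndarray, config: NetworkConfig, atol: float = 1e-12) -> None:
    """Assert the WeightMatrix invariants; raises on violation."""
    W = np.asarray(W)
    if W.shape != (config.N, config.N):
        raise InvalidParameterError("W", f"expected shape ({config.N},{config.N})")
    if np.any(np.abs(np.diag(W)) > 0):
        raise InvalidParameterError("W", "diagonal must be zero (no self-interaction)")
    if np.any(W < -atol) or np.any(W > config.w_max + atol):
        raise InvalidParameterError("W", "entries must lie in [0, w_max]")
    if config.mask is not None and np.any(np.abs(W[~config.mask]) > 0):
        raise InvalidParameterError("W", "nonzero weight on a masked-out connection")
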
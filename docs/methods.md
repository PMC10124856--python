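# Methods

## Model

`stdpnet` simulates networks of linear Poisson ("Hawkes") neurons.  Neuron
*i* fires as an inhomogeneous Poisson process with instantaneous rate

    lambda_i(t) = lambda0_i + sum_k W[i,k] * sum_m a(t - t_k^m),

where `lambda0_i` is the spontaneous rate (Hz), `W[i,k]` the weight of the
synapse from neuron *k* onto neuron *i* (dimensionless: the expected number
of extra spikes one presynaptic spike evokes), and the synaptic kernel

    a(t) = Theta(t) * (1/tau_s) * exp(-t/tau_s)

is normalised to unit integral.  With that convention the stationary rates
are `r = (1-W)^{-1} lambda0` and the spike cross-spectrum is

    C~(omega) = 2 pi delta(omega) r r^T
                + (1 - a~(omega) W)^{-1} D (1 - a~(-omega) W^T)^{-1},

with `D = diag(r)` and `a~(omega) = 1/(1 + i omega tau_s)`.  A homogeneous
assembly of N neurons at weight `w_max` has branching parameter
`rho = (N-1) w_max` (the mean number of spikes each spike triggers inside
the assembly) and rate `lambda0/(1-rho)`; `rho < 1` is required for a
stationary state, restricting assemblies to `N < 1 + 1/w_max`.

Weights evolve under symmetric pair-based STDP: every (unordered) pair of
spikes of neurons i and j changes both `W[i,j]` and `W[j,i]` by
`F(dt) = mu (A_p e^{-|dt|/tau_p} + A_d e^{-|dt|/tau_d})`, applied at the
later spike, with clipping to `[0, w_max]` per spike event.  All parameter
presets are depression dominated: `f0 = 2(A_p tau_p + A_d tau_d) < 0`.
Because the window is a sum of exponentials, two per-neuron traces make the
all-to-all pair sum exact (unit-tested against the explicit double sum to
machine precision).

## Mean-field drift theory

Under quasistationary weights the time-averaged drift of a weight is the
overlap of the pair correlation with the window:

    dW~_ij = f0 r_i r_j + (1/2pi) INT M_ij(omega) F~(omega) domega,

with `M` the smooth spectral term above.  `theory.drift_matrix` evaluates
this for arbitrary `W` by adaptive quadrature: the integral is folded onto
`[0, Omega]` with `Omega = 1e3/min(tau_p, tau_s)` using the Hermitian
symmetry of `M` and the evenness of `F~`, with relative tolerance `1e-8`
and an exact analytic tail (`M -> D`, arctan tail of `F~`).  For the
homogeneous assembly the drift has a closed form `drift_homogeneous(N)`
(rate-rate term plus a potentiation and a depression term); quadrature and
closed form agree to ~1e-9 relative on the tested grid.  The motif
expansion `f0 r^2 + (r/N) sum_k f_k ((N-1)^k - (-1)^k) w^k` with
`f_ab = (1/2pi) INT F~(-w) a~(w)^a a~(-w)^b dw` converges to the closed
form for `rho <= 0.5`; the coefficient sums obey `f_k -> f0/(2 tau_s)`,
which is why long spike cascades act like uncorrelated spiking and cap
assembly growth when `f0 < 0`.

The drift curve's landmarks predict assembly sizes: its zero `N_zero`
(attained size), its argmax `N_max` (preferred size), and the stationarity
bound `N_limit = 1 + 1/w_max`.  `predicted_assembly_size` locates them by
bounded scalar minimisation and Brent root finding (tolerance 1e-8 in N; N
treated as continuous).

## Event-driven simulation

Sampling uses Ogata-style thinning.  Between events every intensity
contribution decays (activations fall with `tau_s`; spontaneous and source
rates are constant within a segment), so the current total intensity is a
valid thinning bound, and the bound is reset at every proposal.  This is
exact — no time discretisation anywhere.  The inner loop is numba-compiled;
state is kept incrementally (per-neuron activation `x`, evoked drive
`y = W x + C^T x_src`, STDP traces) with periodic exact re-synchronisation
of `y` to bound float drift.  Runs are bit-reproducible for a fixed seed;
segment seeds derive from one master generator.

External stimulation sources are extra Poisson emitters wired to their
targets through the same kernel with non-plastic weights; source spikes
carry no STDP traces (the network is stimulated, then evolves on its own).
Spontaneous-rate schedules enter as segment boundaries.  A divergence guard
aborts with status `pathological` when the total intensity exceeds
`1e4 * sum(lambda0)` (configurable); supercritical runs explode on
millisecond timescales, so the factor is uncritical.

`track_mean_drift` freezes the weights and accumulates the STDP increments
(unclipped) in a shadow matrix; the run is split into >= 5 equal batches
and the batch spread gives standard errors.  Entries within a batch share
spikes and are correlated, so averaged quantities take their SE from the
batch means (`DriftEstimate.average`), never from pooled per-entry SEs.

## Assembly detection

Detection is weight-based and deterministic: binarise on
`min(W_ij, W_ji) >= theta * w_max` (default `theta = 0.5`), build candidate
groups, then assign every neuron to each candidate to which it holds a
strict majority of its possible strong links (this membership completion is
what permits overlapping assignments).  Three candidate backends:

* `components` (default) — connected components of the strong graph; right
  for disjoint block structures.
* `communities` — greedy modularity communities; robust when transient
  strong pairs bridge two assemblies (drifting or merging structures) and
  recovers simple overlaps.
* `cliques` — maximal cliques (>= min_size), absorbing near-duplicates;
  recovers fully intertwined patterns exactly for `n_A >= 4`.  For
  `n_A = 3` the thresholded intertwined graph is the octahedron, whose true
  and spurious triangles are graph-automorphic: no detector on the
  binarised matrix can separate them, which is why tests use `n_A >= 4`.

In structurally diluted networks detection takes the connectivity mask and
counts only reciprocally existing links; otherwise an intact assembly at
connection probability p has reciprocal strong-pair density p^2 and
vanishes below the threshold.  Sparse assemblies are summarised by the
corrected size `N_corr = (1 + sqrt(1 + 4 w_sum/w_max))/2`, the size of the
fully connected assembly with the same total internal weight (`w_sum` sums
both directions of every internal pair, so a full block maps back to N
exactly).

When tracking drifting structures, covers are detected on block-averaged
weight snapshots (default: six 5,000-s snapshots per block): borderline
neurons flicker around the threshold on ~1e4-s timescales and averaging
removes that flicker without masking genuine membership changes.

## Protocol scale-downs

The experiment battery runs at desk scale.  Choices that depart from the
published scales, and why:

* **Spontaneous formation** (N=120, `w_max=0.04`, `mu=0.07`): duration
  5e5 s.  Assemblies appear from ~3.5e5 s; corrected sizes cluster near
  `N_zero ~ 20.0` rather than `N_max ~ 16.8`.
* **Drift**: the published high-noise operating point (N=72,
  `w_max=0.056`) leaves only ~4 neurons between the attained size and the
  stationarity limit; with `mu=0.145` our runs dissolve or diverge.  The
  default drift demonstration therefore uses the other published drift
  network (N=120, `w_max=0.024`, `mu=0.05`), whose margin is ~12 neurons,
  with `mu_high = 0.065`: at 0.05 cumulative turnover is ~0.01 over 3e5 s,
  at 0.065 it grows severalfold while consecutive covers still match
  one-to-one, and at >= 0.08 the structure dissolves.  Both published
  learning rates remain available as preset options.
* **Intertwined pattern** (scaled to `n_A=7`, N=28): `w_max` is chosen by
  maximising the mean-field stability margin `min(intra-drift,
  -extra-drift)` over a small grid — the same sign structure that holds at
  the published `n_A=19`, `w=0.018` point — giving `w_max = 0.015`; `mu` is
  reduced to 0.005 because weights clipped at zero rectify fluctuations
  into a net upward ratchet that scales ~mu^2 while the restoring drift
  scales ~mu, and at the published `mu=0.017` the small network's
  extra-assembly weights creep upward.
* **Learning** (N=80, stimulation 180 s at 4.18 Hz, `w_in = 10 w_max`):
  the stimulation's mean pair gain is ~0.25 `w_max` (simulation and
  mean-field agree to ~1 %), which leaves the stimulated group
  half-connected.  Mean-field analysis of partially connected 20-groups at
  these window parameters shows the missing-link drift is negative below
  ~70 % connectivity: the half-connected group is itself an attractor — a
  sparse assembly in the sense above — and completion of all 20 neurons to
  a dense block happens only via fluctuation overshoot, on multi-million
  second timescales and in a minority of realisations.  The learning
  protocol therefore reports the stored structure (group means, corrected
  size, old-assembly preservation, background suppression) and the
  experiment check asserts a persistent, detected new assembly rather than
  guaranteed full completion of all stimulated neurons.
* **Dilution**: a constructed equilibrated structure (assemblies at the
  drift zero) is diluted to p=0.7 and re-equilibrated for 2.5e5 s; the
  detected structure coarsens (fewer, larger assemblies), consistent with
  the sparse-assembly drift curve's zero shifting to larger N.

## What the synthetic conditions do and do not show

All data are generated by the model itself; there is no external data.  The
simulations share every idealisation of the theory: linear (Poisson)
neurons with unbounded rates, no synaptic delays, no explicit inhibition,
no spatial structure, all-to-all potential connectivity unless diluted.
Agreement between simulation and mean-field therefore validates the
implementation and the quasistationary averaging — not the biological
realism of the model.  Clipping at the weight bounds is outside the
mean-field description; where it matters (fluctuation ratchet on silent
synapses, completion of half-connected groups) the package documents the
discrepancy rather than forcing the theory's value.

## Numerical choices

* Quadrature tolerances: drift `epsrel 1e-8` (1e-6 where averaged over
  random masks); motif coefficients `1e-10`.
* Root/argmax tolerances in N: 1e-8.
* Warm-up discard for stationary estimators: configurable, default 100
  tau_s.
* Coincident spikes have measure zero in continuous time; if two events
  ever share a timestamp numerically, processing order breaks the tie
  deterministically.  A spike never pairs with itself.
* Divergence ceiling: 1e4 x total spontaneous rate, returned as a status
  rather than an exception by default so parameter sweeps can flag
  pathological cells.
* The event buffer holds 1e6 events; longer segments resume transparently.

## Known limitations

* The thinning loop is serial per network; very large N (> a few hundred)
  would need a different bound structure.
* `pattern_correlation`'s chance band comes from shuffling the most
  variable checkpoint vector; it is a guide, not a calibrated null.
* Detection thresholds (`theta=0.5`, strict-majority completion) are
  well-behaved for near-binary weight distributions, which is what this
  plasticity rule produces; graded weight structures would need the
  community backend and care.
* The learning and high-noise drift regimes sit near bifurcations of the
  model itself; outcomes there are intrinsically seed-dependent, as the
  reports make explicit.
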
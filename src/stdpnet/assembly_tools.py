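"""Detect and track assemblies in weight matrices.

Assemblies are groups of neurons whose mutual weights sit near the maximum
w_max.  Detection is purely weight-based and deterministic: threshold the
symmetrised weights, take connected components as candidates, then complete
memberships so that a neuron belongs to every candidate to which it holds at
least half of the possible strong links (this is what permits overlaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .model_core import AssemblyCover


def detect_assemblies(
    W: np.ndarray,
    w_max: float,
    theta_frac: float = 0.5,
    min_size: int = 3,
    method: str = "components",
    mask: np.ndarray | None = None,
) -> AssemblyCover:
    """Weight-based assembly detection with overlap support.

    1. Binarise on min(W_ij, W_ji) >= theta_frac * w_max (strong reciprocal
       links only).
    2. Candidate groups are the connected components of that undirected graph
       (``method="components"``, the deterministic default) or its greedy
       modularity communities (``method="communities"``, robust against
       single spurious strong pairs transiently bridging two assemblies --
       useful when tracking drifting structures).
    3. Assign every neuron to each candidate A for which at least half of its
       possible strong links into A are present.
    4. Drop candidates smaller than ``min_size``.

    In structurally diluted networks pass the boolean connectivity ``mask``:
    strong links and the membership denominator are then evaluated over
    reciprocally existing connections only, so that missing (impossible)
    synapses do not count against membership.
    """
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    strong = np.minimum(W, W.T) >= theta_frac * w_max
    np.fill_diagonal(strong, False)
    if mask is not None:
        recip = np.asarray(mask, dtype=bool) & np.asarray(mask, dtype=bool).T
        strong &= recip
    else:
        recip = np.ones((N, N), dtype=bool)
        np.fill_diagonal(recip, False)

    if method == "cliques":
        import networkx as nx

        G = nx.from_numpy_array(strong)
        cliques = [set(c) for c in nx.find_cliques(G) if len(c) >= min_size]
        cliques.sort(key=lambda c: (-len(c), sorted(c)))
        candidates: list[set[int]] = []
        for c in cliques:
            for cand in candidates:
                # absorb near-duplicate cliques produced by a few weak links
                if len(c & cand) >= 0.6 * min(len(c), len(cand)):
                    cand |= c
                    break
            else:
                candidates.append(set(c))
    elif method == "communities":
        import networkx as nx

        G = nx.from_numpy_array(strong.astype(float))
        G.remove_nodes_from([n for n in range(N) if not strong[n].any()])
        if G.number_of_nodes() == 0:
            candidates: list[set[int]] = []
        else:
            candidates = [
                set(int(v) for v in c)
                for c in nx.community.greedy_modularity_communities(G)
            ]
    elif method == "components":
        # connected components by BFS on the strong-link graph
        unvisited = np.ones(N, dtype=bool)
        candidates = []
        for start in range(N):
            if not unvisited[start]:
                continue
            if not strong[start].any():
                unvisited[start] = False
                continue
            comp = set()
            queue = [start]
            unvisited[start] = False
            while queue:
                u = queue.pop()
                comp.add(u)
                for v in np.flatnonzero(strong[u]):
                    if unvisited[v]:
                        unvisited[v] = False
                        queue.append(int(v))
            candidates.append(comp)
    else:
        raise ValueError(f"unknown detection method {method!r}")

    assemblies = []
    for comp in candidates:
        idx = np.fromiter(comp, dtype=int)
        members = set()
        for i in range(N):
            possible = int(recip[i, idx].sum())
            if possible == 0:
                continue
            links = int(strong[i, idx].sum())
            # strict majority: at exactly half the neuron links to every
            # assembly equally (intertwined patterns) and must not be added
            if links > 0.5 * possible:
                members.add(i)
        if len(members) >= min_size:
            assemblies.append(frozenset(members))
    assemblies.sort(key=lambda a: (min(a), -len(a)))
    return AssemblyCover(assemblies, N=N)


def corrected_size(w_sum: float, w_max: float) -> float:
    """Equivalent homogeneous-assembly size of a sparse assembly.

    Positive root of N(N-1) = w_sum / w_max where w_sum sums *all directed*
    intra-assembly weights: N_corr = (1 + sqrt(1 + 4 w_sum/w_max)) / 2.
    A full N-assembly (w_sum = N(N-1) w_max) maps back to exactly N.
    """
    if w_sum < 0 or w_max <= 0:
        raise ValueError("w_sum must be >= 0 and w_max > 0")
    return 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * w_sum / w_max))


def assembly_weight_sum(W: np.ndarray, members: frozenset[int] | set[int]) -> float:
    idx = np.fromiter(members, dtype=int)
    block = np.asarray(W)[np.ix_(idx, idx)]
    return float(block.sum())  # diagonal is zero by construction


def corrected_sizes(W: np.ndarray, cover: AssemblyCover, w_max: float) -> list[float]:
    return [corrected_size(assembly_weight_sum(W, a), w_max) for a in cover]


# ---------------------------------------------------------------------------
# structure metrics (intertwined-stability analysis)


@dataclass
class StructureMetrics:
    """Deviation of a weight matrix from a reference assembly cover.

    extra_sum_fraction: summed weight outside the cover's intra-assembly
    pairs, as a fraction of the total initial weight.  missing_sum_fraction:
    summed shortfall (w_max - W_ij) over intra-cover pairs, same
    normalisation.
    """

    extra_sum_fraction: float
    missing_sum_fraction: float
    time: float = 0.0


def _intra_mask(cover: AssemblyCover, N: int) -> np.ndarray:
    intra = np.zeros((N, N), dtype=bool)
    for a in cover:
        idx = np.fromiter(a, dtype=int)
        intra[np.ix_(idx, idx)] = True
    np.fill_diagonal(intra, False)
    return intra


def structure_metrics(
    W_t: np.ndarray,
    reference: AssemblyCover,
    W_0: np.ndarray,
    w_max: float,
    time: float = 0.0,
) -> StructureMetrics:
    W_t = np.asarray(W_t, dtype=float)
    N = W_t.shape[0]
    intra = _intra_mask(reference, N)
    total0 = float(np.asarray(W_0).sum())
    extra = float(W_t[~intra].sum())
    missing = float(np.maximum(w_max - W_t[intra], 0.0).sum())
    return StructureMetrics(extra / total0, missing / total0, time)


def extra_weight_vector(W_t: np.ndarray, reference: AssemblyCover) -> np.ndarray:
    """Vector of weights on extra-assembly (outside-cover) ordered pairs."""
    W_t = np.asarray(W_t, dtype=float)
    N = W_t.shape[0]
    intra = _intra_mask(reference, N)
    off = ~intra
    np.fill_diagonal(off, False)
    return W_t[off]


def missing_weight_vector(W_t: np.ndarray, reference: AssemblyCover, w_max: float) -> np.ndarray:
    """Vector of shortfalls w_max - W on intra-cover ordered pairs."""
    W_t = np.asarray(W_t, dtype=float)
    intra = _intra_mask(reference, W_t.shape[0])
    return np.maximum(w_max - W_t[intra], 0.0)


def pattern_correlation(
    vectors: np.ndarray,
    times: np.ndarray,
    reference_indices: list[int],
    n_shuffle: int = 200,
    seed: int = 0,
) -> dict:
    """Pearson correlation of deviation patterns against reference times.

    ``vectors`` has shape (n_times, n_entries): per checkpoint, the vector of
    extra-assembly weights (or of missing intra-assembly weights).  Returns
    correlations r[t, ref] plus a shuffle-based chance band.  Zero-variance
    vectors yield NaN.
    """
    vectors = np.asarray(vectors, dtype=float)
    rng = np.random.default_rng(seed)
    n_t = vectors.shape[0]
    corr = np.full((n_t, len(reference_indices)), np.nan)
    for c, ref in enumerate(reference_indices):
        v_ref = vectors[ref]
        if v_ref.std() == 0:
            continue
        for t in range(n_t):
            v = vectors[t]
            if v.std() == 0:
                continue
            corr[t, c] = pearsonr(v, v_ref)[0]
    # chance level: correlations between shuffled copies of the pooled vectors
    null = []
    flat = vectors[np.argmax(vectors.std(axis=1))]
    for _ in range(n_shuffle):
        null.append(pearsonr(rng.permutation(flat), flat)[0])
    null = np.asarray(null)
    return {
        "times": np.asarray(times, dtype=float),
        "corr": corr,
        "chance_mean": float(null.mean()),
        "chance_band": float(2.0 * null.std()),
    }


# ---------------------------------------------------------------------------
# cover matching / drift quantification


@dataclass
class CoverMatch:
    """Greedy maximum-Jaccard matching between two covers."""

    pairs: list[tuple[int, int, float]]  # (index in a, index in b, jaccard)
    turnover: float  # 1 - mean matched overlap fraction
    unmatched_a: list[int]
    unmatched_b: list[int]


def match_covers(cover_a: AssemblyCover, cover_b: AssemblyCover) -> CoverMatch:
    """Greedily match assemblies of two covers by descending Jaccard index.

    The turnover is 1 - mean(|A∩B| / |A∪B|) over matched pairs: 0 for
    identical covers, approaching 1 when matched assemblies barely overlap.
    """
    if len(cover_a) == 0 and len(cover_b) == 0:
        return CoverMatch(pairs=[], turnover=0.0, unmatched_a=[], unmatched_b=[])
    scores = []
    for ia, a in enumerate(cover_a):
        for ib, b in enumerate(cover_b):
            union = len(a | b)
            if union == 0:
                continue
            scores.append((len(a & b) / union, ia, ib))
    scores.sort(reverse=True)
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for j, ia, ib in scores:
        if ia in used_a or ib in used_b or j <= 0.0:
            continue
        pairs.append((ia, ib, j))
        used_a.add(ia)
        used_b.add(ib)
    turnover = 1.0 - (np.mean([p[2] for p in pairs]) if pairs else 0.0)
    return CoverMatch(
        pairs=pairs,
        turnover=float(turnover),
        unmatched_a=[i for i in range(len(cover_a)) if i not in used_a],
        unmatched_b=[i for i in range(len(cover_b)) if i not in used_b],
    )


@dataclass
class DriftTrace:
    """Assembly covers at checkpoints with step-to-step matchings."""

    times: list[float]
    covers: list[AssemblyCover]
    matches: list[CoverMatch]

    @property
    def stepwise_turnover(self) -> np.ndarray:
        return np.asarray([m.turnover for m in self.matches])

    def cumulative_turnover(self) -> float:
        """Turnover between the first and last checkpoint covers."""
        if len(self.covers) < 2:
            return 0.0
        return match_covers(self.covers[0], self.covers[-1]).turnover

    def identifiable(self, threshold: float = 0.5) -> bool:
        """True when every step-to-step matched pair overlaps above threshold."""
        return all(
            all(j > threshold for _, _, j in m.pairs) and m.pairs for m in self.matches
        )


def build_drift_trace(
    snapshots: list[tuple[float, np.ndarray]],
    w_max: float,
    theta_frac: float = 0.5,
    min_size: int = 3,
    method: str = "communities",
) -> DriftTrace:
    times = [t for t, _ in snapshots]
    covers = [detect_assemblies(W, w_max, theta_frac, min_size, method) for _, W in snapshots]
    matches = [match_covers(a, b) for a, b in zip(covers[:-1], covers[1:])]
    return DriftTrace(times=times, covers=covers, matches=matches)
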
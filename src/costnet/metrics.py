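"""Weighted global and nodal graph metrics, plus small-world null models.

All shortest-path quantities use edge length = 1/weight, the standard
convention for correlation-weighted efficiency analyses: a strong correlation
is a short functional distance.  Metrics:

* global efficiency      — mean of 1/d(i, j) over ordered pairs (1/inf = 0)
* nodal efficiency       — per node, mean inverse distance to the others;
                           its node-average equals global efficiency
* local efficiency       — per node, global efficiency of the subgraph
                           induced by its neighbours (original weights kept)
* nodal degree           — binary count of incident edges
* betweenness            — Brandes betweenness with fractional splitting over
                           equal-length shortest paths, normalised by
                           (N-1)(N-2)/2
* Cp / Lp                — Onnela weighted clustering (weights rescaled by the
                           maximum edge weight) and characteristic path length
                           over *connected* ordered pairs only
* gamma, lambda, sigma   — Cp/Cp_rand, Lp/Lp_rand and their ratio against a
                           degree-preserving (Maslov-Sneppen) null ensemble
                           with empirical weights reassigned at random

A graph with no connected pair has undefined Lp; that is reported as NaN and
must be resolved (or the subject excluded) before curve integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .errors import ComputationError, ValidationError
from .network import ThresholdedNetwork

__all__ = [
    "GlobalMetrics",
    "NullEnsemble",
    "shortest_distances",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "nodal_degree",
    "betweenness",
    "clustering_coefficient",
    "characteristic_path_length",
    "clustering_and_pathlength",
    "random_null_ensemble",
    "small_worldness",
    "global_metrics",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary at a single cost."""

    e_global: float
    e_local: float
    clustering_cp: float
    path_length_lp: float
    gamma: float = math.nan
    lambda_: float = math.nan
    sigma: float = math.nan


@dataclass(frozen=True)
class NullEnsemble:
    """Degree-preserving random-rewiring ensemble summary."""

    n_null: int
    cp_rand: float
    lp_rand: float
    cp_sd: float
    lp_sd: float
    seed: int


def _weights(net) -> np.ndarray:
    if isinstance(net, ThresholdedNetwork):
        return net.weights
    w = np.asarray(net, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"weight matrix must be square, got {w.shape}")
    if np.any(w < 0):
        raise ValidationError("edge weights must be non-negative")
    return w


def shortest_distances(net) -> np.ndarray:
    """All-pairs shortest path lengths under edge length 1/weight.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    w = _weights(net)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    # zeros are dropped in the sparse conversion, i.e. treated as absent edges
    return _dijkstra(csr_matrix(lengths), directed=False)


def _inverse_distances(dist: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def global_efficiency(net, dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest distance over ordered node pairs."""
    w = _weights(net)
    n = w.shape[0]
    if n < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    if dist is None:
        dist = shortest_distances(w)
    inv = _inverse_distances(dist)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(net, dist: np.ndarray | None = None) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    w = _weights(net)
    n = w.shape[0]
    if n < 2:
        raise ValidationError("nodal efficiency needs at least 2 nodes")
    if dist is None:
        dist = shortest_distances(w)
    inv = _inverse_distances(dist)
    return inv.sum(axis=1) / (n - 1)


try:  # compiled kernel; the numpy path below is the reference fallback
    import numba

    @numba.njit(cache=False)
    def _local_efficiency_kernel(w: np.ndarray) -> np.ndarray:  # pragma: no cover
        n = w.shape[0]
        vec = np.zeros(n)
        nb = np.empty(n, np.int64)
        for i in range(n):
            k = 0
            for j in range(n):
                if w[i, j] > 0.0:
                    nb[k] = j
                    k += 1
            if k < 2:
                continue
            dist = np.empty((k, k))
            for a in range(k):
                for b in range(k):
                    ww = w[nb[a], nb[b]]
                    dist[a, b] = 1.0 / ww if ww > 0.0 else np.inf
                dist[a, a] = 0.0
            for m in range(k):
                for a in range(k):
                    d_am = dist[a, m]
                    if d_am == np.inf:
                        continue
                    for b in range(k):
                        alt = d_am + dist[m, b]
                        if alt < dist[a, b]:
                            dist[a, b] = alt
            total = 0.0
            for a in range(k):
                for b in range(k):
                    if a != b and dist[a, b] < np.inf:
                        total += 1.0 / dist[a, b]
            vec[i] = total / (k * (k - 1))
        return vec

except ImportError:  # pragma: no cover
    _local_efficiency_kernel = None


def local_efficiency(net) -> tuple[float, np.ndarray]:
    """Mean (and per-node) efficiency of each node's neighbour subgraph.

    The subgraph keeps the original weights between neighbours and excludes
    the node itself; nodes with fewer than two neighbours contribute 0.

    Neighbourhood subgraphs are solved with a compiled Floyd-Warshall kernel
    when numba is available, otherwise with one batched numpy Floyd-Warshall
    padded to the largest neighbourhood; both routes are exact and
    cross-checked in the test suite.
    """
    w = _weights(net)
    if _local_efficiency_kernel is not None:
        if not w.flags["C_CONTIGUOUS"]:
            w = np.ascontiguousarray(w)
        vec = _local_efficiency_kernel(w)
        return float(vec.mean()) if len(vec) else 0.0, vec
    return _local_efficiency_numpy(w)


def _local_efficiency_numpy(w: np.ndarray) -> tuple[float, np.ndarray]:
    n = w.shape[0]
    adjacency = w > 0
    degrees = adjacency.sum(axis=1)
    vec = np.zeros(n)
    nodes = np.flatnonzero(degrees >= 2)
    if nodes.size == 0:
        return 0.0, vec
    k_max = int(degrees[nodes].max())
    batch = np.full((nodes.size, k_max, k_max), np.inf)
    sizes = np.empty(nodes.size, dtype=int)
    for bi, i in enumerate(nodes):
        nb = np.flatnonzero(adjacency[i])
        k = nb.size
        sizes[bi] = k
        sub = w[np.ix_(nb, nb)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), np.inf)
        np.fill_diagonal(lengths, 0.0)
        batch[bi, :k, :k] = lengths
    # padded rows/columns stay +inf and can never shorten a path
    for m in range(k_max):
        np.minimum(batch, batch[:, :, m, None] + batch[:, None, m, :], out=batch)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(batch) & (batch > 0), 1.0 / batch, 0.0)
    valid = np.arange(k_max)[None, :] < sizes[:, None]
    pair_mask = valid[:, :, None] & valid[:, None, :]
    sums = (inv * pair_mask).sum(axis=(1, 2))
    vec[nodes] = sums / (sizes * (sizes - 1))
    return float(vec.mean()), vec


def nodal_degree(net) -> np.ndarray:
    """Binary count of incident edges per node (not strength)."""
    w = _weights(net)
    return (w > 0).sum(axis=1).astype(int)


def betweenness(net) -> np.ndarray:
    """Normalised shortest-path betweenness with fractional tie splitting.

    Path lengths are 1/weight; the raw pair sum is divided by
    ``(N-1)(N-2)/2`` so a star centre scores exactly 1.
    """
    import igraph

    w = _weights(net)
    n = w.shape[0]
    if n < 3:
        return np.zeros(n)
    iu, ju = np.nonzero(np.triu(w, 1))
    g = igraph.Graph(n=n, edges=list(zip(iu.tolist(), ju.tolist())))
    lengths = (1.0 / w[iu, ju]).tolist()
    raw = np.asarray(g.betweenness(weights=lengths), dtype=float)
    return raw / ((n - 1) * (n - 2) / 2.0)


def clustering_coefficient(net) -> tuple[float, np.ndarray]:
    """Onnela weighted clustering, weights rescaled by the maximum weight.

    c_i = (1/(k_i (k_i - 1))) * sum over pairs of neighbours (j, h) of
    (w_ij w_ih w_jh)^(1/3) on the rescaled weights; nodes with degree < 2
    score 0.  Returns (mean, per-node vector).
    """
    w = _weights(net)
    n = w.shape[0]
    wmax = w.max()
    if wmax <= 0:
        return 0.0, np.zeros(n)
    cube = np.cbrt(w / wmax)
    cyc3 = np.diagonal(cube @ cube @ cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    vec = np.where(denom > 0, cyc3 / np.where(denom > 0, denom, 1), 0.0)
    return float(vec.mean()), vec


def characteristic_path_length(net, dist: np.ndarray | None = None) -> float:
    """Mean shortest distance over *connected* ordered pairs (NaN if none)."""
    w = _weights(net)
    if dist is None:
        dist = shortest_distances(w)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(dist)
    if not finite.any():
        return math.nan
    return float(dist[finite].mean())


def clustering_and_pathlength(net) -> tuple[float, float]:
    cp, _ = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    return cp, lp


# ---------------------------------------------------------------------------
# null models and small-worldness
# ---------------------------------------------------------------------------

def _edge_list(w: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(w, 1))
    return np.column_stack([iu, ju])


def _double_edge_swap(edges: np.ndarray, n_nodes: int, rng: np.random.Generator,
                      n_success: int, max_tries: int) -> np.ndarray:
    """Maslov-Sneppen rewiring: repeat degree-preserving two-edge swaps."""
    edges = edges.copy()
    existing = {(int(a), int(b)) for a, b in edges}
    m = len(edges)
    successes = 0
    tries = 0
    while successes < n_success:
        tries += 1
        if tries > max_tries:
            raise ComputationError(
                "double-edge swap failed to reach the requested number of "
                "successful swaps; the graph is too sparse or too constrained"
            )
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(0, 2):
            # orientation flip so both rewirings (a,c)+(b,d) and (a,d)+(b,c)
            # are reachable
            c, d = d, c
        new1 = (min(a, c), max(a, c))
        new2 = (min(b, d), max(b, d))
        if len({a, b, c, d}) < 4:
            continue
        if new1 in existing or new2 in existing:
            continue
        existing.discard((min(a, b), max(a, b)))
        existing.discard((min(c, d), max(c, d)))
        existing.add(new1)
        existing.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    return edges


def random_null_ensemble(net, n_null: int = 100, seed: int = 0, *,
                         swaps_per_edge: int = 10) -> NullEnsemble:
    """Degree-preserving random ensemble for small-world normalisation.

    Each null rewires the topology with at least ``swaps_per_edge * E``
    successful double-edge swaps and reassigns the empirical weight multiset
    to the rewired edges uniformly at random.  Fully determined by ``seed``.
    """
    w = _weights(net)
    n = w.shape[0]
    edges = _edge_list(w)
    if len(edges) < 2:
        raise ValidationError("null ensemble needs at least 2 edges")
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    # at least two independent edges must exist for any swap to succeed
    flat = edges.ravel()
    if len(set(flat.tolist())) < 4:
        raise ComputationError("graph has no two vertex-disjoint edges to swap")
    weights_list = w[edges[:, 0], edges[:, 1]]
    rng = np.random.default_rng(seed)
    n_success = swaps_per_edge * len(edges)
    cps = np.empty(n_null)
    lps = np.empty(n_null)
    for b in range(n_null):
        rewired = _double_edge_swap(edges, n, rng, n_success,
                                    max_tries=100 * n_success + 1000)
        perm = rng.permutation(len(edges))
        null_w = np.zeros_like(w)
        null_w[rewired[:, 0], rewired[:, 1]] = weights_list[perm]
        null_w[rewired[:, 1], rewired[:, 0]] = weights_list[perm]
        cps[b], _ = clustering_coefficient(null_w)
        lps[b] = characteristic_path_length(null_w)
    return NullEnsemble(
        n_null=n_null,
        cp_rand=float(np.nanmean(cps)),
        lp_rand=float(np.nanmean(lps)),
        cp_sd=float(np.nanstd(cps, ddof=1)) if n_null > 1 else 0.0,
        lp_sd=float(np.nanstd(lps, ddof=1)) if n_null > 1 else 0.0,
        seed=seed,
    )


def small_worldness(net, nulls: NullEnsemble) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) = (Cp/Cp_rand, Lp/Lp_rand, gamma/lambda)."""
    cp, lp = clustering_and_pathlength(net)
    if not (nulls.cp_rand > 0):
        raise ComputationError("null clustering Cp_rand is zero; gamma undefined")
    if not (nulls.lp_rand > 0):
        raise ComputationError("null path length Lp_rand is zero; lambda undefined")
    gamma = cp / nulls.cp_rand
    lam = lp / nulls.lp_rand
    sigma = gamma / lam if lam > 0 else math.nan
    return float(gamma), float(lam), float(sigma)


def global_metrics(net, nulls: NullEnsemble | None = None) -> GlobalMetrics:
    """Bundle the whole-network metrics (small-world terms need nulls)."""
    dist = shortest_distances(net)
    e_glob = global_efficiency(net, dist)
    e_loc, _ = local_efficiency(net)
    cp, _ = clustering_coefficient(net)
    lp = characteristic_path_length(net, dist)
    gamma = lam = sigma = math.nan
    if nulls is not None:
        gamma, lam, sigma = small_worldness(net, nulls)
    return GlobalMetrics(
        e_global=e_glob, e_local=e_loc, clustering_cp=cp, path_length_lp=lp,
        gamma=gamma, lambda_=lam, sigma=sigma,
    )
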
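"""Independent brute-force oracles for graph metrics on tiny graphs.

Everything here enumerates simple paths exhaustively (pure-Python DFS) and
never touches the package's shortest-path machinery, so it can serve as an
independent reference for distances, path counts, betweenness and the
efficiency family on graphs small enough to enumerate (n <= 8 or so).
"""

from __future__ import annotations

import numpy as np

#: two path lengths within this relative tolerance count as equally short
REL_TOL = 1e-10


def enumerate_paths(w: np.ndarray):
    """All simple paths between all ordered pairs, with lengths 1/weight.

    Returns ``paths[s][t]`` = list of (length, interior-node tuple).
    """
    n = w.shape[0]
    paths: list[list[list[tuple[float, tuple[int, ...]]]]] = [
        [[] for _ in range(n)] for _ in range(n)
    ]

    def dfs(start: int, current: int, visited: set[int], length: float,
            interior: list[int]) -> None:
        for nxt in range(n):
            if w[current, nxt] <= 0 or nxt in visited:
                continue
            new_length = length + 1.0 / w[current, nxt]
            paths[start][nxt].append((new_length, tuple(interior)))
            visited.add(nxt)
            interior.append(nxt)
            dfs(start, nxt, visited, new_length, interior)
            interior.pop()
            visited.remove(nxt)

    for s in range(n):
        dfs(s, s, {s}, 0.0, [])
    return paths


def oracle_distances(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    paths = enumerate_paths(w)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for s in range(n):
        for t in range(n):
            if s != t and paths[s][t]:
                dist[s, t] = min(length for length, _ in paths[s][t])
    return dist


def oracle_global_efficiency(w: np.ndarray) -> float:
    dist = oracle_distances(w)
    n = w.shape[0]
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(dist[s, t]):
                total += 1.0 / dist[s, t]
    return total / (n * (n - 1))


def oracle_nodal_efficiency(w: np.ndarray) -> np.ndarray:
    dist = oracle_distances(w)
    n = w.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(dist[s, t]):
                out[s] += 1.0 / dist[s, t]
    return out / (n - 1)


def oracle_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        out[i] = oracle_global_efficiency(sub)
    return out


def oracle_betweenness(w: np.ndarray) -> np.ndarray:
    """Normalised betweenness from exhaustive shortest-path counting."""
    n = w.shape[0]
    paths = enumerate_paths(w)
    raw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            candidates = paths[s][t]
            if not candidates:
                continue
            best = min(length for length, _ in candidates)
            shortest = [interior for length, interior in candidates
                        if length <= best * (1 + REL_TOL)]
            sigma = len(shortest)
            for interior in shortest:
                for v in interior:
                    raw[v] += 1.0 / sigma
    if n < 3:
        return raw
    return raw / ((n - 1) * (n - 2) / 2.0)


def random_weighted_graph(n: int, density: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Random symmetric weight matrix with continuous weights in (0.1, 1)."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < density
    weights = rng.uniform(0.1, 1.0, size=iu.size)
    w[iu[mask], ju[mask]] = weights[mask]
    w[ju[mask], iu[mask]] = weights[mask]
    return w
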
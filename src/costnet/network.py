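"""Per-subject connectivity matrices and cost-thresholded weighted graphs.

A subject's 90-node functional network is the matrix of pairwise Pearson
correlations between regional time series.  Because correlation matrices are
dense, graphs are formed by *cost* (sparsity) thresholding: at cost ``s`` the
``K = round(s * N(N-1)/2)`` strongest positive correlations are kept as
undirected weighted edges (weight = r) and everything else is dropped.
Ranking is on the signed correlation by default; negative correlations are
never retained so that 1/weight is a valid edge length downstream
(``edge_sign="absolute"`` ranks and weights by |r| instead).

Thresholding the same matrix over an increasing cost grid yields *nested*
edge sets: every edge present at a sparser cost survives at all denser costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "CostGrid",
    "ThresholdedNetwork",
    "pearson_matrix",
    "threshold_at_cost",
    "threshold_series",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation matrix with a zeroed diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"connectivity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class CostGrid:
    """Strictly increasing sparsity grid; default 0.05..0.40 step 0.01."""

    costs: tuple[float, ...]

    def __post_init__(self) -> None:
        costs = tuple(float(c) for c in self.costs)
        if len(costs) == 0:
            raise ValidationError("cost grid is empty")
        if any(not 0.0 < c < 1.0 for c in costs):
            raise ValidationError("costs must lie strictly between 0 and 1")
        if any(b <= a for a, b in zip(costs, costs[1:])):
            raise ValidationError("costs must be strictly increasing")
        object.__setattr__(self, "costs", costs)

    @classmethod
    def default(cls) -> "CostGrid":
        return cls.from_bounds(0.05, 0.40, 0.01)

    @classmethod
    def from_bounds(cls, lo: float, hi: float, step: float) -> "CostGrid":
        # integer-step generation avoids float drift in the grid length
        scale = 10 ** 9
        lo_i, hi_i, step_i = (round(x * scale) for x in (lo, hi, step))
        values = [k / scale for k in range(lo_i, hi_i + 1, step_i)]
        return cls(tuple(values))

    def __len__(self) -> int:
        return len(self.costs)

    def __iter__(self):
        return iter(self.costs)


@dataclass
class ThresholdedNetwork:
    """Weighted undirected graph retaining the strongest edges at one cost."""

    weights: np.ndarray
    cost: float
    realized_cost: float

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def pearson_matrix(series: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson product-moment correlations between all node pairs.

    The diagonal is forced to zero (self-connections are not edges).
    """
    X = series.values
    variances = X.var(axis=0)
    dead = np.flatnonzero(variances <= 0.0)
    if dead.size:
        raise ValidationError(
            f"{series.subject_id}: node {dead[0] + 1} has zero variance"
        )
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r)


def _ranked_pairs(values: np.ndarray):
    """Upper-triangle pairs sorted by descending value, ties by (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = values[iu, ju]
    # lexsort: last key is primary; -vals descending, then i, then j
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def _network_from_ranking(iu, ju, vals, n: int, cost: float) -> ThresholdedNetwork:
    n_pairs = n * (n - 1) // 2
    k = int(round(cost * n_pairs))
    n_positive = int(np.searchsorted(-vals, 0.0, side="left"))
    kept = min(k, n_positive)
    if kept < k:
        warnings.warn(
            f"cost {cost:g} requests {k} edges but only {kept} positive "
            "correlations exist; keeping all of them",
            stacklevel=3,
        )
    weights = np.zeros((n, n))
    if kept:
        sel = slice(0, kept)
        weights[iu[sel], ju[sel]] = vals[sel]
        weights[ju[sel], iu[sel]] = vals[sel]
    return ThresholdedNetwork(
        weights=weights,
        cost=float(cost),
        realized_cost=kept / n_pairs,
    )


def _validated_values(matrix: ConnectivityMatrix, edge_sign: str) -> np.ndarray:
    if edge_sign not in ("positive", "absolute"):
        raise ValidationError(f"edge_sign must be 'positive' or 'absolute', got {edge_sign!r}")
    values = matrix.values
    if edge_sign == "absolute":
        values = np.abs(values)
    return values


def threshold_at_cost(matrix: ConnectivityMatrix, cost: float, *,
                      edge_sign: str = "positive") -> ThresholdedNetwork:
    """Keep the ``round(cost * N(N-1)/2)`` strongest correlations as edges.

    With ``edge_sign="positive"`` ranking is on signed r and only positive
    correlations are eligible; with ``"absolute"`` ranking and weights use
    |r|.  If fewer eligible edges exist than requested, all of them are kept,
    ``realized_cost`` records the shortfall and a warning is emitted.

    Ties at the boundary are broken deterministically by lowest (i, j).
    """
    if not 0.0 < cost < 1.0:
        raise ValidationError(f"cost must be in (0, 1), got {cost}")
    values = _validated_values(matrix, edge_sign)
    iu, ju, vals = _ranked_pairs(values)
    return _network_from_ranking(iu, ju, vals, values.shape[0], cost)


def threshold_series(matrix: ConnectivityMatrix, grid: CostGrid, *,
                     edge_sign: str = "positive") -> list[ThresholdedNetwork]:
    """One thresholded network per grid cost; edge sets are nested by rank.

    The pair ranking is computed once and sliced per cost, so the nesting
    (every edge at cost s survives at every s' > s) holds by construction.
    """
    values = _validated_values(matrix, edge_sign)
    iu, ju, vals = _ranked_pairs(values)
    n = values.shape[0]
    return [_network_from_ranking(iu, ju, vals, n, c) for c in grid]
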
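"""Subject-level connectivity matrices and sparsity-thresholded networks.

A Pearson correlation matrix is Fisher z-transformed and binarized by
retaining the strongest edges until a target sparsity (fraction of all
possible edges) is reached.  Edge selection is rank-based with a fixed
deterministic tie-break, so networks across a threshold grid are nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from wmhnet.preprocess import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "SparsityGrid",
    "BinaryNetwork",
    "WeightedNetwork",
    "pearson_matrix",
    "fisher_z",
    "binarize_at_sparsity",
    "sparsity_sweep",
    "weighted_network",
]

DEFAULT_SPARSITIES = tuple(np.round(np.arange(0.05, 0.401, 0.05), 2))

_R_CLIP = 1.0 - 1e-7


def _check_square_symmetric(values: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    if np.abs(values - values.T).max(initial=0.0) > tol:
        raise ValueError("matrix is not symmetric")
    return (values + values.T) / 2.0


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N symmetric association matrix with a zero diagonal.

    ``kind`` is ``"pearson_r"`` or ``"fisher_z"``; the diagonal is excluded
    from every downstream thresholding or statistic.
    """

    values: np.ndarray
    kind: str
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = _check_square_symmetric(self.values)
        np.fill_diagonal(values, 0.0)
        if self.kind not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "pearson_r" and np.abs(values).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("pearson_r entries must lie in [-1, 1]")
        labels = tuple(self.node_labels) or tuple(f"ROI_{i + 1:03d}" for i in range(values.shape[0]))
        if len(labels) != values.shape[0]:
            raise ValueError(f"{len(labels)} labels for {values.shape[0]} nodes")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SparsityGrid:
    """Strictly increasing sparsity thresholds in (0, 1)."""

    thresholds: tuple[float, ...] = DEFAULT_SPARSITIES

    def __post_init__(self) -> None:
        thresholds = tuple(float(s) for s in self.thresholds)
        if not thresholds:
            raise ValueError("grid must contain at least one threshold")
        if any(not 0.0 < s < 1.0 for s in thresholds):
            raise ValueError(f"thresholds must lie in (0, 1): {thresholds}")
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {thresholds}")
        object.__setattr__(self, "thresholds", thresholds)

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected 0/1 adjacency at a stated sparsity."""

    adjacency: np.ndarray
    sparsity: float
    node_labels: tuple[str, ...] = field(default=())
    connected: bool = True

    def __post_init__(self) -> None:
        adj = _check_square_symmetric(self.adjacency, tol=0.0)
        if not np.isin(adj, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        np.fill_diagonal(adj, 0.0)
        labels = tuple(self.node_labels) or tuple(f"ROI_{i + 1:03d}" for i in range(adj.shape[0]))
        if len(labels) != adj.shape[0]:
            raise ValueError(f"{len(labels)} labels for {adj.shape[0]} nodes")
        object.__setattr__(self, "adjacency", adj.astype(np.uint8))
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected network carrying |z| edge weights; sparsity may be "dense"."""

    weights: np.ndarray
    sparsity: float | str
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = _check_square_symmetric(self.weights)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        labels = tuple(self.node_labels) or tuple(f"ROI_{i + 1:03d}" for i in range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise ValueError(f"{len(labels)} labels for {w.shape[0]} nodes")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between regional time series."""
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = data.std(axis=0)
    zero_var = np.nonzero(sd == 0)[0]
    if zero_var.size:
        names = [ts.node_labels[i] for i in zero_var]
        raise ValueError(f"zero-variance time series for nodes: {names}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix((r + r.T) / 2.0, "pearson_r", ts.node_labels)


def fisher_z(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Variance-stabilizing arctanh transform; |r| clipped below 1 first."""
    if c.kind != "pearson_r":
        raise ValueError(f"fisher_z expects a pearson_r matrix, got {c.kind!r}")
    z = np.arctanh(np.clip(c.values, -_R_CLIP, _R_CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, "fisher_z", c.node_labels)


def _edge_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All upper-triangle pairs sorted by descending value, ties by (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = values[iu, ju]
    # lexsort: last key is primary -> sort by -value, then i, then j
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def _edge_count(n: int, sparsity: float) -> int:
    max_edges = n * (n - 1) // 2
    e = int(np.round(sparsity * max_edges))  # round-half-even
    if e <= 0 or e >= max_edges:
        raise ValueError(
            f"sparsity {sparsity} is degenerate for N={n} ({e} of {max_edges} edges)"
        )
    return e


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return bool(n_comp == 1)


def binarize_at_sparsity(z: ConnectivityMatrix, sparsity: float) -> BinaryNetwork:
    """Keep exactly ``round(s * N(N-1)/2)`` strongest edges as a 0/1 graph."""
    if not 0.0 < sparsity < 1.0:
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    n = z.n_nodes
    e = _edge_count(n, sparsity)
    iu, ju = _edge_order(z.values)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[:e], ju[:e]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, float(sparsity), z.node_labels, connected=_is_connected(adj))


def sparsity_sweep(z: ConnectivityMatrix, grid: SparsityGrid | None = None) -> list[BinaryNetwork]:
    """Binarize at every grid threshold; edge sets are nested along the grid."""
    grid = grid or SparsityGrid()
    return [binarize_at_sparsity(z, s) for s in grid]


def weighted_network(z: ConnectivityMatrix, sparsity: float | str = "dense") -> WeightedNetwork:
    """Same edge retention as binarization but edges carry |z| weights."""
    if sparsity == "dense":
        w = np.abs(z.values)
        np.fill_diagonal(w, 0.0)
        return WeightedNetwork(w, "dense", z.node_labels)
    support = binarize_at_sparsity(z, float(sparsity))
    w = np.abs(z.values) * support.adjacency
    return WeightedNetwork(w, float(sparsity), z.node_labels)
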
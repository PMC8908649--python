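"""Topological indices on binary and weighted networks.

Implements clustering, characteristic path length, global/local/nodal
efficiency, and small-world ratios against degree-preserving rewired null
ensembles.  Conventions (GRETNA-compatible):

* nodes with degree < 2 contribute 0 to the Cp and Eloc means;
* unreachable pairs contribute 0 to efficiencies (1/inf = 0);
* Lp is averaged over reachable pairs only, with a disconnected flag;
* the across-threshold summary is the arithmetic mean of per-threshold
  values ("auc" — mean scaled by grid width — is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from wmhnet.connectivity import BinaryNetwork, ConnectivityMatrix, SparsityGrid, WeightedNetwork, binarize_at_sparsity

__all__ = [
    "NullEnsembleParams",
    "GlobalMetricProfile",
    "NodalMetricProfile",
    "PathLengthResult",
    "RewireResult",
    "SmallWorldIndices",
    "across_threshold_summary",
    "clustering_coefficient",
    "shortest_path_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "degree_preserving_rewire",
    "small_world_indices",
    "global_profile",
    "metric_profiles",
    "weighted_metrics",
]

GLOBAL_METRICS = ("gamma", "lambda_", "sigma", "cp", "lp", "eglob", "eloc")


@dataclass(frozen=True)
class NullEnsembleParams:
    """Size and seeding of the degree-preserving random-network ensemble."""

    n_random: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swaps_per_edge < 0:
            raise ValueError("swaps_per_edge must be >= 0")


class PathLengthResult(NamedTuple):
    value: float
    disconnected: bool


class RewireResult(NamedTuple):
    network: "BinaryNetwork"
    n_swapped: int


class SmallWorldIndices(NamedTuple):
    gamma: float
    lambda_: float
    sigma: float


def _adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(float)
    return np.asarray(net, dtype=float)


def clustering_coefficient(net: BinaryNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node transitivity 2*t_i / (k_i (k_i - 1)) and its mean Cp."""
    a = _adjacency(net)
    if a.shape[0] < 3:
        raise ValueError("clustering needs at least 3 nodes")
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    per_node = np.divide(2.0 * triangles, denom, out=np.zeros_like(denom), where=denom > 0)
    return per_node, float(per_node.mean())


def shortest_path_matrix(net: BinaryNetwork | WeightedNetwork | np.ndarray) -> np.ndarray:
    """Pairwise graph distances; binary hops via BFS, weighted via Dijkstra
    on edge lengths 1/weight.  Unreachable pairs are ``inf``.
    """
    if isinstance(net, WeightedNetwork):
        w = net.weights
        lengths = np.divide(1.0, w, out=np.zeros_like(w), where=w > 0)
        return shortest_path(csr_matrix(lengths), method="D", directed=False)
    a = _adjacency(net)
    return shortest_path(csr_matrix(a), method="D", directed=False, unweighted=True)


def characteristic_path_length(net: BinaryNetwork | WeightedNetwork | np.ndarray) -> PathLengthResult:
    """Mean distance over reachable ordered pairs, flagged if any pair is not."""
    d = shortest_path_matrix(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("edgeless graph has no path length")
    disconnected = bool(finite.sum() < off.sum())
    return PathLengthResult(float(d[finite].mean()), disconnected)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & off
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


def global_efficiency(net: BinaryNetwork | WeightedNetwork | np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs; 1/inf counts as 0."""
    return _efficiency_from_distances(shortest_path_matrix(net))


def nodal_efficiency(net: BinaryNetwork | WeightedNetwork | np.ndarray) -> np.ndarray:
    """Node i's mean inverse distance to every other node."""
    d = shortest_path_matrix(net)
    n = d.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & off
    inv[finite] = 1.0 / d[finite]
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net: BinaryNetwork | WeightedNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Global efficiency of each node's neighbor-induced subgraph.

    For weighted input the subgraph keeps its weights. Nodes with fewer than
    two neighbors contribute 0.
    """
    weighted = isinstance(net, WeightedNetwork)
    m = net.weights if weighted else _adjacency(net)
    n = m.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(m[i] > 0)[0]
        if nbrs.size < 2:
            continue
        sub = m[np.ix_(nbrs, nbrs)]
        lengths = np.divide(1.0, sub, out=np.full_like(sub, np.inf), where=sub > 0)
        per_node[i] = _efficiency_from_distances(_floyd_warshall_dense(lengths))
    return per_node, float(per_node.mean())


def _floyd_warshall_dense(lengths: np.ndarray) -> np.ndarray:
    """Vectorized all-pairs shortest paths on a small dense length matrix.

    Cheaper than a sparse-graph call for the tiny neighbor subgraphs that
    local efficiency visits (no per-call conversion overhead).
    """
    d = lengths.copy()
    np.fill_diagonal(d, 0.0)
    for k in range(d.shape[0]):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def degree_preserving_rewire(net: BinaryNetwork, params: NullEnsembleParams) -> RewireResult:
    """Maslov–Sneppen double-edge swaps: ``swaps_per_edge * E`` attempts,
    rejecting self-loops and multi-edges; the degree sequence is preserved.

    Graphs admitting no valid swap (e.g. complete graphs) come back
    unchanged with ``n_swapped == 0``.
    """
    rng = np.random.default_rng(params.seed)
    edges = sorted(net.edge_set())
    n_edges = len(edges)
    if n_edges < 2 or params.swaps_per_edge == 0:
        return RewireResult(net, 0)
    edge_lookup = set(edges)
    attempts = params.swaps_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(attempts, 2))
    orient = rng.random(attempts) < 0.5
    n_swapped = 0
    for (e1, e2), flip in zip(pick, orient):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # proposed replacement: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (b, c) if b < c else (c, b)
        if new1 in edge_lookup or new2 in edge_lookup:
            continue
        edge_lookup.discard((a, b) if a < b else (b, a))
        edge_lookup.discard((c, d) if c < d else (d, c))
        edge_lookup.add(new1)
        edge_lookup.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        n_swapped += 1
    if n_swapped == 0:
        return RewireResult(net, 0)
    adj = np.zeros_like(net.adjacency)
    idx = np.array(sorted(edge_lookup))
    adj[idx[:, 0], idx[:, 1]] = 1
    adj |= adj.T
    out = BinaryNetwork(adj, net.sparsity, net.node_labels, connected=net.connected)
    return RewireResult(out, n_swapped)


def small_world_indices(net: BinaryNetwork, params: NullEnsembleParams | None = None) -> SmallWorldIndices:
    """gamma = Cp/‹Cp_null›, lambda = Lp/‹Lp_null›, sigma = gamma/lambda,
    against ``n_random`` degree-preserving rewirings.
    """
    params = params or NullEnsembleParams()
    if params.swaps_per_edge == 0:
        # ensemble of the graph itself: ratios are exactly 1 by definition
        return SmallWorldIndices(1.0, 1.0, 1.0)
    _, cp_real = clustering_coefficient(net)
    lp_real = characteristic_path_length(net).value
    child_seeds = np.random.SeedSequence(params.seed).spawn(params.n_random)
    cp_null = np.empty(params.n_random)
    lp_null = np.empty(params.n_random)
    for r, seq in enumerate(child_seeds):
        null = degree_preserving_rewire(
            net, NullEnsembleParams(1, params.swaps_per_edge, int(seq.generate_state(1)[0]))
        ).network
        _, cp_null[r] = clustering_coefficient(null)
        lp_null[r] = characteristic_path_length(null).value
    cp_bar = cp_null.mean()
    lp_bar = lp_null.mean()
    if cp_bar == 0:
        raise ValueError("null ensemble has zero mean clustering; gamma undefined")
    gamma = cp_real / cp_bar
    lambda_ = lp_real / lp_bar
    return SmallWorldIndices(float(gamma), float(lambda_), float(gamma / lambda_))


def across_threshold_summary(rows: pd.DataFrame, method: str = "mean") -> pd.Series:
    """Collapse per-threshold metric rows into one summary value per metric.

    ``mean`` is the arithmetic mean over thresholds; ``auc`` integrates each
    metric over the sparsity axis (trapezoid rule).
    """
    metrics = [m for m in GLOBAL_METRICS if m in rows.columns]
    if not metrics:
        raise ValueError("no metric columns to summarize")
    if method == "mean":
        return rows[metrics].mean()
    if method == "auc":
        s = rows["sparsity"].to_numpy()
        return pd.Series({m: np.trapezoid(rows[m].to_numpy(), s) for m in metrics})
    raise ValueError(f"unknown summary method {method!r}")


@dataclass(frozen=True)
class GlobalMetricProfile:
    """Per-threshold global metrics plus an across-threshold summary."""

    rows: pd.DataFrame  # columns: sparsity + GLOBAL_METRICS
    summary_method: str = "mean"

    def __post_init__(self) -> None:
        required = {"sparsity", *GLOBAL_METRICS}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"profile rows missing columns: {sorted(missing)}")
        if self.summary_method not in ("mean", "auc"):
            raise ValueError(f"unknown summary method {self.summary_method!r}")
        ratio = self.rows["gamma"] / self.rows["lambda_"]
        if not np.allclose(ratio, self.rows["sigma"], atol=1e-9):
            raise ValueError("sigma must equal gamma / lambda_ per row")

    @property
    def summary(self) -> pd.Series:
        """Arithmetic mean (or trapezoidal AUC) of each metric over thresholds."""
        return across_threshold_summary(self.rows, self.summary_method)

    @classmethod
    def from_rows(cls, rows: list[dict], summary_method: str = "mean") -> "GlobalMetricProfile":
        return cls(pd.DataFrame(rows), summary_method)


@dataclass(frozen=True)
class NodalMetricProfile:
    """Per-node efficiency metrics across the threshold grid.

    ``nodal_e`` and ``nodal_eloc`` are node x sparsity DataFrames; the
    across-threshold mean is exposed per node.
    """

    nodal_e: pd.DataFrame
    nodal_eloc: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.nodal_e.index.equals(self.nodal_eloc.index):
            raise ValueError("nodal_e and nodal_eloc must share node labels")

    @property
    def nodal_e_mean(self) -> pd.Series:
        return self.nodal_e.mean(axis=1)

    @property
    def nodal_eloc_mean(self) -> pd.Series:
        return self.nodal_eloc.mean(axis=1)


def metric_profiles(
    z: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    null_params: NullEnsembleParams | None = None,
    summary_method: str = "mean",
) -> tuple[GlobalMetricProfile, NodalMetricProfile]:
    """Binarize ``z`` at every grid threshold and compute all metrics.

    Null seeds are derived deterministically from ``null_params.seed`` and
    the threshold index, so the whole profile is reproducible.
    """
    grid = grid or SparsityGrid()
    null_params = null_params or NullEnsembleParams()
    rows = []
    nodal_e_cols: dict[float, np.ndarray] = {}
    nodal_eloc_cols: dict[float, np.ndarray] = {}
    for t_idx, s in enumerate(grid):
        net = binarize_at_sparsity(z, s)
        _, cp = clustering_coefficient(net)
        lp = characteristic_path_length(net).value
        eloc_nodes, eloc = local_efficiency(net)
        nodal_e = nodal_efficiency(net)
        per_threshold = NullEnsembleParams(
            null_params.n_random,
            null_params.swaps_per_edge,
            int(np.random.SeedSequence([null_params.seed, t_idx]).generate_state(1)[0]),
        )
        gamma, lambda_, sigma = small_world_indices(net, per_threshold)
        rows.append(
            {
                "sparsity": float(s),
                "gamma": gamma,
                "lambda_": lambda_,
                "sigma": sigma,
                "cp": cp,
                "lp": lp,
                "eglob": float(nodal_e.mean()),
                "eloc": eloc,
            }
        )
        nodal_e_cols[float(s)] = nodal_e
        nodal_eloc_cols[float(s)] = eloc_nodes
    labels = list(z.node_labels)
    nodal = NodalMetricProfile(
        pd.DataFrame(nodal_e_cols, index=labels),
        pd.DataFrame(nodal_eloc_cols, index=labels),
    )
    return GlobalMetricProfile(pd.DataFrame(rows), summary_method), nodal


def global_profile(
    z: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    null_params: NullEnsembleParams | None = None,
    summary_method: str = "mean",
) -> GlobalMetricProfile:
    """Global metrics only; see :func:`metric_profiles`."""
    profile, _ = metric_profiles(z, grid, null_params, summary_method)
    return profile


def weighted_metrics(net: WeightedNetwork) -> dict:
    """Weighted analogues of the binary metric set.

    Distances use edge lengths 1/weight; clustering uses the Onnela
    geometric-mean rule with weights normalized by the maximum weight.
    With 0/1 weights every value reduces to its binary counterpart.
    """
    w = net.weights
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        raise ValueError("weighted network has no edges")
    w_hat = np.cbrt(w / wmax)
    k = (w > 0).sum(axis=1).astype(float)
    triangles = np.einsum("ij,jk,ki->i", w_hat, w_hat, w_hat) / 2.0
    denom = k * (k - 1)
    cp_nodes = np.divide(2.0 * triangles, denom, out=np.zeros(n), where=denom > 0)
    d = shortest_path_matrix(net)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else float("inf")
    nodal_e = nodal_efficiency(net)
    eloc_nodes, eloc = local_efficiency(net)
    return {
        "cp": float(cp_nodes.mean()),
        "cp_nodes": cp_nodes,
        "lp": lp,
        "disconnected": bool(finite.sum() < off.sum()),
        "eglob": float(nodal_e.mean()),
        "nodal_e": nodal_e,
        "eloc": eloc,
        "nodal_eloc": eloc_nodes,
    }
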
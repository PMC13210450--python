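"""Weighted-graph summaries of an ROI connectivity matrix.

Conventions follow the Brain Connectivity Toolbox: connection weights
W ∈ [0, 1] (the PLV matrix with its diagonal zeroed) are mapped to
lengths L = 1/W (∞ for absent edges); shortest-path distances d_ij come
from Dijkstra on L.

* nodal strength        s_i = Σ_j W_ij
* global efficiency     E = mean over ordered pairs of 1/d_ij (1/∞ = 0)
* clustering (Onnela)   C_i = Σ_{jk} (ŵ_ij ŵ_jk ŵ_ik)^{1/3} / (k_i (k_i−1)),
                        ŵ = W / max(W), k_i = number of nonzero W_ij,
                        C_i = 0 when k_i < 2
* local efficiency      E_loc(i) = global efficiency of the subgraph
                        induced by the neighbors of i (weights
                        restricted), 0 when k_i < 2

Metrics are always computed on the full weighted matrix; the 0.7
visualization threshold never enters here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix
from .errors import InvalidArgumentError


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float).copy()
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidArgumentError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise InvalidArgumentError("weight matrix must be symmetric")
        if np.any(W < 0):
            raise InvalidArgumentError("weights must be non-negative")
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @classmethod
    def from_connectivity(cls, matrix: ConnectivityMatrix) -> "WeightedGraph":
        return cls(weights=matrix.values, labels=tuple(matrix.labels))

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def lengths(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            L = 1.0 / self.weights
        L[self.weights == 0] = np.inf
        return L


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    L = np.zeros_like(W)
    nz = W > 0
    L[nz] = 1.0 / W[nz]
    # csgraph treats 0 as "no edge"; mask handled via nz
    return dijkstra(np.where(nz, L, 0.0), directed=False, unweighted=False)


def _efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(W)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_strength(graph: WeightedGraph) -> pd.Series:
    """Total connection weight per node."""
    return pd.Series(graph.weights.sum(axis=1), index=list(graph.labels), name="strength")


def global_efficiency(graph: WeightedGraph) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    if graph.n < 2:
        raise InvalidArgumentError("global efficiency needs at least 2 nodes")
    return _efficiency(graph.weights)


def clustering_coefficient(graph: WeightedGraph) -> pd.Series:
    """Onnela weighted clustering coefficient per node."""
    W = graph.weights
    wmax = W.max()
    out = np.zeros(graph.n)
    if wmax > 0:
        cube = np.cbrt(W / wmax)
        triangles = np.diagonal(cube @ cube @ cube)  # 2 × weighted triangle count
        k = (W > 0).sum(axis=1)
        valid = k >= 2
        out[valid] = triangles[valid] / (k[valid] * (k[valid] - 1))
    return pd.Series(out, index=list(graph.labels), name="clustering")


def local_efficiency(graph: WeightedGraph) -> pd.Series:
    """Global efficiency of each node's neighbor-induced subgraph."""
    W = graph.weights
    out = np.zeros(graph.n)
    for i in range(graph.n):
        nbrs = np.nonzero(W[i])[0]
        if len(nbrs) >= 2:
            out[i] = _efficiency(W[np.ix_(nbrs, nbrs)])
    return pd.Series(out, index=list(graph.labels), name="local_efficiency")


def network_summary(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """One-row-per-node metric table plus the global efficiency scalar
    (repeated in a ``global_efficiency`` column for flat writing)."""
    g = WeightedGraph.from_connectivity(matrix)
    df = pd.concat(
        [nodal_strength(g), clustering_coefficient(g), local_efficiency(g)], axis=1
    )
    df.insert(0, "global_efficiency", global_efficiency(g))
    df.index.name = "node"
    return df
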
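"""Binary graph metrics: clustering, path length, efficiencies, small-worldness.

Conventions (binary, undirected, simple graphs throughout):

* C — Watts–Strogatz mean local clustering: average over all nodes of the
  fraction of a node's neighbour pairs that are connected; nodes of degree
  < 2 contribute 0.
* L — characteristic path length: mean shortest-path hop distance over
  *reachable* ordered pairs. Unreachable pairs are excluded and counted,
  never imputed; a graph with no reachable pair has no defined L. This
  makes L sensitive to fragmentation of sparse thresholded networks, which
  is why global efficiency is reported alongside.
* E_glob — Latora–Marchiori global efficiency: mean of 1/d(i, j) over
  ordered pairs with 1/inf = 0; robust to fragmentation.
* E_loc — mean over nodes of the global efficiency of the subgraph induced
  by the node's neighbours (node itself excluded); degree < 2 contributes 0.
* sigma — small-worldness (C / C_rand) / (L / L_rand), with C_rand and
  L_rand ensemble means over degree-preserving rewired nulls by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryNetwork
from .nulls import NullEnsembleSpec, null_ensemble

try:
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _local_efficiency_kernel_py(adj):
    # per-node BFS over the neighbourhood-induced subgraph
    n = adj.shape[0]
    total = 0.0
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        inv_sum = 0.0
        dist = np.empty(k, np.int64)
        queue = np.empty(k, np.int64)
        for s in range(k):
            for t in range(k):
                dist[t] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                for v in range(k):
                    if dist[v] < 0 and adj[nbrs[u], nbrs[v]]:
                        dist[v] = dist[u] + 1
                        queue[tail] = v
                        tail += 1
            for t in range(k):
                if t != s and dist[t] > 0:
                    inv_sum += 1.0 / dist[t]
        total += inv_sum / (k * (k - 1))
    return total / n


_local_efficiency_kernel = (
    njit(cache=True)(_local_efficiency_kernel_py)
    if njit is not None
    else _local_efficiency_kernel_py
)


def _bfs_all_pairs_py(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


_bfs_all_pairs = (
    njit(cache=True)(_bfs_all_pairs_py) if njit is not None else None
)

__all__ = [
    "MetricVector",
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "small_worldness",
    "metric_vector",
]

#: Canonical ordering of the five graph metrics in tables.
METRIC_NAMES = ("C", "L", "sigma", "E_glob", "E_loc")


@dataclass(frozen=True)
class MetricVector:
    C: float
    L: float
    E_glob: float
    E_loc: float
    sigma: float
    n_unreachable_pairs: int
    density: float

    def as_dict(self) -> dict[str, float]:
        return {
            "C": self.C,
            "L": self.L,
            "sigma": self.sigma,
            "E_glob": self.E_glob,
            "E_loc": self.E_loc,
        }


def clustering_coefficient(g: BinaryNetwork) -> float:
    a = g.adjacency.astype(np.float64)
    deg = a.sum(axis=0)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0  # diag(A^3)/2 via BLAS
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return float(local.mean())


def shortest_path_lengths(g: BinaryNetwork) -> np.ndarray:
    """All-pairs BFS hop distances; unreachable pairs are ``inf``."""
    if g.n_edges == 0:
        d = np.full((g.n_nodes, g.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    if _bfs_all_pairs is not None:
        return _bfs_all_pairs(np.ascontiguousarray(g.adjacency))
    return shortest_path(csr_matrix(g.adjacency), method="D", unweighted=True)


def _char_path_from_distances(dist: np.ndarray) -> tuple[float, int]:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise ValueError("no reachable pairs: characteristic path length undefined")
    return float(dist[finite].mean()), n_unreachable


def characteristic_path_length(g: BinaryNetwork) -> tuple[float, int]:
    """(L, number of unreachable ordered pairs)."""
    return _char_path_from_distances(shortest_path_lengths(g))


def _global_eff_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / dist, 0.0)
    return float(inv[off].mean())


def global_efficiency(g: BinaryNetwork) -> float:
    return _global_eff_from_distances(shortest_path_lengths(g))


def local_efficiency(g: BinaryNetwork) -> float:
    if g.n_nodes == 0:
        return 0.0
    return float(_local_efficiency_kernel(np.ascontiguousarray(g.adjacency)))


def null_reference_means(
    g: BinaryNetwork, nulls: NullEnsembleSpec
) -> tuple[float, float]:
    """Ensemble means (C_rand, L_rand) over the seeded null ensemble."""
    cs, ls = [], []
    for null in null_ensemble(g, nulls):
        cs.append(clustering_coefficient(null))
        ls.append(characteristic_path_length(null)[0])
    return float(np.mean(cs)), float(np.mean(ls))


def small_worldness(g: BinaryNetwork, nulls: NullEnsembleSpec) -> float:
    """sigma = (C / C_rand) / (L / L_rand); > 1 indicates small-world order."""
    c = clustering_coefficient(g)
    length, _ = characteristic_path_length(g)
    c_rand, l_rand = null_reference_means(g, nulls)
    if c_rand == 0:
        raise ValueError("degenerate null ensemble: C_rand = 0")
    return (c / c_rand) / (length / l_rand)


def metric_vector(g: BinaryNetwork, nulls: NullEnsembleSpec) -> MetricVector:
    """All five metrics of one thresholded network (distances computed once)."""
    dist = shortest_path_lengths(g)
    c = clustering_coefficient(g)
    length, n_unreach = _char_path_from_distances(dist)
    e_glob = _global_eff_from_distances(dist)
    e_loc = local_efficiency(g)
    c_rand, l_rand = null_reference_means(g, nulls)
    if c_rand == 0:
        raise ValueError("degenerate null ensemble: C_rand = 0")
    sigma = (c / c_rand) / (length / l_rand)
    return MetricVector(
        C=c,
        L=length,
        E_glob=e_glob,
        E_loc=e_loc,
        sigma=sigma,
        n_unreachable_pairs=n_unreach,
        density=g.density,
    )
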
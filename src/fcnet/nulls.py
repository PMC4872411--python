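"""Random reference networks for small-worldness normalisation.

The default null model is Maslov–Sneppen degree-preserving rewiring:
repeated double-edge swaps (a–b, c–d -> a–d, c–b) that keep the degree
sequence exactly while randomising topology. An Erdos–Renyi null with
matched node and edge counts is available as an alternative. Connectedness
of nulls is deliberately not enforced — rejection sampling for connectivity
biases the ensemble — so path-length statistics on nulls use the same
reachable-pairs convention as on data networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import BinaryNetwork

logger = logging.getLogger(__name__)

try:  # optional JIT of the swap kernel; the pure-Python path is identical
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _swap_kernel_py(adj, edges, picks, flips):
    accepted = 0
    for t in range(picks.shape[0]):
        e1, e2 = picks[t, 0], picks[t, 1]
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if flips[t]:
            c, d = d, c
        # propose a-b, c-d -> a-d, c-b
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1, 0], edges[e1, 1] = min(a, d), max(a, d)
        edges[e2, 0], edges[e2, 1] = min(c, b), max(c, b)
        accepted += 1
    return accepted


_swap_kernel = njit(cache=True)(_swap_kernel_py) if njit is not None else _swap_kernel_py

__all__ = [
    "NullEnsembleSpec",
    "rewire_degree_preserving",
    "erdos_renyi_matched",
    "null_ensemble",
]


@dataclass(frozen=True)
class NullEnsembleSpec:
    n_nulls: int = 100
    swaps_per_edge: int = 10
    method: str = "rewire_degree_preserving"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")
        if self.method not in ("rewire_degree_preserving", "erdos_renyi_matched"):
            raise ValueError(f"unknown null method {self.method!r}")


def rewire_degree_preserving(
    g: BinaryNetwork,
    spec: NullEnsembleSpec = NullEnsembleSpec(),
    rng: np.random.Generator | None = None,
) -> BinaryNetwork:
    """One degree-preserving rewired null of ``g``.

    Attempts ``swaps_per_edge * |E|`` double-edge swaps (attempts, not
    successes); a swap is accepted only if it creates no self-loop or
    multi-edge. If no swap is ever accepted the input is returned as a copy
    with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    m = g.n_edges
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    adj = g.adjacency.astype(np.uint8).copy()
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    attempts = spec.swaps_per_edge * m
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    accepted = _swap_kernel(adj, edges, picks, flips)
    if accepted == 0:
        logger.warning(
            '{"event": "rewire_no_legal_swap", "n_edges": %d, "attempts": %d}',
            m,
            attempts,
        )
    else:
        logger.debug(
            '{"event": "rewire_acceptance", "rate": %.4f}', accepted / attempts
        )
    return BinaryNetwork(
        adjacency=adj,
        density=g.density,
        region_labels=list(g.region_labels),
    )


def erdos_renyi_matched(
    g: BinaryNetwork,
    spec: NullEnsembleSpec = NullEnsembleSpec(),
    rng: np.random.Generator | None = None,
) -> BinaryNetwork:
    """G(N, M) null with the node and edge counts of ``g``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, m = g.n_nodes, g.n_edges
    iu, ju = np.triu_indices(n, 1)
    chosen = rng.choice(iu.size, size=m, replace=False)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[chosen], ju[chosen]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj, density=g.density, region_labels=list(g.region_labels)
    )


def null_ensemble(
    g: BinaryNetwork, spec: NullEnsembleSpec = NullEnsembleSpec()
) -> list[BinaryNetwork]:
    """Seeded ensemble of ``n_nulls`` reference networks.

    Reproducible bit-exactly for a given (graph, spec): each null gets its
    own child stream of ``spec.seed``. Degree sequence (rewired) or edge
    count (ER) conservation is asserted on every null.
    """
    maker = (
        rewire_degree_preserving
        if spec.method == "rewire_degree_preserving"
        else erdos_renyi_matched
    )
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_nulls)
    out = []
    deg = g.adjacency.sum(axis=0)
    for ss in streams:
        null = maker(g, spec, rng=np.random.default_rng(ss))
        if spec.method == "rewire_degree_preserving":
            assert np.array_equal(null.adjacency.sum(axis=0), deg)
        assert null.n_edges == g.n_edges
        assert np.all(np.diag(null.adjacency) == 0)
        out.append(null)
    return out
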
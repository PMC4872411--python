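"""Census of the eight connected undirected 3–4-node motif classes.

There are exactly two isomorphism classes of connected undirected graphs on
three nodes (the 3-path and the triangle) and six on four nodes (4-path,
4-star, 4-cycle, paw, diamond, K4) — eight classes in all. Counting is of
*induced* connected subgraphs, so the classes partition all connected 3- and
4-node vertex sets and, e.g., a diamond is never double-counted as two
4-cycles. Classes containing a cycle (triangle, 4-cycle, paw, diamond, K4)
form the "cyclic" family; the trees (3-path, 4-path, 4-star) the "acyclic"
family — the contrast the group analysis tests.

Two counting routes are provided: closed-form matrix identities (default;
fast enough for density sweeps over hundreds of sessions) and an ESU-style
connected-subgraph enumeration used as a structural cross-check. For
graphs on at most four nodes the pair (node count, edge count, sorted
degree sequence) is a complete isomorphism invariant, which is what both
routes use to classify.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .connectivity import BinaryNetwork

__all__ = [
    "MotifClass",
    "MotifCensus",
    "MOTIF_ORDER",
    "CYCLIC_CLASSES",
    "ACYCLIC_CLASSES",
    "motif_catalogue",
    "census",
    "census_enumerate",
    "cyclic_acyclic_totals",
]

#: Fixed output ordering of the eight classes (3-node first, then by edges).
MOTIF_ORDER = (
    "3-path",
    "triangle",
    "4-path",
    "4-star",
    "4-cycle",
    "paw",
    "diamond",
    "K4",
)
CYCLIC_CLASSES = frozenset({"triangle", "4-cycle", "paw", "diamond", "K4"})
ACYCLIC_CLASSES = frozenset({"3-path", "4-path", "4-star"})

# (n_nodes, n_edges, sorted degree sequence) -> class name; complete for <= 4 nodes
_SIGNATURE_TO_NAME = {
    (3, 2, (1, 1, 2)): "3-path",
    (3, 3, (2, 2, 2)): "triangle",
    (4, 3, (1, 1, 2, 2)): "4-path",
    (4, 3, (1, 1, 1, 3)): "4-star",
    (4, 4, (2, 2, 2, 2)): "4-cycle",
    (4, 4, (1, 2, 2, 3)): "paw",
    (4, 5, (2, 2, 3, 3)): "diamond",
    (4, 6, (3, 3, 3, 3)): "K4",
}


@dataclass(frozen=True)
class MotifClass:
    name: str
    n_nodes: int
    n_edges: int
    degree_sequence: tuple[int, ...]
    cyclic: bool
    canonical_edges: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MotifCensus:
    """Counts of induced connected 3- and 4-node subgraphs by class."""

    counts: dict[str, int]
    density: float = float("nan")

    def __post_init__(self) -> None:
        if set(self.counts) != set(MOTIF_ORDER):
            raise ValueError("census must cover exactly the 8 motif classes")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")


def _is_connected_small(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in np.nonzero(adj[u])[0]:
            if v not in seen:
                seen.add(int(v))
                frontier.append(int(v))
    return len(seen) == n


def motif_catalogue() -> list[MotifClass]:
    """Enumerate all connected-graph isomorphism classes on 3 and 4 nodes.

    Built by exhaustive enumeration of labelled graphs (8 graphs on 3
    nodes, 64 on 4), grouped by the complete signature above; returned in
    the fixed :data:`MOTIF_ORDER`. A class is cyclic iff it has at least as
    many edges as nodes (trees are the only connected acyclic graphs).
    """
    found: dict[tuple, tuple[tuple[int, int], ...]] = {}
    for k in (3, 4):
        pairs = list(itertools.combinations(range(k), 2))
        for mask in range(1 << len(pairs)):
            adj = np.zeros((k, k), dtype=int)
            edges = []
            for b, (i, j) in enumerate(pairs):
                if mask >> b & 1:
                    adj[i, j] = adj[j, i] = 1
                    edges.append((i, j))
            if not _is_connected_small(adj):
                continue
            sig = (k, len(edges), tuple(sorted(adj.sum(axis=0).tolist())))
            found.setdefault(sig, tuple(edges))
    classes = []
    for sig, edges in found.items():
        name = _SIGNATURE_TO_NAME[sig]
        classes.append(
            MotifClass(
                name=name,
                n_nodes=sig[0],
                n_edges=sig[1],
                degree_sequence=sig[2],
                cyclic=sig[1] >= sig[0],
                canonical_edges=edges,
            )
        )
    classes.sort(key=lambda c: MOTIF_ORDER.index(c.name))
    return classes


def census(g: BinaryNetwork, method: str = "matrix") -> MotifCensus:
    """Count induced connected 3- and 4-node subgraphs of each class.

    ``method="matrix"`` (default) uses exact combinatorial identities on the
    adjacency matrix (degree/triangle/common-neighbour counts with
    inclusion–exclusion down to induced counts); ``method="enumerate"`` runs
    the ESU connected-subgraph enumeration. Both return identical counts;
    the matrix route is the fast path for whole-study density sweeps.
    """
    if method == "enumerate":
        return census_enumerate(g)
    if method != "matrix":
        raise ValueError(f"unknown census method {method!r}")
    a = g.adjacency.astype(np.int64)
    n = a.shape[0]
    d = a.sum(axis=0)
    a2 = a @ a
    a3 = a2 @ a
    tri_total = int(np.trace(a3)) // 6
    t_node = np.diag(a3) // 2  # triangles through each node
    wedges = int((d * (d - 1) // 2).sum())
    p3 = wedges - 3 * tri_total

    iu, ju = np.nonzero(np.triu(a, 1))
    c_uv = a2[iu, ju]  # common neighbours per edge
    m = iu.size

    # K4: per edge, adjacent pairs inside the common neighbourhood
    k4_6 = 0
    ab = a.astype(bool)
    for u, v in zip(iu, ju):
        common = np.nonzero(ab[u] & ab[v])[0]
        if common.size >= 2:
            k4_6 += int(a[np.ix_(common, common)].sum()) // 2
    k4 = k4_6 // 6

    diamonds_ni = int((c_uv * (c_uv - 1) // 2).sum())
    diamond = diamonds_ni - 6 * k4

    paw_ni = int((t_node * (d - 2)).sum())
    paw = paw_ni - 4 * diamond - 12 * k4

    tr_a4 = int(np.trace(a2 @ a2))
    c4_ni = (tr_a4 - 2 * m - 2 * int((d * (d - 1)).sum())) // 8
    c4 = c4_ni - diamond - 3 * k4

    star_ni = int((d * (d - 1) * (d - 2) // 6).sum())
    star = star_ni - paw - 2 * diamond - 4 * k4

    p4_ni = int(((d[iu] - 1) * (d[ju] - 1) - c_uv).sum())
    p4 = p4_ni - 2 * paw - 4 * c4 - 6 * diamond - 12 * k4

    counts = {
        "3-path": p3,
        "triangle": tri_total,
        "4-path": p4,
        "4-star": star,
        "4-cycle": c4,
        "paw": paw,
        "diamond": diamond,
        "K4": k4,
    }
    assert all(v >= 0 for v in counts.values()), counts
    return MotifCensus(counts=counts, density=g.density)


def _classify(adj_sub: np.ndarray) -> str | None:
    k = adj_sub.shape[0]
    if not _is_connected_small(adj_sub):
        return None
    sig = (k, int(adj_sub.sum()) // 2, tuple(sorted(adj_sub.sum(axis=0).tolist())))
    return _SIGNATURE_TO_NAME[sig]


def _esu_extend(adj_sets, sub, extension, v_root, size, out):
    if len(sub) == size:
        out.append(tuple(sub))
        return
    while extension:
        w = extension.pop()
        # exclusive neighbourhood: neighbours of w beyond root and current sub
        excl = {
            u
            for u in adj_sets[w]
            if u > v_root and u not in sub and not (adj_sets[u] & set(sub))
        }
        _esu_extend(adj_sets, sub + [w], extension | excl, v_root, size, out)


def census_enumerate(g: BinaryNetwork) -> MotifCensus:
    """ESU enumeration: visit each connected 3-/4-node vertex set once."""
    a = g.adjacency.astype(bool)
    n = g.n_nodes
    adj_sets = [set(np.nonzero(a[i])[0].tolist()) for i in range(n)]
    counts = {name: 0 for name in MOTIF_ORDER}
    for size in (3, 4):
        sets: list[tuple[int, ...]] = []
        for v in range(n):
            ext = {u for u in adj_sets[v] if u > v}
            _esu_extend(adj_sets, [v], ext, v, size, sets)
        for vs in sets:
            name = _classify(g.adjacency[np.ix_(vs, vs)].astype(int))
            counts[name] += 1  # ESU sets are connected by construction
    return MotifCensus(counts=counts, density=g.density)


def cyclic_acyclic_totals(c: MotifCensus) -> tuple[int, int]:
    """(cyclic total, acyclic total) over the fixed class partition."""
    cyc = sum(v for k, v in c.counts.items() if k in CYCLIC_CLASSES)
    acyc = sum(v for k, v in c.counts.items() if k in ACYCLIC_CLASSES)
    return cyc, acyc
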
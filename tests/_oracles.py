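"""Brute-force oracles shared across test modules."""

import itertools

import networkx as nx
import numpy as np

from fcnet.motifs import MOTIF_ORDER

# (n_nodes, n_edges, sorted degree sequence) -> class; complete for <= 4 nodes
SIGNATURES = {
    (3, 2, (1, 1, 2)): "3-path",
    (3, 3, (2, 2, 2)): "triangle",
    (4, 3, (1, 1, 2, 2)): "4-path",
    (4, 3, (1, 1, 1, 3)): "4-star",
    (4, 4, (2, 2, 2, 2)): "4-cycle",
    (4, 4, (1, 2, 2, 3)): "paw",
    (4, 5, (2, 2, 3, 3)): "diamond",
    (4, 6, (3, 3, 3, 3)): "K4",
}


def brute_force_census(adj: np.ndarray) -> dict[str, int]:
    """Oracle: test every 3- and 4-node vertex subset for connected class."""
    n = adj.shape[0]
    counts = {name: 0 for name in MOTIF_ORDER}
    for k in (3, 4):
        for subset in itertools.combinations(range(n), k):
            sub = adj[np.ix_(subset, subset)]
            g = nx.from_numpy_array(sub)
            if not nx.is_connected(g):
                continue
            sig = (k, int(sub.sum()) // 2, tuple(sorted(sub.sum(axis=0).tolist())))
            counts[SIGNATURES[sig]] += 1
    return counts
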
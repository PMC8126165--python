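"""JIT-compiled inner loop for degree-preserving bipartite edge swaps.

The graph lives as a boolean incidence matrix (consensus genes x patients)
plus parallel edge-endpoint arrays; a swap rewires two edges (c1,p1),(c2,p2)
into (c1,p2),(c2,p1).  A proposal is rejected (but still consumes one of the
``n_swaps`` attempts) when the two edges share an endpoint or when either
rewired edge already exists, so the incidence matrix stays 0/1 and every
node keeps its degree.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def swap_edges(adj, edge_c, edge_p, n_swaps, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edge_c.shape[0]
    applied = 0
    if n_edges < 2:
        return applied
    for _ in range(n_swaps):
        i = np.random.randint(0, n_edges)
        j = np.random.randint(0, n_edges)
        if i == j:
            continue
        c1 = edge_c[i]
        p1 = edge_p[i]
        c2 = edge_c[j]
        p2 = edge_p[j]
        if c1 == c2 or p1 == p2:
            continue
        if adj[c1, p2] or adj[c2, p1]:
            continue
        adj[c1, p1] = False
        adj[c2, p2] = False
        adj[c1, p2] = True
        adj[c2, p1] = True
        edge_p[i] = p2
        edge_p[j] = p1
        applied += 1
    return applied
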
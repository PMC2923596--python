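"""JIT-compiled inner loops for degree-preserving edge-swap dynamics.

The chains operate on a dense boolean adjacency matrix plus an (E, 2) edge
array; both are updated in place.  All randomness flows through numba's
per-thread legacy RNG, seeded explicitly, so runs are reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["edge_swap_chain", "anneal_degree_product"]


@njit(cache=False)
def edge_swap_chain(adj, edges, target_accepted, max_proposals, seed):
    """Run the hold-counting edge-swap chain in place.

    A proposal is an ordered pair of distinct edges plus one of the two
    rewiring orientations, drawn uniformly from this state-independent set.
    Proposals that would create a self-loop or a duplicate edge are counted
    as executed "stay" moves (the hold), which makes the proposal kernel
    symmetric and the stationary distribution uniform over all simple
    graphs with the given degree sequence.  Only edge-changing moves count
    as accepted.

    Returns (accepted, proposed).
    """
    np.random.seed(seed)
    E = edges.shape[0]
    accepted = 0
    proposed = 0
    while accepted < target_accepted and proposed < max_proposals:
        e1 = np.random.randint(0, E)
        e2 = np.random.randint(0, E)
        if e1 == e2:
            continue
        proposed += 1
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            x1, y1, x2, y2 = a, d, c, b
        else:
            x1, y1, x2, y2 = a, c, b, d
        if x1 == y1 or x2 == y2:
            continue
        if adj[x1, y1] or adj[x2, y2]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[x1, y1] = True
        adj[y1, x1] = True
        adj[x2, y2] = True
        adj[y2, x2] = True
        if x1 < y1:
            edges[e1, 0], edges[e1, 1] = x1, y1
        else:
            edges[e1, 0], edges[e1, 1] = y1, x1
        if x2 < y2:
            edges[e2, 0], edges[e2, 1] = x2, y2
        else:
            edges[e2, 0], edges[e2, 1] = y2, x2
        accepted += 1
    return accepted, proposed


@njit(cache=False)
def anneal_degree_product(adj, edges, deg, s_target, s_tol, max_proposals, seed):
    """Greedy degree-preserving swaps driving S = sum_edges k_i k_j to a target.

    Because swaps preserve every degree, the assortativity is an affine
    function of S, so steering S plants a chosen assortativity.  A proposed
    valid swap is applied only if it brings S strictly closer to
    ``s_target``.  Returns (S, proposed).
    """
    np.random.seed(seed)
    E = edges.shape[0]
    S = 0.0
    for e in range(E):
        S += deg[edges[e, 0]] * deg[edges[e, 1]]
    proposed = 0
    while abs(S - s_target) > s_tol and proposed < max_proposals:
        e1 = np.random.randint(0, E)
        e2 = np.random.randint(0, E)
        if e1 == e2:
            continue
        proposed += 1
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            x1, y1, x2, y2 = a, d, c, b
        else:
            x1, y1, x2, y2 = a, c, b, d
        if x1 == y1 or x2 == y2:
            continue
        if adj[x1, y1] or adj[x2, y2]:
            continue
        dS = (deg[x1] * deg[y1] + deg[x2] * deg[y2]
              - deg[a] * deg[b] - deg[c] * deg[d])
        if abs(S + dS - s_target) >= abs(S - s_target):
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[x1, y1] = True
        adj[y1, x1] = True
        adj[x2, y2] = True
        adj[y2, x2] = True
        if x1 < y1:
            edges[e1, 0], edges[e1, 1] = x1, y1
        else:
            edges[e1, 0], edges[e1, 1] = y1, x1
        if x2 < y2:
            edges[e2, 0], edges[e2, 1] = x2, y2
        else:
            edges[e2, 0], edges[e2, 1] = y2, x2
        S += dS
    return S, proposed
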
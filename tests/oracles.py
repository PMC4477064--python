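"""Independent brute-force oracles used by several test modules.

These deliberately avoid the package's vectorized code paths: ranks are
computed by explicit counting and Kendall's W by explicit loops, so agreement
with the implementation is a genuine cross-check.
"""

import numpy as np


def midranks_bruteforce(x):
    """Midranks of a sequence by pairwise counting (O(n^2))."""
    x = list(x)
    n = len(x)
    ranks = []
    for i in range(n):
        less = sum(1 for j in range(n) if x[j] < x[i])
        equal = sum(1 for j in range(n) if x[j] == x[i])
        ranks.append(less + (equal - 1) / 2.0 + 1.0)
    return ranks


def kendalls_w_bruteforce(signals):
    """Kendall's W of a K x n signal matrix via explicit loops."""
    signals = np.asarray(signals, dtype=float)
    K, n = signals.shape
    ranks = [midranks_bruteforce(signals[k]) for k in range(K)]
    rank_sums = [sum(ranks[k][i] for k in range(K)) for i in range(n)]
    rbar = sum(rank_sums) / n
    s = sum((r - rbar) ** 2 for r in rank_sums)
    return 12.0 * s / (K**2 * (n**3 - n))


def ring_neighbors_bfs(mesh, vertex, ring_order):
    """Graph-distance neighborhood by breadth-first search over face edges."""
    neighbors = {v: set() for v in range(mesh.n_vertices)}
    for a, b, c in mesh.faces:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    frontier = {vertex}
    seen = {vertex}
    out = set()
    for _ in range(ring_order):
        nxt = set()
        for u in frontier:
            nxt.update(neighbors[u])
        nxt -= seen
        out |= nxt
        seen |= nxt
        frontier = nxt
    return sorted(out)
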
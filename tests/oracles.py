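"""Independent brute-force oracles used to validate the implementation.

Deliberately naive: adjacency-matrix arithmetic, BFS by hand, binomial
tail sums and a from-scratch step-up procedure. Nothing here imports the
package's computational paths.
"""

from __future__ import annotations

from math import comb

import numpy as np


def adjacency_matrix(nodes, edges) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=int)
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    return a


def degree_oracle(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1)


def clustering_oracle(a: np.ndarray) -> list:
    """2 e_n / (k (k-1)) by explicit neighbour-pair counting; None for k<2."""
    out = []
    n = len(a)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            out.append(None)
            continue
        e = sum(a[u, v] for x, u in enumerate(nbrs) for v in nbrs[x + 1:])
        out.append(2 * e / (k * (k - 1)))
    return out


def bfs_distances(a: np.ndarray, start: int) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(a[u]):
                if v not in dist:
                    dist[int(v)] = dist[u] + 1
                    nxt.append(int(v))
        frontier = nxt
    return dist


def closeness_oracle(a: np.ndarray) -> list:
    """1 / sum of BFS distances within the node's component; None if isolated."""
    out = []
    for i in range(len(a)):
        total = sum(bfs_distances(a, i).values())
        out.append(1.0 / total if total else None)
    return out


def hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) by summing hypergeometric point masses via binomial coefficients."""
    denom = comb(big_n, n)
    total = 0
    for x in range(k, min(big_k, n) + 1):
        if n - x <= big_n - big_k:
            total += comb(big_k, x) * comb(big_n - big_k, n - x)
    return total / denom


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg from first principles: sort, scale by m/i, cummin."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
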
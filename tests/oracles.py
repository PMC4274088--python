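"""Independent brute-force oracles for the graph metrics.

Shortest paths are found by exhaustive enumeration of all simple paths
(lengths = 1/weight per edge), with no shortest-path library involved, so
these functions stay independent of the implementation they check.  Only
usable for tiny graphs.
"""

from __future__ import annotations

import numpy as np


def brute_shortest_path(w: np.ndarray, i: int, j: int) -> float:
    """Minimum total length over every simple path from i to j."""
    n = w.shape[0]
    best = np.inf

    def extend(node: int, visited: set, length: float) -> None:
        nonlocal best
        if length >= best:
            return
        if node == j:
            best = length
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                extend(nxt, visited | {nxt}, length + 1.0 / w[node, nxt])

    extend(i, {i}, 0.0)
    return best


def brute_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = brute_shortest_path(w, i, j)
            if np.isfinite(d) and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def brute_nodal_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = brute_shortest_path(w, i, j)
            if np.isfinite(d) and d > 0:
                out[i] += 1.0 / d
    return out / (n - 1)


def brute_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = brute_global_efficiency(sub)
    return out


def random_weighted_graph(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    mask = rng.random((n, n)) < density
    w = rng.uniform(0.1, 2.0, (n, n)) * mask
    w = np.triu(w, 1)
    return w + w.T
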
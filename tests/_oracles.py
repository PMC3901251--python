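"""Independent brute-force graph-metric oracles used only by the tests.

Deliberately naive: explicit edge counting, exhaustive triple/triangle
enumeration, Floyd-Warshall shortest paths, dense eigendecomposition.
Kept free of any import from the package's metric implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_density(A: np.ndarray) -> float:
    n = len(A)
    edges = sum(A[i, j] for i in range(n) for j in range(i + 1, n))
    return edges / (n * (n - 1) / 2)


def brute_clustering(A: np.ndarray) -> float:
    n = len(A)
    triangles = 0
    for i, j, k in itertools.combinations(range(n), 3):
        if A[i, j] and A[j, k] and A[i, k]:
            triangles += 1
    triples = 0
    for center in range(n):
        neigh = [v for v in range(n) if A[center, v]]
        triples += len(neigh) * (len(neigh) - 1) // 2
    if triples == 0:
        return 0.0
    return 3 * triangles / triples


def brute_efficiency(A: np.ndarray) -> float:
    n = len(A)
    INF = float("inf")
    D = [[0 if i == j else (1 if A[i, j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i][j] < INF:
                total += 1.0 / D[i][j]
    return total / (n * (n - 1) / 2)


def brute_eigenvector_centrality(A: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the largest component, unit maximum."""
    n = len(A)
    if A.sum() == 0:
        return np.zeros(n)
    # connected components by DFS
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in range(n):
                if A[v, w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    comp = max(comps, key=len)
    sub = A[np.ix_(comp, comp)].astype(float)
    vals, vecs = np.linalg.eigh(sub)
    v = np.abs(vecs[:, np.argmax(vals)])
    out = np.zeros(n)
    out[comp] = v / v.max()
    return out


def random_graph_suite(n_graphs: int, max_nodes: int, seed: int):
    """Small random adjacency matrices spanning sizes and densities."""
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = rng.uniform(0, 1)
        A = (rng.random((n, n)) < p).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        graphs.append(A)
    return graphs
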
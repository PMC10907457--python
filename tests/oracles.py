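"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (explicit loops,
exhaustive enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall_cpl(W: np.ndarray) -> float:
    """Characteristic path length by exhaustive Floyd–Warshall relaxation
    on distances 1 − w."""
    n = W.shape[0]
    INF = float("inf")
    d = [[0.0 if i == j else (1.0 - W[i][j] if W[i][j] > 0 else INF)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    vals = [d[i][j] for i in range(n) for j in range(i + 1, n)]
    return sum(vals) / len(vals)


def triple_transitivity(W: np.ndarray) -> float:
    """Weighted transitivity by explicit triple enumeration."""
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return 0.0
    num = 0.0
    triples = 0
    for i in range(n):
        neighbours = [j for j in range(n) if W[i][j] > 0]
        k = len(neighbours)
        triples += k * (k - 1)
        for j in neighbours:
            for h in neighbours:
                if j == h or W[j][h] == 0:
                    continue
                num += ((W[i][j] / wmax) * (W[i][h] / wmax) * (W[j][h] / wmax)) ** (1.0 / 3.0)
    return num / triples if triples else 0.0


def edgewise_assortativity(W: np.ndarray) -> float:
    """Weighted strength assortativity by definitional accumulation over
    (both orientations of) every edge."""
    n = W.shape[0]
    s = [sum(W[i]) for i in range(n)]
    xs, ys, ws = [], [], []
    for i in range(n):
        for j in range(n):
            if i != j and W[i][j] > 0:
                xs.append(s[i])
                ys.append(s[j])
                ws.append(W[i][j])
    H = sum(ws)
    mx = sum(w * x for w, x in zip(ws, xs)) / H
    my = sum(w * y for w, y in zip(ws, ys)) / H
    cov = sum(w * (x - mx) * (y - my) for w, x, y in zip(ws, xs, ys)) / H
    vx = sum(w * (x - mx) ** 2 for w, x in zip(ws, xs)) / H
    vy = sum(w * (y - my) ** 2 for w, y in zip(ws, ys)) / H
    denom = (vx * vy) ** 0.5
    return float("nan") if denom <= 1e-15 else cov / denom


def set_partitions(items: list):
    """All set partitions of ``items`` (exhaustive recursion)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield [[first]] + part


def partition_modularity(W: np.ndarray, blocks: list[list[int]]) -> float:
    two_m = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for block in blocks:
        for i in block:
            for j in block:
                q += W[i][j] - k[i] * k[j] / two_m
    return q / two_m


def max_modularity_enumerated(W: np.ndarray) -> float:
    """Maximum weighted Newman Q over every partition (n <= ~10)."""
    n = W.shape[0]
    return max(partition_modularity(W, p) for p in set_partitions(list(range(n))))


def all_spanning_trees_max_weight(W: np.ndarray) -> tuple[float, list]:
    """Enumerate every spanning tree of the complete graph via Prüfer
    sequences; return the maximum total weight and the argmax edge sets."""
    n = W.shape[0]
    best_w, best_trees = -np.inf, []
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = prufer_to_tree(list(seq), n)
        w = sum(W[i][j] for i, j in edges)
        if w > best_w + 1e-12:
            best_w, best_trees = w, [edges]
        elif abs(w - best_w) <= 1e-12:
            best_trees.append(edges)
    return best_w, best_trees


def prufer_to_tree(seq: list[int], n: int) -> set[tuple[int, int]]:
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = set()
    ptr = 0
    leaf = -1
    seq = list(seq)
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.add((min(leaf, v), max(leaf, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.add((min(u, v), max(u, v)))
    return edges


def spearman_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho from the definitional Pearson-on-midranks formula."""

    def midrank(a):
        order = sorted(range(len(a)), key=lambda i: a[i])
        ranks = [0.0] * len(a)
        i = 0
        while i < len(a):
            j = i
            while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx, ry = midrank(list(x)), midrank(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def random_connected_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.45) -> np.ndarray:
    """Random connected weighted undirected graph as a dense matrix."""
    import networkx as nx

    while True:
        A = rng.random((n, n)) < p
        A = np.triu(A, 1)
        A = A + A.T
        W = np.where(A, rng.random((n, n)), 0.0)
        W = np.triu(W, 1)
        W = W + W.T
        if nx.is_connected(nx.from_numpy_array(W)):
            return W
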
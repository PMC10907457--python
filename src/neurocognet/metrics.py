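"""Global and local graph metrics for individual neurocognitive networks.

Global: total strength, modularity (weighted Newman Q of a
deterministically detected partition), weighted degree assortativity,
characteristic path length (mean shortest-path distance, distance = 1 − w),
weighted transitivity, and smallworldness
``sigma = (C / C_rand) / (L / L_rand)`` against degree-preserving rewired
references.  Local: a hubness composite — the mean of min–max-normalized
strength, betweenness, closeness and eigenvector centralities — and
selection of the most influential fraction of variables by mean baseline
hubness.

Community detection is a deterministic greedy agglomeration (best ΔQ
merge, fixed tie-break) followed by single-node move refinement, so the
modularity endpoint carries no algorithmic randomness; only the
smallworldness null model consumes a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .networks import IndividualNetwork


@dataclass
class GlobalMetrics:
    strength: float
    modularity: float
    assortativity: float
    char_path_length: float
    transitivity: float
    smallworldness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "strength": self.strength,
            "modularity": self.modularity,
            "assortativity": self.assortativity,
            "char_path_length": self.char_path_length,
            "transitivity": self.transitivity,
            "smallworldness": self.smallworldness,
        }


# ---------------------------------------------------------------------------
# individual statistics on a symmetric weight matrix (zero diagonal)
# ---------------------------------------------------------------------------

def total_strength(W: np.ndarray) -> float:
    """Sum of edge weights over the (undirected) edge set."""
    return float(W.sum() / 2.0)


def modularity_value(W: np.ndarray, labels: Sequence[int]) -> float:
    """Weighted Newman modularity Q of a given partition."""
    labels = np.asarray(labels)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((W - np.outer(k, k) / two_m) * same).sum() / two_m)


def _heuristic_partition(W: np.ndarray) -> np.ndarray:
    """Deterministic modularity maximization (no random restarts).

    Starting from singletons, alternate (a) sweeps of single-node moves —
    each node may join any community or split off on its own — and
    (b) best-gain community merges, until neither changes the partition.
    Node order and tie-breaks are fixed, so the result is reproducible.
    """
    n = W.shape[0]
    two_m = W.sum()
    if two_m == 0:
        return np.zeros(n, dtype=int)
    k = W.sum(axis=1)
    labels = np.arange(n)

    def move_pass() -> bool:
        moved = False
        for v in range(n):
            a = labels[v]
            comms = sorted(set(labels.tolist()))
            s_to = {c: W[v, labels == c].sum() for c in comms}
            k_of = {c: k[labels == c].sum() for c in comms}
            s_va, k_a = s_to[a], k_of[a]
            best_gain, best_c = 1e-12, a
            for c in comms + [n + v]:  # n+v = split off alone
                if c == labels[v]:
                    continue
                s_vb = s_to.get(c, 0.0)
                k_b = k_of.get(c, 0.0)
                gain = (2 * (s_vb - s_va) / two_m
                        - 2 * k[v] * (k_b - k_a + k[v]) / two_m**2)
                if gain > best_gain + 1e-15:
                    best_gain, best_c = gain, c
            if best_c != a:
                labels[v] = best_c
                moved = True
        return moved

    def best_merge() -> bool:
        comms = sorted(set(labels.tolist()))
        k_of = {c: k[labels == c].sum() for c in comms}
        best_gain, best_pair = 1e-12, None
        for ai in range(len(comms)):
            ma = labels == comms[ai]
            for bi in range(ai + 1, len(comms)):
                mb = labels == comms[bi]
                e_ab = W[np.ix_(np.flatnonzero(ma), np.flatnonzero(mb))].sum()
                gain = 2 * e_ab / two_m - 2 * k_of[comms[ai]] * k_of[comms[bi]] / two_m**2
                if gain > best_gain + 1e-15:
                    best_gain, best_pair = gain, (comms[ai], comms[bi])
        if best_pair is None:
            return False
        labels[labels == best_pair[1]] = best_pair[0]
        return True

    changed = True
    while changed:
        changed = False
        while move_pass():
            changed = True
        if best_merge():
            changed = True
    return labels


def _exact_partition(W: np.ndarray) -> np.ndarray:
    """Globally optimal modularity partition by dynamic programming over
    vertex subsets: best[S] = max over the block containing S's lowest
    vertex of (block score + best[rest]).  O(3^n); used for small n."""
    n = W.shape[0]
    two_m = W.sum()
    if two_m == 0:
        return np.zeros(n, dtype=int)
    k = W.sum(axis=1)
    B = (W - np.outer(k, k) / two_m) / two_m

    size = 1 << n
    # f[S] = sum of B over ordered pairs within S, built incrementally
    f = np.zeros(size)
    lowbit_index = [0] * size
    for v in range(n):
        lowbit_index[1 << v] = v
    g = [np.zeros(size) for _ in range(n)]  # g[v][S] = Σ_{u∈S} B[u, v]
    for v in range(n):
        gv = g[v]
        for S in range(1, size):
            low = S & -S
            gv[S] = gv[S ^ low] + B[lowbit_index[low], v]
    for S in range(1, size):
        low = S & -S
        v = lowbit_index[low]
        rest = S ^ low
        f[S] = f[rest] + B[v, v] + 2.0 * g[v][rest]

    best = np.full(size, -np.inf)
    choice = np.zeros(size, dtype=np.int64)
    best[0] = 0.0
    for S in range(1, size):
        low = S & -S
        sub = S
        while sub:
            if sub & low:
                val = f[sub] + best[S ^ sub]
                if val > best[S]:
                    best[S] = val
                    choice[S] = sub
            sub = (sub - 1) & S
    labels = np.zeros(n, dtype=int)
    S, c = size - 1, 0
    while S:
        block = int(choice[S])
        for v in range(n):
            if block & (1 << v):
                labels[v] = c
        S ^= block
        c += 1
    return labels


#: largest node count for which the exact DP partition is used
EXACT_MODULARITY_LIMIT = 12


def detect_communities(W: np.ndarray) -> np.ndarray:
    """Community labels maximizing weighted Newman Q.

    Exact (subset dynamic programming) for networks of up to
    ``EXACT_MODULARITY_LIMIT`` nodes; deterministic move/merge heuristic
    beyond that.  Labels are relabelled 0..c-1 in node order.
    """
    n = W.shape[0]
    if n <= EXACT_MODULARITY_LIMIT:
        labels = _exact_partition(W)
    else:
        labels = _heuristic_partition(W)
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(int(lab), len(seen))
    return out


def modularity(W: np.ndarray) -> float:
    """Q of the deterministically detected partition."""
    return modularity_value(W, detect_communities(W))


def assortativity_weighted(W: np.ndarray) -> float:
    """Weighted degree (strength) assortativity: edge-weighted Pearson
    correlation of endpoint strengths (Newman 2002, weighted form).
    Returns nan for degenerate (zero-variance) strength distributions."""
    s = W.sum(axis=1)
    iu, ju = np.nonzero(np.triu(W, 1))
    if iu.size == 0:
        return float("nan")
    w = W[iu, ju]
    h = w.sum()
    x, y = s[iu], s[ju]
    mean = (w * (x + y)).sum() / (2 * h)
    var = (w * ((x - mean) ** 2 + (y - mean) ** 2)).sum() / (2 * h)
    if var <= 1e-15:
        return float("nan")
    cov = (w * (x - mean) * (y - mean)).sum() / h
    return float(cov / var)


def distance_matrix(W: np.ndarray) -> np.ndarray:
    """Edge distances 1 − w (absent edges = no direct link)."""
    D = np.where(W > 0, 1.0 - W, 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def char_path_length(W: np.ndarray) -> float:
    """Mean shortest-path distance over all unordered node pairs."""
    n = W.shape[0]
    if n < 2:
        return 0.0
    # explicit sparse graph: zero-distance edges (w = 1) kept as tiny eps,
    # absent edges truly absent (dense input would null small entries)
    from scipy.sparse import coo_matrix
    ii, jj = np.nonzero(W)
    D = coo_matrix((np.maximum(1.0 - W[ii, jj], 1e-12), (ii, jj)), shape=(n, n)).tocsr()
    sp = shortest_path(D, method="D", directed=False)
    iu = np.triu_indices(n, 1)
    d = sp[iu]
    if np.isinf(d).any():
        raise ValueError("network is disconnected")
    d = np.where(d <= n * 1e-12, 0.0, d)
    return float(d.mean())


def transitivity_weighted(W: np.ndarray) -> float:
    """Weighted transitivity: geometric-mean triangle intensity over the
    number of connected triples (weights normalized by the maximum)."""
    wmax = W.max()
    if wmax == 0:
        return 0.0
    Wh = (W / wmax) ** (1.0 / 3.0)
    triangles = np.trace(Wh @ Wh @ Wh)  # = sum_i 2*t_i with t_i as half-sums
    k = (W > 0).sum(axis=1)
    triples = (k * (k - 1)).sum()
    if triples == 0:
        return 0.0
    return float(triangles / triples)


def _rewired_reference(G: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving rewiring (connected double edge swaps) with the
    original weight multiset re-assigned to the rewired edges."""
    H = nx.Graph()
    H.add_nodes_from(G.nodes())
    H.add_edges_from(G.edges())
    m = H.number_of_edges()
    if m > 1 and H.number_of_nodes() > 3:
        seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.connected_double_edge_swap(H, nswap=4 * m, seed=seed)
        except nx.NetworkXError:
            pass  # too few swappable pairs; keep original topology
    weights = sorted(d["weight"] for _, _, d in G.edges(data=True))
    perm = rng.permutation(m)
    for idx, (u, v) in enumerate(sorted(H.edges())):
        w = weights[perm[idx]]
        H[u][v]["weight"] = w
        H[u][v]["distance"] = max(1.0 - w, 0.0)
    return H


def _graph_to_matrix(G: nx.Graph, nodes: Optional[list] = None) -> np.ndarray:
    nodes = nodes or sorted(G.nodes())
    return nx.to_numpy_array(G, nodelist=nodes, weight="weight")


def smallworldness(W: np.ndarray, n_random: int = 20, seed: int = 0) -> float:
    """``(C/C_rand) / (L/L_rand)`` vs degree-preserving rewired graphs.

    Stochastic only through ``seed``; nan when a ratio is undefined
    (e.g. zero path length on a complete unit-weight graph).
    """
    rng = np.random.default_rng(seed)
    G = nx.from_numpy_array(W)
    c = transitivity_weighted(W)
    length = char_path_length(W)
    cr, lr = [], []
    for _ in range(n_random):
        H = _rewired_reference(G, rng)
        Wr = _graph_to_matrix(H, nodes=list(range(W.shape[0])))
        cr.append(transitivity_weighted(Wr))
        try:
            lr.append(char_path_length(Wr))
        except ValueError:
            continue
    c_rand, l_rand = float(np.mean(cr)), float(np.mean(lr)) if lr else float("nan")
    if not np.isfinite(l_rand) or c_rand == 0 or l_rand == 0 or length == 0:
        return float("nan")
    return float((c / c_rand) / (length / l_rand))


# ---------------------------------------------------------------------------
# public per-network entry points
# ---------------------------------------------------------------------------

def _weights_of(net) -> np.ndarray:
    if isinstance(net, IndividualNetwork):
        return net.weights
    return np.asarray(net, dtype=float)


def global_metrics(net, n_random: int = 20, seed: int = 0) -> GlobalMetrics:
    """All six global statistics of a connected weighted network."""
    W = _weights_of(net)
    if W.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    return GlobalMetrics(
        strength=total_strength(W),
        modularity=modularity(W),
        assortativity=assortativity_weighted(W),
        char_path_length=char_path_length(W),
        transitivity=transitivity_weighted(W),
        smallworldness=smallworldness(W, n_random=n_random, seed=seed),
    )


def _minmax(values: np.ndarray, metric: str) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo <= 1e-12:
        warnings.warn(f"degenerate normalization for {metric}; contributing 0.5")
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def hubness(net) -> pd.DataFrame:
    """Composite node importance: mean of min–max-normalized strength,
    betweenness, closeness and eigenvector centralities (path-based ones
    on distance 1 − w)."""
    if isinstance(net, IndividualNetwork):
        G = net.to_graph()
        nodes = net.nodes
    else:
        W = np.asarray(net, dtype=float)
        G = nx.from_numpy_array(W)
        for u, v, d in G.edges(data=True):
            d["distance"] = max(1.0 - d["weight"], 0.0)
        nodes = list(G.nodes())
    strength = np.array([G.degree(v, weight="weight") for v in nodes], dtype=float)
    btw = nx.betweenness_centrality(G, weight="distance", normalized=True)
    cls = nx.closeness_centrality(G, distance="distance")
    # leading eigenvector of the symmetric weight matrix (deterministic,
    # Perron vector of a connected non-negative matrix)
    Wm = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    eigval, eigvec = np.linalg.eigh(Wm)
    lead = np.abs(eigvec[:, int(np.argmax(eigval))])
    eig = {v: float(lead[i]) for i, v in enumerate(nodes)}
    comp = pd.DataFrame(
        {
            "strength": _minmax(strength, "strength"),
            "betweenness": _minmax(np.array([btw[v] for v in nodes]), "betweenness"),
            "closeness": _minmax(np.array([cls[v] for v in nodes]), "closeness"),
            "eigenvector": _minmax(np.array([eig[v] for v in nodes]), "eigenvector"),
        },
        index=pd.Index(nodes, name="node"),
    )
    comp["hubness"] = comp.mean(axis=1)
    return comp


def hubness_table(networks: Sequence[IndividualNetwork]) -> pd.DataFrame:
    """Tidy hubness for a list of networks."""
    rows = []
    for net in networks:
        h = hubness(net)
        for node, r in h.iterrows():
            rows.append({"participant": net.participant_id, "timepoint": net.timepoint,
                         "variable": node, **r.to_dict()})
    return pd.DataFrame(rows)


def select_top_hubs(baseline_hubness: pd.DataFrame, fraction: float = 0.20) -> list[str]:
    """Variables with highest mean baseline hubness across participants.

    Returns the top ``ceil(fraction * n_vars)``; ties broken
    lexicographically.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    means = (
        baseline_hubness.groupby("variable")["hubness"].mean()
        .sort_index()
        .sort_values(ascending=False, kind="stable")
    )
    k = int(np.ceil(fraction * len(means)))
    return list(means.index[:k])


def global_metrics_table(
    networks: Sequence[IndividualNetwork], n_random: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Global metrics for every network; the smallworldness seed is derived
    per network from (seed, participant, timepoint) so results do not
    depend on list order."""
    rows = []
    for net in networks:
        sub = int(np.random.SeedSequence([seed, _stable_key(net)]).generate_state(1)[0] & 0x7FFFFFFF)
        gm = global_metrics(net, n_random=n_random, seed=sub)
        rows.append({"participant": net.participant_id, "timepoint": net.timepoint,
                     **gm.as_dict()})
    return pd.DataFrame(rows)


def _stable_key(net: IndividualNetwork) -> int:
    """Deterministic integer from participant id and timepoint."""
    text = f"{net.participant_id}|{net.timepoint}"
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h
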
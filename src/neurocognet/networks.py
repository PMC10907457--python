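"""Individual neurocognitive network construction.

One weighted, undirected, connected graph per participant per timepoint.
Nodes are neurocognitive variables; the edge weight between two variables
is the inverse of the absolute difference of the participant's normalized
scores, ``w = 1 / (1 + |z_i - z_j|)`` — 1 when the two functions are at
exactly the same relative level, decaying toward 0 as they diverge.

Three corrections shape the raw connectivity matrix into the network:

1. *Skeleton*: only variable pairs that covary at the population level
   (significant positive baseline Pearson correlation) are admissible,
   removing chance connectivity.
2. *Proportional thresholding*: only the strongest ``density`` fraction
   of admissible edges is retained, equalizing edge counts across
   individuals.
3. *MST closure*: the maximum-weight spanning tree of the full
   connectivity matrix is unioned in, guaranteeing a connected graph.

Normalization constants are frozen at baseline so day-91 networks are
sensitive to change rather than re-standardized away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class Skeleton:
    """Population-level admissibility mask over variable pairs."""

    variables: list[str]
    admissible: np.ndarray  # symmetric bool, zero diagonal
    population_r: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        a = self.admissible
        if a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
            raise ValueError("admissibility matrix must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are never admissible")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.population_r, index=self.variables, columns=self.variables)


@dataclass
class IndividualNetwork:
    """Connected weighted graph over one participant's scores at one timepoint."""

    participant_id: str
    timepoint: str
    nodes: list[str]
    weights: np.ndarray  # symmetric, zero diagonal; 0 where no edge
    edge_origin: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.edge_origin)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), origin in sorted(self.edge_origin.items()):
            w = float(self.weights[i, j])
            g.add_edge(self.nodes[i], self.nodes[j], weight=w,
                       distance=max(1.0 - w, 0.0), origin=origin)
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"participant": self.participant_id, "timepoint": self.timepoint,
             "node_a": self.nodes[i], "node_b": self.nodes[j],
             "weight": float(self.weights[i, j]), "edge_origin": o}
            for (i, j), o in sorted(self.edge_origin.items())
        ]
        return pd.DataFrame(rows)


def pairwise_connectivity(z_i, z_j):
    """``w = 1 / (1 + |z_i - z_j|)``: bounded in (0, 1], 1 iff equal."""
    return 1.0 / (1.0 + np.abs(np.asarray(z_i) - np.asarray(z_j)))


def build_skeleton(
    baseline_z: pd.DataFrame,
    alpha: float = 0.05,
    positive_only: bool = True,
    min_pairs: int = 4,
) -> Skeleton:
    """Admissible edges = baseline Pearson correlations significant at
    ``alpha`` (two-sided, unadjusted), positive by default; pairwise
    complete observations."""
    if len(baseline_z) < 10:
        raise ValueError("need at least 10 participants to estimate the skeleton")
    cols = list(baseline_z.columns)
    p = len(cols)
    r_mat = np.zeros((p, p))
    p_mat = np.ones((p, p))
    adm = np.zeros((p, p), dtype=bool)
    vals = baseline_z.to_numpy(dtype=float)
    for i in range(p):
        for j in range(i + 1, p):
            pair = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            if pair.sum() < min_pairs:
                warnings.warn(f"fewer than {min_pairs} complete pairs for "
                              f"({cols[i]}, {cols[j]}); edge inadmissible")
                continue
            r, pv = stats.pearsonr(vals[pair, i], vals[pair, j])
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = pv
            ok = pv < alpha and (r > 0 if positive_only else r != 0)
            adm[i, j] = adm[j, i] = ok
    return Skeleton(cols, adm, r_mat, p_mat)


def threshold_network(weights: np.ndarray, admissible: np.ndarray, density: float) -> set[tuple[int, int]]:
    """Top ``density`` proportion of admissible edges by weight.

    Retains ``ceil(density * n_admissible)`` edges; ties broken by
    lexicographic node-pair order (earlier pair wins).
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    cand = [
        (i, j) for i in range(weights.shape[0]) for j in range(i + 1, weights.shape[0])
        if admissible[i, j] and weights[i, j] > 0
    ]
    if not cand:
        return set()
    k = min(len(cand), ceil(density * len(cand)))
    cand.sort(key=lambda e: (-weights[e[0], e[1]], e[0], e[1]))
    return set(cand[:k])


def maximum_spanning_tree(weights: np.ndarray) -> set[tuple[int, int]]:
    """Kruskal on distance 1 − w with deterministic lexicographic tie-break."""
    n = weights.shape[0]
    edges = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0),
        key=lambda e: (1.0 - weights[e[0], e[1]], e[0], e[1]),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: set[tuple[int, int]] = set()
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.add((i, j))
            if len(tree) == n - 1:
                break
    return tree


def close_with_mst(
    sparse_edges: set[tuple[int, int]], full_weights: np.ndarray
) -> tuple[set[tuple[int, int]], dict[tuple[int, int], str]]:
    """Union the thresholded edges with the maximum-weight spanning tree of
    the full connectivity matrix; closure edges are flagged."""
    tree = maximum_spanning_tree(full_weights)
    origin = {e: "thresholded" for e in sparse_edges}
    for e in tree - sparse_edges:
        origin[e] = "mst_closure"
    return sparse_edges | tree, origin


class NetworkBuilder(BaseEstimator):
    """Fit on baseline scores (normalization constants + skeleton), then
    transform any timepoint's scores into individual networks.

    Parameters
    ----------
    alpha : skeleton significance level (two-sided, unadjusted).
    density : proportion of admissible edges retained by thresholding.
    positive_only : restrict the skeleton to positive correlations.
    max_missing_frac : participants missing more than this fraction of
        variables are dropped with a warning.
    min_nodes : participants with fewer usable nodes are skipped.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        density: float = 0.20,
        positive_only: bool = True,
        max_missing_frac: float = 0.20,
        min_nodes: int = 3,
    ):
        self.alpha = alpha
        self.density = density
        self.positive_only = positive_only
        self.max_missing_frac = max_missing_frac
        self.min_nodes = min_nodes

    def fit(self, baseline_scores: pd.DataFrame, y=None) -> "NetworkBuilder":
        """``baseline_scores``: oriented scores (incl. contrasts), id-indexed."""
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        X = pd.DataFrame(baseline_scores)
        sd = X.std(axis=0, ddof=1)
        dead = list(X.columns[(sd == 0) | sd.isna()])
        if dead:
            warnings.warn(f"excluding zero-variance variables: {dead}")
            X = X.drop(columns=dead)
        self.variables_ = list(X.columns)
        self.mean_ = X.mean(axis=0).to_numpy()
        self.scale_ = X.std(axis=0, ddof=1).to_numpy()
        self.skeleton_ = build_skeleton(
            self.normalize(X), alpha=self.alpha, positive_only=self.positive_only
        )
        return self

    def normalize(self, scores: pd.DataFrame) -> pd.DataFrame:
        """z-standardize with the frozen pooled-baseline constants."""
        check = getattr(self, "mean_", None)
        if check is None:
            raise ValueError("fit before normalizing")
        X = pd.DataFrame(scores)[self.variables_]
        return (X - self.mean_) / self.scale_

    def build_one(self, pid: str, timepoint: str, z_row: pd.Series) -> Optional[IndividualNetwork]:
        present = [v for v in self.variables_ if pd.notna(z_row.get(v))]
        n_total = len(self.variables_)
        if len(present) < max(self.min_nodes, 3):
            warnings.warn(f"{pid}/{timepoint}: fewer than {self.min_nodes} usable nodes; skipped")
            return None
        if (n_total - len(present)) / n_total > self.max_missing_frac:
            warnings.warn(f"{pid}/{timepoint}: too many missing variables; dropped")
            return None
        idx = [self.variables_.index(v) for v in present]
        z = z_row[present].to_numpy(dtype=float)
        diff = np.abs(z[:, None] - z[None, :])
        W = 1.0 / (1.0 + diff)
        np.fill_diagonal(W, 0.0)
        adm = self.skeleton_.admissible[np.ix_(idx, idx)]
        sparse = threshold_network(W, adm, self.density)
        edges, origin = close_with_mst(sparse, W)
        weights = np.zeros_like(W)
        for i, j in edges:
            weights[i, j] = weights[j, i] = W[i, j]
        return IndividualNetwork(pid, timepoint, present, weights, origin)

    def transform(self, scores: pd.DataFrame, timepoint: str = "baseline") -> list[IndividualNetwork]:
        z = self.normalize(scores)
        nets = []
        for pid in z.index:
            net = self.build_one(str(pid), timepoint, z.loc[pid])
            if net is not None:
                nets.append(net)
        return nets

    def build_networks(self, data) -> list[IndividualNetwork]:
        """One network per (participant, timepoint) of a :class:`TrialDataset`."""
        nets = []
        for t in ("baseline", "d91"):
            nets.extend(self.transform(data.timepoint(t), timepoint=t))
        return nets
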
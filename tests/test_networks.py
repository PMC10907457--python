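import warnings

import numpy as np
import pandas as pd
import pytest

import oracles
from neurocognet.networks import (NetworkBuilder, build_skeleton, close_with_mst,
                                  maximum_spanning_tree, pairwise_connectivity,
                                  threshold_network)


# ---------------------------------------------------------------------------
# connectivity functional form
# ---------------------------------------------------------------------------

def test_connectivity_maximal_when_scores_equal():
    assert pairwise_connectivity(1.3, 1.3) == 1.0


def test_connectivity_half_at_unit_difference():
    assert pairwise_connectivity(0.0, 1.0) == pytest.approx(0.5)


def test_connectivity_symmetric_and_monotone():
    rng = np.random.default_rng(0)
    a, b = rng.standard_normal(100), rng.standard_normal(100)
    assert np.allclose(pairwise_connectivity(a, b), pairwise_connectivity(b, a))
    # smaller |difference| never decreases the weight
    d = np.abs(a - b)
    w = pairwise_connectivity(a, b)
    order = np.argsort(d)
    assert np.all(np.diff(w[order]) <= 1e-12)
    assert np.all((w > 0) & (w <= 1))


# ---------------------------------------------------------------------------
# population normalization
# ---------------------------------------------------------------------------

def test_normalization_baseline_mean_zero_sd_one(full):
    nb = NetworkBuilder().fit(full.timepoint("baseline"))
    z = nb.normalize(full.timepoint("baseline"))
    assert np.allclose(z.mean(axis=0, skipna=True), 0.0, atol=1e-10)
    assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_normalization_location_invariance(full):
    base = full.timepoint("baseline")
    nb1 = NetworkBuilder().fit(base)
    shifted = base.copy()
    shifted["bs_rt"] = shifted["bs_rt"] + 1000.0
    nb2 = NetworkBuilder().fit(shifted)
    z1 = nb1.normalize(base)["bs_rt"]
    z2 = nb2.normalize(shifted)["bs_rt"]
    assert np.allclose(z1, z2, equal_nan=True)


def test_frozen_constants_expose_d91_shift(full):
    base = full.timepoint("baseline")
    nb = NetworkBuilder().fit(base)
    shifted = base + nb.scale_  # +1 baseline SD on every variable
    z = nb.normalize(shifted)
    assert np.allclose(z.mean(axis=0), nb.normalize(base).mean(axis=0) + 1.0, atol=1e-10)


def test_zero_variance_variable_excluded(full):
    base = full.timepoint("baseline").copy()
    base["flat"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        nb = NetworkBuilder().fit(base)
    assert "flat" not in nb.variables_


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

def test_skeleton_correlated_pair_admissible():
    rng = np.random.default_rng(1)
    shared = rng.standard_normal(83)
    z = pd.DataFrame({
        "a": shared + 0.7 * rng.standard_normal(83),
        "b": shared + 0.7 * rng.standard_normal(83),
        "c": rng.standard_normal(83),
    })
    sk = build_skeleton(z, alpha=0.05)
    assert sk.admissible[0, 1]
    assert not sk.admissible.diagonal().any()


def test_skeleton_false_positive_rate_near_half_alpha():
    """Independent variables pass the positive-significant rule with
    probability ~alpha/2 (one tail of a two-sided test)."""
    rng = np.random.default_rng(2)
    hits = trials = 0
    for _ in range(40):
        z = pd.DataFrame(rng.standard_normal((83, 8)))
        sk = build_skeleton(z, alpha=0.05)
        iu = np.triu_indices(8, 1)
        hits += sk.admissible[iu].sum()
        trials += len(iu[0])
    rate = hits / trials
    assert 0.005 < rate < 0.06  # wide band around 0.025


def test_skeleton_needs_ten_participants():
    z = pd.DataFrame(np.random.default_rng(3).standard_normal((9, 4)))
    with pytest.raises(ValueError, match="10 participants"):
        build_skeleton(z)


def test_skeleton_sparse_pair_warns_and_inadmissible():
    rng = np.random.default_rng(4)
    z = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
    z.loc[z.index[:18], "c"] = np.nan  # only 2 complete pairs with c
    with pytest.warns(UserWarning, match="complete pairs"):
        sk = build_skeleton(z)
    assert not sk.admissible[0, 2] and not sk.admissible[1, 2]


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def _toy_weights(n=5, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.random((n, n))
    W = np.triu(W, 1)
    W = W + W.T
    np.fill_diagonal(W, 0.0)
    return W


def test_threshold_density_one_keeps_all():
    W = _toy_weights()
    adm = np.ones_like(W, dtype=bool)
    np.fill_diagonal(adm, False)
    kept = threshold_network(W, adm, 1.0)
    assert len(kept) == 10


def test_threshold_exact_count():
    W = _toy_weights()
    adm = np.ones_like(W, dtype=bool)
    np.fill_diagonal(adm, False)
    kept = threshold_network(W, adm, 0.2)
    assert len(kept) == 2


def test_threshold_keeps_heaviest_edges():
    W = _toy_weights(seed=7)
    adm = np.ones_like(W, dtype=bool)
    np.fill_diagonal(adm, False)
    kept = threshold_network(W, adm, 0.3)
    removed = {(i, j) for i in range(5) for j in range(i + 1, 5)} - kept
    assert min(W[e] for e in kept) >= max(W[e] for e in removed)


def test_threshold_density_validation():
    W = _toy_weights()
    with pytest.raises(ValueError, match="density"):
        threshold_network(W, np.ones_like(W, dtype=bool), 0.0)


# ---------------------------------------------------------------------------
# MST closure
# ---------------------------------------------------------------------------

def test_mst_matches_exhaustive_enumeration():
    """Kruskal's maximum spanning tree attains the maximum total weight
    over all 125 spanning trees of K5 (Prüfer enumeration)."""
    for seed in range(5):
        W = _toy_weights(seed=seed)
        tree = maximum_spanning_tree(W)
        best_w, best_trees = oracles.all_spanning_trees_max_weight(W)
        assert sum(W[e] for e in tree) == pytest.approx(best_w, rel=1e-12)
        assert tree in best_trees


def test_closure_of_empty_threshold_is_a_tree():
    W = _toy_weights(seed=3)
    edges, origin = close_with_mst(set(), W)
    assert len(edges) == 4
    assert all(o == "mst_closure" for o in origin.values())


def test_closure_noop_when_tree_inside_threshold():
    W = _toy_weights(seed=3)
    tree = maximum_spanning_tree(W)
    dense = tree | {(0, 1), (2, 3), (1, 4)}
    edges, origin = close_with_mst(dense, W)
    assert edges == dense
    assert all(origin[e] == "thresholded" for e in dense)


# ---------------------------------------------------------------------------
# full individual-network construction
# ---------------------------------------------------------------------------

@pytest.fixture()
def fitted_builder(full):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return NetworkBuilder().fit(full.timepoint("baseline"))


def test_one_network_per_participant_timepoint(full, fitted_builder):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets = fitted_builder.build_networks(full)
    # MCAR missingness may drop a handful below the node threshold
    assert len(nets) >= 160
    assert len(nets) == len({(n.participant_id, n.timepoint) for n in nets})


def test_networks_connected_and_bounded(full, fitted_builder):
    import networkx as nx
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets = fitted_builder.build_networks(full)
    for net in nets[:40]:
        g = net.to_graph()
        assert nx.is_connected(g)
        tri = net.weights[np.triu_indices(net.n_nodes, 1)]
        present = tri[tri > 0]
        assert np.all((present > 0) & (present <= 1))
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)


def test_identical_profiles_give_identical_networks(fitted_builder):
    z = pd.Series(np.linspace(-1, 1, len(fitted_builder.variables_)),
                  index=fitted_builder.variables_)
    a = fitted_builder.build_one("a", "baseline", z)
    b = fitted_builder.build_one("b", "baseline", z)
    assert np.array_equal(a.weights, b.weights)
    assert a.edge_origin == b.edge_origin


def test_variable_order_permutation_gives_isomorphic_networks(full, spec):
    base = full.timepoint("baseline")
    nb1 = NetworkBuilder().fit(base)
    perm_cols = list(reversed(base.columns))
    nb2 = NetworkBuilder().fit(base[perm_cols])
    z = base.iloc[0]
    n1 = nb1.build_one("p", "baseline", z)
    n2 = nb2.build_one("p", "baseline", z[perm_cols])
    e1 = {frozenset((n1.nodes[i], n1.nodes[j])): round(n1.weights[i, j], 10)
          for i, j in n1.edge_origin}
    e2 = {frozenset((n2.nodes[i], n2.nodes[j])): round(n2.weights[i, j], 10)
          for i, j in n2.edge_origin}
    assert e1 == e2


def test_too_few_nodes_skipped(fitted_builder):
    z = pd.Series(np.nan, index=fitted_builder.variables_)
    z.iloc[:2] = 0.0
    with pytest.warns(UserWarning):
        out = fitted_builder.build_one("p", "baseline", z)
    assert out is None
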
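import numpy as np
import pandas as pd
import pytest

from neurocognet.domains import (DomainExtractor, elbow_point, label_components,
                                 select_n_components, varimax, varimax_criterion)
from neurocognet.simulate import DEFAULT_DOMAINS, SimConfig, generate_trial
from neurocognet.battery import orient_scores


def tucker(a, b):
    return abs(a @ b) / np.sqrt((a @ a) * (b @ b))


# ---------------------------------------------------------------------------
# component-count selection
# ---------------------------------------------------------------------------

def test_select_components_equal_spectrum():
    """Ten equal eigenvalues, 70% target -> 7 components."""
    assert select_n_components(np.ones(10), 0.70) == 7


def test_select_components_single_variable():
    assert select_n_components(np.array([1.0]), 0.70) == 1


def test_select_components_validation():
    with pytest.raises(ValueError, match="empty"):
        select_n_components(np.array([]))
    with pytest.raises(ValueError, match="descending"):
        select_n_components(np.array([1.0, 2.0]))


def test_elbow_at_largest_second_difference():
    # curvature e[i-1] - 2 e[i] + e[i+1] peaks at the 3rd eigenvalue,
    # where the scree turns from the steep drop into the flat tail
    eig = np.array([5.0, 4.5, 1.0, 0.9, 0.8])
    assert elbow_point(eig) == 3


# ---------------------------------------------------------------------------
# varimax rotation
# ---------------------------------------------------------------------------

def test_varimax_improves_simple_structure():
    rng = np.random.default_rng(0)
    blocks = np.kron(np.eye(3), np.ones((4, 1))) * 0.8
    # mix the columns with a random rotation, then ask varimax to undo it
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    mixed = blocks @ q
    rotated, R = varimax(mixed)
    assert varimax_criterion(rotated) >= varimax_criterion(mixed) - 1e-12
    # the rotation is orthogonal
    assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
    for j in range(3):
        assert max(tucker(rotated[:, c], blocks[:, j]) for c in range(3)) > 0.99


def test_varimax_preserves_subspace():
    rng = np.random.default_rng(1)
    L = rng.standard_normal((8, 3))
    rotated, _ = varimax(L)
    P0 = L @ np.linalg.pinv(L)
    P1 = rotated @ np.linalg.pinv(rotated)
    assert np.allclose(P0, P1, atol=1e-6)


# ---------------------------------------------------------------------------
# fitted extractor
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def block_fit(spec):
    """Extractor fitted on clean 8-block data (high loadings, no missing)."""
    raw = spec.raw_names
    L = np.zeros((len(raw), 8))
    for j, dom in enumerate(DEFAULT_DOMAINS):
        for v in DEFAULT_DOMAINS[dom]:
            L[raw.index(v), j] = 0.95
    cfg = SimConfig(seed=21, n_placebo=150, n_active=150,
                    loading_matrix=L, missing_rate=0.0)
    data, truth = generate_trial(cfg, spec)
    o = orient_scores(data, spec)
    ext = DomainExtractor(n_components=8).fit(o.timepoint("baseline")[raw])
    return ext, L, truth, o


def test_block_structure_recovered(block_fit):
    ext, L, _, _ = block_fit
    rot = ext.loadings_.to_numpy()
    for j in range(8):
        assert max(tucker(rot[:, c], L[:, j]) for c in range(8)) > 0.95


def test_rotated_axes_are_orthonormal(block_fit):
    ext, _, _, _ = block_fit
    C = ext.components_.to_numpy()
    assert np.allclose(C.T @ C, np.eye(C.shape[1]), atol=1e-8)


def test_rotation_preserves_projection_subspace(block_fit):
    ext, _, _, _ = block_fit
    C = ext.components_.to_numpy()
    L = ext.loadings_.to_numpy()
    P_axes = C @ C.T
    P_load = L @ np.linalg.pinv(L)
    assert np.allclose(P_axes, P_load, atol=1e-6)


def test_baseline_scores_standardized(block_fit):
    ext, _, _, o = block_fit
    scores = ext.transform(o.timepoint("baseline")[ext.feature_names_in_])
    assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-8)
    assert np.allclose(scores.std(axis=0, ddof=1), 1.0, atol=1e-6)


def test_participant_at_sample_mean_scores_zero(block_fit):
    ext, _, _, o = block_fit
    base = o.timepoint("baseline")[ext.feature_names_in_]
    mean_row = pd.DataFrame([base.mean(axis=0)], index=["avg"])
    scores = ext.transform(mean_row)
    assert np.allclose(scores.to_numpy()[0], 0.0, atol=1e-8)


def test_missing_variable_renormalized_not_nan(block_fit):
    ext, _, _, o = block_fit
    base = o.timepoint("baseline")[ext.feature_names_in_]
    row = base.iloc[[0]].copy()
    row.iloc[0, 0] = np.nan
    scores = ext.transform(row)
    assert np.isfinite(scores.to_numpy()).all()


def test_identity_correlation_gives_unit_vector_loadings():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((4000, 5)), columns=list("abcde"))
    ext = DomainExtractor(n_components=5).fit(X)
    L = ext.loadings_.to_numpy()
    # each rotated component concentrated on one variable
    for j in range(5):
        col = np.abs(L[:, j])
        assert col.max() > 0.95
        assert np.sort(col)[-2] < 0.2


def test_duplicate_variables_load_together():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(500)
    X = pd.DataFrame({"x1": x, "x2": x, "y": rng.standard_normal(500)})
    ext = DomainExtractor(n_components=2).fit(X)
    eta = ext.loadings_ ** 2
    lead = eta.idxmax(axis=1)
    assert lead["x1"] == lead["x2"]


def test_more_components_than_variables_rejected():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.standard_normal((50, 3)))
    with pytest.raises(ValueError, match="components"):
        DomainExtractor(n_components=4).fit(X)


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def test_label_boundary_at_largest_eta_squared_drop():
    load = pd.DataFrame(
        {"C1": [np.sqrt(v) for v in (0.81, 0.77, 0.12, 0.08)]},
        index=["a", "b", "c", "d"],
    )
    labels = label_components(load)
    assert labels[0]["members"] == ["a", "b"]


def test_label_single_variable_component():
    load = pd.DataFrame({"C1": [0.9]}, index=["solo"])
    assert label_components(load)[0]["members"] == ["solo"]


def test_label_tie_break_prefers_earlier_boundary():
    # eta-squared 49, 25, 1: exactly equal drops of 24 -> cut after the 1st
    load = pd.DataFrame({"C1": [7.0, 5.0, 1.0]}, index=list("abc"))
    assert label_components(load)[0]["members"] == ["a"]


def test_label_zero_component_flagged_unassigned():
    load = pd.DataFrame({"C1": [0.0, 0.0]}, index=["a", "b"])
    with pytest.warns(UserWarning, match="unassigned"):
        labels = label_components(load)
    assert labels[0]["name"] == "unassigned"


# ---------------------------------------------------------------------------
# scoring change through frozen baseline weights
# ---------------------------------------------------------------------------

def test_injected_latent_shift_attenuated_by_loading(spec):
    """A +0.5 latent shift appears in the domain score as
    0.5 * (w . lambda_block) / sd_base(raw score) — the closed-form
    attenuation through the fitted weights."""
    cfg = SimConfig(seed=31, n_placebo=400, n_active=400, missing_rate=0.0,
                    effect_mean={"verbal_memory": 0.5})
    data, truth = generate_trial(cfg, spec)
    o = orient_scores(data, spec)
    raw = spec.raw_names
    ext = DomainExtractor(n_components=8).fit(o.timepoint("baseline")[raw])
    # find the rotated component carrying the verbal-memory block
    j = int(np.argmax([
        abs(ext.loadings_.loc["ravlt_recall", c]) for c in ext.loadings_.columns
    ]))
    comp = ext.loadings_.columns[j]
    w = ext.loadings_[comp].to_numpy()
    lam = truth.loading_matrix[:, truth.domain_names.index("verbal_memory")]
    expected = 0.5 * float(w @ lam) / ext.score_scale_[j]

    arm = data.demographics["arm"]
    scores_b = ext.transform(o.timepoint("baseline")[raw])[comp]
    scores_d = ext.transform(o.timepoint("d91")[raw])[comp]
    change = scores_d - scores_b
    observed = change[arm == "active"].mean() - change[arm == "placebo"].mean()
    se = 2 * np.sqrt(2.0 / 400)
    assert observed == pytest.approx(expected, abs=3 * se)
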
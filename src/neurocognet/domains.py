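"""Data-driven neurocognitive domain extraction: PCA with varimax rotation.

Variables are standardized (correlation-matrix PCA — the battery mixes
milliseconds, error counts and span lengths), the number of components is
chosen as the smallest k whose cumulative explained variance reaches a
target (default 70%), the retained loadings are varimax-rotated for
simple structure, and each rotated component is labelled by the set of
variables contributing most to it, measured by η² (squared structure
loading = the share of that variable's variance the component carries)
with the member boundary at the largest consecutive drop in η².

The model is fitted on baseline data only; later timepoints are scored
through the frozen baseline standardization constants and loadings so a
change in a domain score is interpretable as change, not re-weighting.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def select_n_components(eigenvalues: np.ndarray, target: float = 0.70) -> int:
    """Smallest k with cumulative explained variance >= ``target``."""
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if np.any(np.diff(eig) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    cum = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def elbow_point(eigenvalues: np.ndarray) -> int:
    """Scree elbow: index (1-based) of the maximum second difference."""
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 3:
        return 1
    second = eig[:-2] - 2 * eig[1:-1] + eig[2:]
    return int(np.argmax(second) + 2)  # elbow at the middle point


def varimax(
    loadings: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm, optional Kaiser row
    normalization); deterministic start from the unrotated solution.

    Returns (rotated loadings, rotation matrix R) with ``rotated = L @ R``.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1)) if kaiser else np.ones(p)
    h[h == 0] = 1.0
    Ln = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = Ln @ R
        u, s, vt = np.linalg.svd(
            Ln.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d_old * (1 + tol):
            break
        d_old = d_new
    return (Ln @ R) * h[:, None], R


def varimax_criterion(loadings: np.ndarray) -> float:
    """The variance-of-squared-loadings objective that varimax maximizes."""
    L2 = np.asarray(loadings) ** 2
    return float((L2.var(axis=0)).sum())


def label_components(
    loadings: pd.DataFrame, overrides: Optional[dict[int, str]] = None
) -> list[dict]:
    """Name each component from its strongest contributors.

    For each component, variables are ranked by η² (squared structure
    loading); the member set is cut at the largest drop between two
    consecutive η² values (ties resolved toward the earlier, larger-η²
    boundary).  The label joins the member variables' names unless
    overridden.
    """
    labels = []
    for j, comp in enumerate(loadings.columns):
        eta2 = (loadings[comp] ** 2).sort_values(ascending=False, kind="stable")
        if float(eta2.iloc[0]) == 0.0:
            warnings.warn(f"component {comp} has all-zero loadings; labelled unassigned")
            labels.append({"component": comp, "name": "unassigned", "members": []})
            continue
        vals = eta2.to_numpy()
        if len(vals) == 1:
            cut = 1
        else:
            drops = vals[:-1] - vals[1:]
            cut = int(np.argmax(drops) + 1)  # argmax returns first (earlier) max
        members = list(eta2.index[:cut])
        name = (overrides or {}).get(j) or "+".join(members)
        labels.append({"component": comp, "name": name, "members": members})
    return labels


class DomainExtractor(BaseEstimator, TransformerMixin):
    """Correlation-PCA + varimax transformer over oriented battery scores.

    Parameters
    ----------
    n_components : int or None
        Fixed component count; ``None`` selects the smallest count whose
        cumulative explained variance reaches ``variance_target``.
    variance_target : float
        Cumulative-variance threshold used when ``n_components`` is None.
    kaiser, tol, max_iter : varimax settings.

    Fitted attributes (suffix ``_``): ``loadings_`` (structure loadings,
    variables × components), ``components_`` (rotated orthonormal axes),
    ``eigenvalues_``, ``variance_explained_``, ``cumulative_variance_``,
    ``n_components_``, ``elbow_``, ``labels_``, ``mean_``/``scale_``
    (baseline variable standardization) and ``score_mean_``/``score_scale_``
    (baseline domain-score standardization).
    """

    def __init__(
        self,
        n_components: Optional[int] = None,
        variance_target: float = 0.70,
        kaiser: bool = True,
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.n_components = n_components
        self.variance_target = variance_target
        self.kaiser = kaiser
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None) -> "DomainExtractor":
        X = pd.DataFrame(X)
        complete = X.dropna()
        if len(complete) < 3:
            raise ValueError("need at least 3 complete-case rows to fit")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        vals = complete.to_numpy(dtype=float)
        self.mean_ = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        if np.any(sd == 0):
            dead = list(X.columns[sd == 0])
            raise ValueError(f"zero-variance variables cannot be standardized: {dead}")
        self.scale_ = sd
        Z = (vals - self.mean_) / self.scale_
        p = Z.shape[1]

        corr = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
        self.eigenvalues_ = eigval
        self.elbow_ = elbow_point(eigval)

        k = self.n_components or select_n_components(eigval, self.variance_target)
        if k > p:
            raise ValueError(f"more components ({k}) than variables ({p})")
        self.n_components_ = k

        unrotated = eigvec[:, :k] * np.sqrt(eigval[:k])
        rotated, R = varimax(unrotated, kaiser=self.kaiser, tol=self.tol, max_iter=self.max_iter)
        axes = eigvec[:, :k] @ R  # rotated orthonormal basis

        # deterministic sign: dominant loading positive
        for j in range(k):
            if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
                rotated[:, j] *= -1
                axes[:, j] *= -1
        # order components by explained variance after rotation
        ssl = (rotated**2).sum(axis=0)
        order = np.argsort(-ssl, kind="stable")
        rotated, axes, ssl = rotated[:, order], axes[:, order], ssl[order]

        comp_names = [f"C{j + 1}" for j in range(k)]
        self.loadings_ = pd.DataFrame(rotated, index=X.columns, columns=comp_names)
        self.components_ = pd.DataFrame(axes, index=X.columns, columns=comp_names)
        self.variance_explained_ = pd.Series(ssl / p, index=comp_names)
        self.cumulative_variance_ = self.variance_explained_.cumsum()
        self.labels_ = label_components(self.loadings_)

        raw_scores = self._raw_scores(complete)
        self.score_mean_ = raw_scores.mean(axis=0).to_numpy()
        ssd = raw_scores.std(axis=0, ddof=1).to_numpy()
        ssd[ssd == 0] = 1.0
        self.score_scale_ = ssd
        return self

    def _raw_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        """Unstandardized component scores; missing variables contribute
        nothing and the remaining weights are renormalized by total
        absolute weight."""
        Z = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        W = self.loadings_.to_numpy()
        present = ~np.isnan(Z)
        Zf = np.where(present, Z, 0.0)
        raw = Zf @ W
        total = np.abs(W).sum(axis=0)
        avail = present.astype(float) @ np.abs(W)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = raw * (total / avail)
        raw[avail == 0] = np.nan
        return pd.DataFrame(raw, index=X.index, columns=self.loadings_.columns)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Standardized domain scores (baseline constants), any timepoint."""
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        raw = self._raw_scores(X)
        return (raw - self.score_mean_) / self.score_scale_

    def score_frame(self, data) -> pd.DataFrame:
        """Tidy domain scores for both timepoints of a :class:`TrialDataset`."""
        check_is_fitted(self, "loadings_")
        parts = []
        for t in ("baseline", "d91"):
            scores = self.transform(data.timepoint(t))
            scores.insert(0, "timepoint", t)
            parts.append(scores.reset_index())
        return pd.concat(parts, ignore_index=True)
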
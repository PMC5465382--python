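"""Dense and sparse principal component analysis of centered item matrices.

Model
-----
Given a centered data matrix X (N samples x M items), a principal component
is a unit-norm loading vector w maximizing the explained variance w'Sw,
where S is the sample covariance of X.  Dense PCA takes the leading
eigenvectors of S; every item then receives a nonzero loading, which makes
the components hard to interpret as symptom clusters.  Sparse PCA (SPCA)
trades variance for interpretability by restricting each component to a
small item subset: :class:`SparsePCA` maximizes w'Sw over unit vectors
supported on at most ``k`` items (the *cardinality*).

The solver is a truncated power iteration with hard thresholding: iterate
``w <- normalize(top_k(S w))`` from multiple deterministic and random
starts (thresholded leading eigenvector, every coordinate axis, random unit
vectors), then refine the winning support by taking the exact leading
eigenvector of the principal submatrix ``S[support, support]``.  Because the
final loading is the exact optimum *for its support*, the achieved variance
equals the leading eigenvalue of that submatrix; for the small item counts
of mood questionnaires (M <= 21) the multistart scheme recovers the global
k-sparse optimum, which tests verify against exhaustive subset enumeration.
An L1-penalized variant (soft thresholding, with the penalty bisected to
hit a target cardinality) is available via ``solver="l1"``.

Successive components are obtained by projection deflation of the data
matrix, ``X <- X (I - w w')``, which zeroes the variance along ``w`` while
keeping component scores computable against the original X.  Because sparse
components are generally correlated, cumulative explained variance is
computed by successive orthogonalization of the score vectors (QR), so
shared variance is not double-counted; for dense PCA loadings this reduces
exactly to the usual eigenvalue ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.linalg import eigh, qr
from sklearn.base import BaseEstimator, TransformerMixin

from .dataio import CenteredMatrix
from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "ComponentSet",
    "DensePCA",
    "SparsePCA",
    "covariance",
    "pca",
    "sparse_component",
    "deflate",
    "spca_fit",
    "adjusted_variance",
    "cardinality_path",
]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _as_array(X) -> np.ndarray:
    if isinstance(X, CenteredMatrix):
        return np.asarray(X.X, dtype=float)
    return np.asarray(X, dtype=float)


def _item_names(X, M: int) -> tuple[str, ...]:
    if isinstance(X, CenteredMatrix):
        return tuple(X.item_names)
    return tuple(f"x{j + 1}" for j in range(M))


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry is
    positive (ties broken by lowest index via argmax)."""
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        return -w
    return w


def _check_covariance(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("covariance matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValidationError("covariance matrix must be symmetric")
    return 0.5 * (S + S.T)


def covariance(X) -> np.ndarray:
    """Unbiased sample covariance (divisor N-1) of the matrix columns.

    Raises :class:`InsufficientDataError` for N < 2.
    """
    A = _as_array(X)
    if A.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    if A.shape[0] < 2:
        raise InsufficientDataError(
            f"covariance requires N >= 2 samples, got {A.shape[0]}"
        )
    mean = A.mean(axis=0)
    D = A - mean
    S = D.T @ D / (A.shape[0] - 1)
    return 0.5 * (S + S.T)


def deflate(X, w: np.ndarray):
    """Projection deflation: remove the variance along loading ``w``.

    Returns ``X (I - w w')``; the deflated matrix has zero variance along
    ``w``.  Accepts and returns plain arrays (a :class:`CenteredMatrix`
    input yields a deflated copy of its array).
    """
    A = _as_array(X)
    w = np.asarray(w, dtype=float)
    if w.shape != (A.shape[1],):
        raise ValidationError(
            f"loading length {w.shape} does not match {A.shape[1]} items"
        )
    if abs(np.linalg.norm(w) - 1.0) > 1e-8:
        raise ValidationError("loading vector must have unit norm")
    return A - np.outer(A @ w, w)


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """Ordered loading vectors with scores and variance accounting.

    Attributes
    ----------
    loadings : (K, M) array
        Unit-norm loading vectors, one row per component.
    supports : tuple of tuple of int
        Per-component index sets of items allowed a nonzero weight.  For
        sparse fits each support has exactly the configured cardinality
        (items whose optimal weight is zero still count toward it); for
        dense fits the support is all items.
    scores : (N, K) array or None
        Component scores against the original (undeflated) matrix.
    cum_variance_pct : (K,) array
        Cumulative % of total variance explained (adjusted for component
        correlation in the sparse case); nondecreasing, <= 100.
    explained_variance : (K,) array
        Achieved variance w'Sw of each component at its deflation stage.
    method : "dense" or "sparse"
    item_names : tuple of str
    """

    loadings: np.ndarray
    supports: tuple[tuple[int, ...], ...]
    scores: np.ndarray | None
    cum_variance_pct: np.ndarray
    explained_variance: np.ndarray
    method: str
    item_names: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def support_items(self, i: int) -> tuple[str, ...]:
        """Item names in component ``i``'s support."""
        return tuple(self.item_names[j] for j in self.supports[i])

    def loading_table(self, zero_tol: float = 0.0):
        """Loading table in the conventional layout: rows = items, columns
        = P1..PK with exact zeros for excluded items, plus a cumulative
        '% total variance explained' row."""
        import pandas as pd

        cols = {f"P{i + 1}": self.loadings[i] for i in range(self.n_components)}
        table = pd.DataFrame(cols, index=list(self.item_names))
        if zero_tol > 0:
            table = table.mask(table.abs() <= zero_tol, 0.0)
        table.loc["% total variance explained"] = np.round(
            self.cum_variance_pct, 1
        )
        return table


# ---------------------------------------------------------------------------
# Sparse solver
# ---------------------------------------------------------------------------

def _top_k_support(v: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |entries|, ties broken by lowest index."""
    order = np.argsort(-np.abs(v), kind="stable")
    return np.sort(order[:k])

def _submatrix_leading(S: np.ndarray, idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Leading eigenpair of S[idx, idx], embedded into full dimension."""
    sub = S[np.ix_(idx, idx)]
    vals, vecs = eigh(sub)
    w = np.zeros(S.shape[0])
    w[idx] = vecs[:, -1]
    w = _fix_sign(w)
    return float(vals[-1]), np.where(w == 0.0, 0.0, w)  # drop negative zeros


def _truncated_power(S: np.ndarray, k: int, w0: np.ndarray,
                     max_iter: int, tol: float) -> np.ndarray:
    """Run hard-thresholded power iteration from w0; return the support."""
    w = w0 / np.linalg.norm(w0)
    var = float(w @ S @ w)
    for _ in range(max_iter):
        v = S @ w
        if np.linalg.norm(v) < 1e-15:
            break
        idx = _top_k_support(v, k)
        t = np.zeros_like(v)
        t[idx] = v[idx]
        w = t / np.linalg.norm(t)
        new_var = float(w @ S @ w)
        if abs(new_var - var) <= tol * max(abs(var), 1.0):
            var = new_var
            break
        var = new_var
    return _top_k_support(w, k)


def _soft_threshold_power(S: np.ndarray, lam: float, w0: np.ndarray,
                          max_iter: int, tol: float) -> np.ndarray:
    """L1 (soft-thresholded) power iteration; returns the final vector
    (possibly zero when the penalty kills every coordinate)."""
    w = w0 / np.linalg.norm(w0)
    var = float(w @ S @ w)
    for _ in range(max_iter):
        v = S @ w
        t = np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)
        norm = np.linalg.norm(t)
        if norm < 1e-15:
            return t
        w = t / norm
        new_var = float(w @ S @ w)
        if abs(new_var - var) <= tol * max(abs(var), 1.0):
            break
        var = new_var
    return w


def _l1_support(S: np.ndarray, k: int, w0: np.ndarray,
                max_iter: int, tol: float) -> np.ndarray:
    """Bisect the L1 penalty until the soft-thresholded iteration leaves
    exactly k (or at most k) nonzero coordinates; return that support."""
    lo, hi = 0.0, float(np.max(np.abs(S @ (w0 / np.linalg.norm(w0)))))
    best = _top_k_support(w0, k)
    for _ in range(60):
        lam = 0.5 * (lo + hi)
        w = _soft_threshold_power(S, lam, w0, max_iter, tol)
        nnz = int(np.count_nonzero(np.abs(w) > 1e-12))
        if nnz > k:
            lo = lam
        else:
            if nnz > 0:
                best = np.flatnonzero(np.abs(w) > 1e-12)
            hi = lam
        if hi - lo < 1e-12:
            break
    if len(best) < k:
        # Pad to the configured cardinality with the next-best coordinates
        # of the dense power direction.
        w = _soft_threshold_power(S, 0.0, w0, max_iter, tol)
        extra = [j for j in np.argsort(-np.abs(w), kind="stable")
                 if j not in set(best)]
        best = np.sort(np.concatenate([best, extra[: k - len(best)]]))
    return np.asarray(best[:k] if len(best) > k else best, dtype=int)


def _candidate_inits(S: np.ndarray, k: int, restarts: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    M = S.shape[0]
    inits: list[np.ndarray] = []
    vals, vecs = eigh(S)
    lead = vecs[:, -1]
    inits.append(lead.copy())
    # Hard-thresholded leading eigenvector.
    idx = _top_k_support(lead, k)
    t = np.zeros(M)
    t[idx] = lead[idx]
    if np.linalg.norm(t) > 0:
        inits.append(t)
    # Every coordinate axis: guarantees the best single item is considered.
    for j in range(M):
        e = np.zeros(M)
        e[j] = 1.0
        inits.append(e)
    for _ in range(max(0, restarts)):
        inits.append(rng.standard_normal(M))
    return inits


def sparse_component(
    S: np.ndarray,
    k: int,
    *,
    restarts: int = 8,
    max_iter: int = 1000,
    tol: float = 1e-9,
    solver: str = "truncated_power",
    random_state: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, tuple[int, ...], float]:
    """Best k-sparse leading component of a covariance matrix.

    Maximizes w'Sw over unit vectors with at most k nonzero entries.  The
    reported support always has exactly k indices (padded with zero-weight
    items when the optimal loading needs fewer), and the loading is the
    exact leading eigenvector of the support submatrix, so the achieved
    variance is the submatrix's leading eigenvalue.

    Returns ``(w, support, variance)``.
    """
    S = _check_covariance(S)
    M = S.shape[0]
    if not (1 <= k <= M):
        raise ValidationError(f"cardinality k={k} outside [1, {M}]")
    rng = np.random.default_rng(random_state)

    best_var, best_w, best_support = -np.inf, None, None
    for w0 in _candidate_inits(S, k, restarts, rng):
        if solver == "truncated_power":
            support = _truncated_power(S, k, w0, max_iter, tol)
        elif solver == "l1":
            support = _l1_support(S, k, w0, max_iter, tol)
        else:
            raise ValidationError(f"unknown solver {solver!r}")
        if len(support) < k:
            order = np.argsort(-np.diag(S), kind="stable")
            pad = [j for j in order if j not in set(support)]
            support = np.sort(
                np.concatenate([support, pad[: k - len(support)]])
            ).astype(int)
        var, w = _submatrix_leading(S, np.asarray(support, dtype=int))
        if var > best_var + 1e-15:
            best_var, best_w, best_support = var, w, tuple(int(j) for j in support)
    assert best_w is not None
    return best_w, best_support, best_var


def adjusted_variance(X, loadings: np.ndarray) -> np.ndarray:
    """Cumulative % of total variance explained by (possibly correlated)
    loading vectors, via successive orthogonalization of the score vectors.

    The score matrix T = X L' is QR-factorized; component i contributes
    R[i,i]^2 / (N-1), i.e. only variance not already captured by earlier
    components.  Equals the eigenvalue ratios exactly when the loadings are
    the dense PCA eigenvectors.
    """
    A = _as_array(X)
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[1] != A.shape[1]:
        raise ValidationError("loading length does not match item count")
    S = covariance(A)
    total = float(np.trace(S))
    if total <= 0:
        return np.zeros(L.shape[0])
    T = (A - A.mean(axis=0)) @ L.T
    _, R = qr(T, mode="reduced")
    increments = np.diag(R) ** 2 / (A.shape[0] - 1)
    return 100.0 * np.cumsum(increments) / total


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class DensePCA(BaseEstimator, TransformerMixin):
    """Classical PCA via the eigendecomposition of the sample covariance.

    Components are ordered by eigenvalue (descending); signs follow the
    largest-magnitude-entry-positive rule, and eigenvalue ties keep the
    eigensolver's deterministic output order.

    Attributes (after fit): ``components_`` (K x M loadings),
    ``explained_variance_`` (eigenvalues), ``cum_variance_pct_``,
    ``item_names_``, ``n_features_in_``.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        A = _as_array(X)
        S = covariance(A)
        M = S.shape[0]
        if not (1 <= self.n_components <= M):
            raise ValidationError(
                f"n_components={self.n_components} outside [1, {M}]"
            )
        vals, vecs = eigh(S)
        order = np.argsort(-vals, kind="stable")
        vals, vecs = vals[order], vecs[:, order]
        K = self.n_components
        self.components_ = np.vstack(
            [_fix_sign(vecs[:, i]) for i in range(K)]
        )
        self.explained_variance_ = vals[:K]
        total = float(np.trace(S))
        self.cum_variance_pct_ = (
            100.0 * np.cumsum(vals[:K]) / total if total > 0
            else np.zeros(K)
        )
        self.item_names_ = _item_names(X, M)
        self.n_features_in_ = M
        return self

    def transform(self, X):
        A = _as_array(X)
        return A @ self.components_.T

    def to_component_set(self, X) -> ComponentSet:
        A = _as_array(X)
        return ComponentSet(
            loadings=self.components_.copy(),
            supports=tuple(
                tuple(range(self.n_features_in_))
                for _ in range(self.n_components)
            ),
            scores=A @ self.components_.T,
            cum_variance_pct=self.cum_variance_pct_.copy(),
            explained_variance=self.explained_variance_.copy(),
            method="dense",
            item_names=self.item_names_,
        )


class SparsePCA(BaseEstimator, TransformerMixin):
    """Cardinality-constrained sparse PCA with projection deflation.

    Parameters
    ----------
    n_components : int, default 3
        Number of components to extract (successive deflation rounds).
    cardinality : int, sequence of int, or "auto", default 2
        Target nonzero count per component.  ``"auto"`` picks, per stage,
        the smallest k whose achieved variance reaches
        ``auto_variance_fraction`` of the dense leading eigenvalue at that
        stage.
    auto_variance_fraction : float, default 0.9
        Threshold for the automatic cardinality rule.
    restarts : int, default 8
        Random restarts added to the deterministic initializations.
    max_iter : int, default 1000
    tol : float, default 1e-9
        Relative achieved-variance convergence tolerance.
    solver : {"truncated_power", "l1"}, default "truncated_power"
        Hard-thresholded power iteration, or the soft-thresholded (L1
        penalized) variant with the penalty bisected to hit the target
        cardinality.
    random_state : int or Generator, default 0

    Attributes (after fit)
    ----------------------
    components_ : (K, M) array of unit-norm sparse loadings.
    supports_ : per-component tuples of item indices (exactly k each).
    explained_variance_ : achieved variance per component at its stage.
    cum_variance_pct_ : adjusted cumulative % of total variance.
    cardinalities_ : resolved per-component cardinalities.
    """

    def __init__(
        self,
        n_components: int = 3,
        cardinality: int | Sequence[int] | str = 2,
        auto_variance_fraction: float = 0.9,
        restarts: int = 8,
        max_iter: int = 1000,
        tol: float = 1e-9,
        solver: str = "truncated_power",
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.cardinality = cardinality
        self.auto_variance_fraction = auto_variance_fraction
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.solver = solver
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _resolve_cardinalities(self, M: int) -> list[int | None]:
        if isinstance(self.cardinality, str):
            if self.cardinality != "auto":
                raise ValidationError(
                    f"cardinality must be an int, a sequence or 'auto', "
                    f"got {self.cardinality!r}"
                )
            return [None] * self.n_components
        if np.isscalar(self.cardinality):
            ks = [int(self.cardinality)] * self.n_components
        else:
            ks = [int(k) for k in self.cardinality]
            if len(ks) != self.n_components:
                raise ValidationError(
                    f"{len(ks)} cardinalities for "
                    f"{self.n_components} components"
                )
        for k in ks:
            if not (1 <= k <= M):
                raise ValidationError(f"cardinality {k} outside [1, {M}]")
        return list(ks)

    def _auto_k(self, S: np.ndarray, rng_seed) -> tuple[int, np.ndarray,
                                                        tuple[int, ...], float]:
        dense_var = float(eigh(S)[0][-1])
        M = S.shape[0]
        for k in range(1, M + 1):
            w, support, var = sparse_component(
                S, k, restarts=self.restarts, max_iter=self.max_iter,
                tol=self.tol, solver=self.solver, random_state=rng_seed,
            )
            if var >= self.auto_variance_fraction * dense_var:
                return k, w, support, var
        return M, w, support, var  # pragma: no cover - k=M always passes

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        A = _as_array(X)
        S0 = covariance(A)
        M = S0.shape[0]
        if not (1 <= self.n_components <= M):
            raise ValidationError(
                f"n_components={self.n_components} outside [1, {M}]"
            )
        ks = self._resolve_cardinalities(M)
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")

        seeds = np.random.SeedSequence(self.random_state).spawn(
            self.n_components
        )
        loadings, supports, variances, resolved = [], [], [], []
        D = A.copy()
        for i, k in enumerate(ks):
            rng = np.random.default_rng(seeds[i])
            S = covariance(D)
            if k is None:
                k, w, support, var = self._auto_k(S, rng)
            else:
                w, support, var = sparse_component(
                    S, k, restarts=self.restarts, max_iter=self.max_iter,
                    tol=self.tol, solver=self.solver, random_state=rng,
                )
            loadings.append(w)
            supports.append(support)
            variances.append(var)
            resolved.append(k)
            D = deflate(D, w)

        self.components_ = np.vstack(loadings)
        self.supports_ = tuple(supports)
        self.explained_variance_ = np.asarray(variances)
        self.cardinalities_ = tuple(resolved)
        self.cum_variance_pct_ = adjusted_variance(A, self.components_)
        self.item_names_ = _item_names(X, M)
        self.n_features_in_ = M
        return self

    def transform(self, X):
        A = _as_array(X)
        return A @ self.components_.T

    def to_component_set(self, X) -> ComponentSet:
        """Package the fitted loadings with scores against ``X``."""
        A = _as_array(X)
        return ComponentSet(
            loadings=self.components_.copy(),
            supports=self.supports_,
            scores=A @ self.components_.T,
            cum_variance_pct=self.cum_variance_pct_.copy(),
            explained_variance=self.explained_variance_.copy(),
            method="sparse",
            item_names=self.item_names_,
        )


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def pca(X, n_components: int = 3) -> ComponentSet:
    """Dense PCA of a centered matrix; see :class:`DensePCA`."""
    est = DensePCA(n_components=n_components).fit(X)
    return est.to_component_set(X)


def spca_fit(X, n_components: int = 3, cardinality=2, **kwargs) -> ComponentSet:
    """Sparse PCA of a centered matrix; see :class:`SparsePCA`."""
    est = SparsePCA(
        n_components=n_components, cardinality=cardinality, **kwargs
    ).fit(X)
    return est.to_component_set(X)


def cardinality_path(
    X,
    component_index: int = 0,
    *,
    cardinality: int | Sequence[int] | str = 2,
    restarts: int = 8,
    max_iter: int = 1000,
    tol: float = 1e-9,
    solver: str = "truncated_power",
    random_state: int | None = 0,
) -> list[tuple[int, float]]:
    """Cardinality-variance trade-off at one deflation stage.

    Deflates ``X`` through the first ``component_index`` sparse components
    (fitted with the given configuration), then reports, for k = 1..M, the
    achieved variance of the best k-sparse component as a percentage of the
    original total variance.  The curve is nondecreasing in k and reaches
    the dense leading eigenvalue at k = M; it is the quantitative basis for
    choosing how many items each component keeps.
    """
    A = _as_array(X)
    total = float(np.trace(covariance(A)))
    if component_index > 0:
        est = SparsePCA(
            n_components=component_index, cardinality=cardinality,
            restarts=restarts, max_iter=max_iter, tol=tol, solver=solver,
            random_state=random_state,
        ).fit(A)
        for w in est.components_:
            A = deflate(A, w)
    S = covariance(A)
    out = []
    for k in range(1, S.shape[0] + 1):
        _, _, var = sparse_component(
            S, k, restarts=restarts, max_iter=max_iter, tol=tol,
            solver=solver, random_state=random_state,
        )
        out.append((k, 100.0 * var / total if total > 0 else 0.0))
    return out
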
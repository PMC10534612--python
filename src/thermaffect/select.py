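"""Neighborhood component analysis (NCA) feature weighting and selection.

NCA learns one non-negative relevance weight per feature by maximizing a
soft (probabilistic) leave-one-out nearest-neighbour classification
accuracy.  With a weighted cityblock distance

    D_w(x_i, x_j) = sum_l  w_l^2 |x_il - x_jl|,

sample ``i`` picks sample ``j`` as its reference point with probability
``p_ij`` proportional to ``exp(-D_w(x_i, x_j) / sigma)`` (``p_ii = 0``), is
correctly classified with probability ``p_i`` (the total probability mass
on same-class reference points), and the regularized objective

    xi(w) = sum_i p_i - lambda * sum_l w_l^2

is maximized by first-order ascent with a backtracking line search.  The
regularization strength ``lambda`` is tuned by fivefold cross-validation
(participant-grouped when groups are supplied) on the held-out soft-LOO
classification loss; features are then ranked by their squared weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import ThermaffectError

logger = logging.getLogger(__name__)

#: Cache limit for the pairwise |x_il - x_jl| tensor, in bytes.
_CACHE_LIMIT = 600_000_000
_FEATURE_CHUNK = 64


class _NcaCore:
    """Shared state for repeated objective/gradient evaluations on one set."""

    def __init__(self, X: np.ndarray, y: np.ndarray, sigma: float):
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y)
        self.sigma = float(sigma)
        self.n, self.d = self.X.shape
        if self.n < 2:
            raise ValueError("need at least 2 samples")
        self.same = self.y[:, None] == self.y[None, :]
        nbytes = self.n * self.n * self.d * 8
        if nbytes <= _CACHE_LIMIT:
            self.A = np.abs(self.X[:, None, :] - self.X[None, :, :])
            self.A_flat = self.A.reshape(self.n * self.n, self.d)
        else:  # pragma: no cover - exercised only on very large problems
            self.A = None
            self.A_flat = None

    def distances(self, w: np.ndarray) -> np.ndarray:
        w2 = np.asarray(w, dtype=float) ** 2
        if self.A_flat is not None:
            return (self.A_flat @ w2).reshape(self.n, self.n)
        D = np.zeros((self.n, self.n))
        for start in range(0, self.d, _FEATURE_CHUNK):
            sl = slice(start, start + _FEATURE_CHUNK)
            block = np.abs(self.X[:, None, sl] - self.X[None, :, sl])
            D += block @ w2[sl]
        return D

    def probabilities(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Reference-point probabilities ``p_ij`` and per-sample ``p_i``.

        Rows are shifted by their off-diagonal minimum before
        exponentiation so no kernel row can underflow to all-zeros.
        """
        D = self.distances(w)
        shifted = D.copy()
        np.fill_diagonal(shifted, np.inf)
        row_min = shifted.min(axis=1)
        # The inf diagonal maps to exp(-inf) = 0, enforcing p_ii = 0.
        E = np.exp(-(shifted - row_min[:, None]) / self.sigma)
        p = E / E.sum(axis=1, keepdims=True)
        p_i = (p * self.same).sum(axis=1)
        return p, p_i

    def objective(self, w: np.ndarray, lam: float) -> float:
        _, p_i = self.probabilities(w)
        return float(p_i.sum() - lam * float(np.sum(np.asarray(w) ** 2)))

    def objective_and_gradient(
        self, w: np.ndarray, lam: float
    ) -> tuple[float, np.ndarray]:
        w = np.asarray(w, dtype=float)
        p, p_i = self.probabilities(w)
        obj = float(p_i.sum() - lam * float(np.sum(w**2)))
        B = p * p_i[:, None] - p * self.same
        if self.A_flat is not None:
            inner = self.A_flat.T @ B.ravel()
        else:  # pragma: no cover
            inner = np.zeros(self.d)
            for start in range(0, self.d, _FEATURE_CHUNK):
                sl = slice(start, start + _FEATURE_CHUNK)
                block = np.abs(self.X[:, None, sl] - self.X[None, :, sl])
                inner[sl] = np.einsum("ij,ijl->l", B, block)
        grad = 2.0 * w * (inner / self.sigma - lam)
        return obj, grad


def nca_probabilities(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Soft nearest-neighbour reference probabilities and per-sample accuracy."""
    return _NcaCore(X, y, sigma).probabilities(np.asarray(w, dtype=float))


def nca_objective(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float, sigma: float = 1.0
) -> float:
    """Regularized soft-LOO accuracy ``xi(w)``."""
    return _NcaCore(X, y, sigma).objective(np.asarray(w, dtype=float), lam)


def nca_gradient(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float, sigma: float = 1.0
) -> np.ndarray:
    """Analytic gradient of ``xi(w)`` with respect to the raw weights."""
    return _NcaCore(X, y, sigma).objective_and_gradient(np.asarray(w, dtype=float), lam)[1]


@dataclass
class NcaResult:
    """Fitted NCA weights and the tuning trace that produced them."""

    omega: np.ndarray
    lam: float
    sigma: float
    objective_trace: list[float]
    cv_loss: dict[float, float] = field(default_factory=dict)
    feature_names: list[str] | None = None

    @property
    def weights(self) -> np.ndarray:
        """Reported feature weights: the squared raw weights ``omega**2``."""
        return self.omega**2


def _ascend(
    core: _NcaCore, lam: float, max_iter: int, tol: float
) -> tuple[np.ndarray, list[float]]:
    """Gradient ascent from all-ones with a backtracking (Armijo) search."""
    w = np.ones(core.d)
    obj, grad = core.objective_and_gradient(w, lam)
    trace = [obj]
    step = 1.0
    for _ in range(max_iter):
        gsq = float(grad @ grad)
        if gsq < 1e-20:
            break
        s = step
        accepted = False
        while s > 1e-14:
            w_new = w + s * grad
            obj_new = core.objective(w_new, lam)
            if obj_new >= obj + 1e-4 * s * gsq:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        rel = (obj_new - obj) / (1.0 + abs(obj))
        w = w_new
        obj, grad = core.objective_and_gradient(w, lam)
        trace.append(obj)
        step = min(s * 2.0, 1e4)
        if rel < tol:
            break
    return w, trace


def _holdout_loss(
    w: np.ndarray,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    sigma: float,
) -> float:
    """Mean ``1 - p(correct)`` of held-out samples under the soft-LOO rule."""
    w2 = np.asarray(w, dtype=float) ** 2
    D = np.zeros((len(X_test), len(X_train)))
    for start in range(0, X_train.shape[1], _FEATURE_CHUNK):
        sl = slice(start, start + _FEATURE_CHUNK)
        block = np.abs(X_test[:, None, sl] - X_train[None, :, sl])
        D += block @ w2[sl]
    E = np.exp(-(D - D.min(axis=1, keepdims=True)) / sigma)
    p = E / E.sum(axis=1, keepdims=True)
    same = y_test[:, None] == y_train[None, :]
    return float(np.mean(1.0 - (p * same).sum(axis=1)))


def _cv_folds(y: np.ndarray, groups: np.ndarray | None, n_splits: int, seed: int):
    """Stratified (optionally group-aware) folds; re-stratify or fail loudly."""

    def _valid(folds) -> bool:
        classes = set(np.unique(y))
        for train_idx, test_idx in folds:
            if len(test_idx) == 0 or set(np.unique(y[train_idx])) != classes:
                return False
        return True

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        try:
            folds = list(splitter.split(np.zeros(len(y)), y, groups))
        except ValueError:
            folds = []
        if folds and _valid(folds):
            return folds
        logger.warning("group-aware folds degenerate; re-stratifying without groups")
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    if not _valid(folds):
        raise ThermaffectError("cannot build folds containing every class")
    return folds


def fit_nca(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    lambda_grid: list[float] | None = None,
    sigma: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    cv_folds: int = 5,
    seed: int = 0,
) -> NcaResult:
    """Tune ``lambda`` by fivefold CV, then refit the weights on all data.

    ``X`` is expected standardized.  Each candidate ``lambda`` is scored by
    the mean held-out soft-LOO classification loss over the folds; the
    minimizer (smaller ``lambda`` on ties) is refit on the full set.
    Deterministic for fixed data and ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct labels to fit NCA")
    n = len(X)
    if lambda_grid is None:
        lambda_grid = [v / n for v in (0.0, 0.5, 1.0, 2.0, 4.0)]
    if len(lambda_grid) == 0:
        raise ValueError("lambda_grid must be nonempty")

    cv_loss: dict[float, float] = {}
    if len(lambda_grid) == 1:
        best_lam = float(lambda_grid[0])
    else:
        folds = _cv_folds(y, groups, cv_folds, seed)
        cores = []
        for train_idx, test_idx in folds:
            cores.append((_NcaCore(X[train_idx], y[train_idx], sigma), train_idx, test_idx))
        for lam in lambda_grid:
            losses = []
            for core, train_idx, test_idx in cores:
                w, _ = _ascend(core, lam, max_iter, tol)
                losses.append(
                    _holdout_loss(w, X[train_idx], y[train_idx], X[test_idx], y[test_idx], sigma)
                )
            cv_loss[float(lam)] = float(np.mean(losses))
        best_lam = min(cv_loss, key=lambda l: (cv_loss[l], l))

    core = _NcaCore(X, y, sigma)
    omega, trace = _ascend(core, best_lam, max_iter, tol)
    return NcaResult(
        omega=omega,
        lam=best_lam,
        sigma=sigma,
        objective_trace=trace,
        cv_loss=cv_loss,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def top_k(result: NcaResult, k: int) -> list[str]:
    """The ``k`` features with the largest weights.

    Sorted by weight descending; exact ties broken by canonical
    (lexicographic) feature-name order.
    """
    d = len(result.omega)
    if k > d:
        raise ValueError(f"k={k} exceeds the number of features ({d})")
    names = (
        result.feature_names
        if result.feature_names is not None
        else [f"f{i}" for i in range(d)]
    )
    order = sorted(zip(names, result.weights), key=lambda nw: (-nw[1], nw[0]))
    return [name for name, _ in order[:k]]


def selection_frequency(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    groups: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    lam: float = 0.0,
    sigma: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Rank features by how often they enter the per-fold top-``k``.

    An alternative ranking mode: NCA is refit on each CV fold's training
    side at a fixed ``lambda`` and every feature is scored by its number of
    appearances among that fold's ``k`` largest weights.  Returns
    ``(name, count)`` pairs sorted by count descending then name.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(d)]
    counts = {name: 0 for name in names}
    for train_idx, _ in _cv_folds(y, groups, cv_folds, seed):
        core = _NcaCore(X[train_idx], y[train_idx], sigma)
        omega, _ = _ascend(core, lam, max_iter, tol)
        fold_result = NcaResult(
            omega=omega, lam=lam, sigma=sigma, objective_trace=[], feature_names=list(names)
        )
        for name in top_k(fold_result, k):
            counts[name] += 1
    return sorted(counts.items(), key=lambda nc: (-nc[1], nc[0]))
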
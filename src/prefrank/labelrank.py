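"""Local k-nearest-neighbor label ranking.

Predicts a complete ranking for a new judge from their covariates: the
``n_neighbors`` nearest training judges (Euclidean distance) are selected, a
Luce model is fitted to their rankings, and the predicted ranking orders the
items by decreasing estimated utility.  The neighborhood size can be chosen
by seeded 10-fold cross-validation minimizing the total Kendall distance
between predicted and observed rankings.

Tiny neighborhoods routinely produce degenerate Luce fits (an item never
beaten, utilities diverging); those neighborhoods fall back to the mean-rank
ordering of the neighbors, which is also the Luce modal ordering in the
degenerate limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .models import LuceModel, utilities_to_ranking
from .rankdist import distance_matrix

__all__ = ["KNNLabelRanker", "local_knn", "local_knn_cv", "CVResult"]


def _neighbor_predict(rankings: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Predicted ranking from one neighborhood (Luce fit, mean-rank fallback)."""
    neigh = rankings[idx]
    if len(neigh) == 1:
        return neigh[0].astype(np.int64)
    mean_rank = neigh.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            m = LuceModel(n_restarts=0).fit(neigh)
            if m.converged_ and not m.boundary_:
                return utilities_to_ranking(m.util_)[0]
        except Exception:
            pass
    return utilities_to_ranking(-mean_rank)[0]


class KNNLabelRanker(BaseEstimator):
    """Local kNN label ranker (fit covariates + rankings, predict rankings).

    Parameters
    ----------
    n_neighbors : int
        Neighborhood size; must not exceed the training set size.
    standardize : bool
        Standardize covariate columns (training mean/SD) before computing
        Euclidean distances.  Off by default: the neighborhood structure is
        scale-dependent and the caller may already work in comparable units.
    """

    def __init__(self, n_neighbors: int = 5, standardize: bool = False):
        self.n_neighbors = n_neighbors
        self.standardize = standardize

    def fit(self, X, rankings):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        rankings = np.asarray(rankings)
        if len(X) != len(rankings):
            raise ValueError("covariates and rankings must have one row per judge")
        if not 1 <= self.n_neighbors <= len(X):
            raise ValueError(f"n_neighbors must be in 1..{len(X)}")
        self.X_ = X
        self.rankings_ = np.asarray(rankings, dtype=np.int64)
        if self.standardize:
            self.mu_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.standardize:
            return (X - self.mu_) / self.sd_
        return X

    def kneighbors(self, X) -> np.ndarray:
        """Indices of the n_neighbors nearest training judges per query row.

        Distance ties beyond the neighborhood boundary are broken by
        training index (stable sort), so predictions are deterministic.
        """
        Xq = self._prep(X)
        Xt = self._prep(self.X_)
        d2 = ((Xq[:, None, :] - Xt[None, :, :]) ** 2).sum(axis=2)
        return np.argsort(d2, axis=1, kind="stable")[:, : self.n_neighbors]

    def predict(self, X) -> np.ndarray:
        idxs = self.kneighbors(X)
        return np.stack([_neighbor_predict(self.rankings_, idx) for idx in idxs])


def local_knn(train_rankings, train_cov, test_cov, knn_k: int,
              standardize: bool = False) -> np.ndarray:
    """One-call local kNN label ranking: predicted rankings for test judges."""
    model = KNNLabelRanker(n_neighbors=knn_k, standardize=standardize)
    return model.fit(train_cov, train_rankings).predict(test_cov)


@dataclass
class CVResult:
    best_k: int
    predictions: np.ndarray
    cv_errors: np.ndarray   # total Kendall distance per candidate k
    k_grid: np.ndarray


def _fold_assignment(n: int, folds: int, rng) -> np.ndarray:
    """Seeded shuffled fold labels; remainders spread across the first folds."""
    labels = np.concatenate([np.arange(folds)] * (n // folds + 1))[:n]
    labels.sort()
    perm = rng.permutation(n)
    out = np.empty(n, dtype=np.int64)
    out[perm] = labels
    return out


def local_knn_cv(train_rankings, train_cov, test_cov, folds: int = 10,
                 k_grid=range(1, 21), seed: int = 0,
                 standardize: bool = False) -> CVResult:
    """Cross-validated neighborhood size for local kNN label ranking.

    For each candidate k, every held-out judge is predicted from its
    neighbors in the remaining folds and charged the Kendall distance to its
    observed ranking; the CV error is the total over judges.  The smallest k
    attaining the minimum wins ties.  A fold whose neighborhood prediction
    fails outright is penalized with the maximum Kendall distance C(k_items, 2).
    Final predictions for ``test_cov`` use the winning k on the full
    training data.
    """
    rankings = np.asarray(train_rankings, dtype=np.int64)
    X = np.asarray(train_cov, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k_items = rankings.shape
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError("need at least one judge per fold")
    k_grid = np.asarray(list(k_grid), dtype=np.int64)
    rng = np.random.default_rng(seed)
    fold_of = _fold_assignment(n, folds, rng)
    max_d = k_items * (k_items - 1) / 2.0

    errors = np.zeros(len(k_grid))
    for fold in range(folds):
        test_mask = fold_of == fold
        tr_r, tr_x = rankings[~test_mask], X[~test_mask]
        te_r, te_x = rankings[test_mask], X[test_mask]
        for ki, kk in enumerate(k_grid):
            if kk > len(tr_r):
                errors[ki] += max_d * len(te_r)
                continue
            try:
                pred = local_knn(tr_r, tr_x, te_x, int(kk), standardize=standardize)
                for p, o in zip(pred, te_r):
                    errors[ki] += distance_matrix(p[None, :], o.astype(float), "tau")[0]
            except Exception:
                errors[ki] += max_d * len(te_r)

    best_k = int(k_grid[np.argmin(errors)])
    predictions = local_knn(rankings, X, test_cov, best_k, standardize=standardize)
    return CVResult(best_k=best_k, predictions=predictions,
                    cv_errors=errors, k_grid=k_grid)
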
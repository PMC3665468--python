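"""Multidimensional preference analysis (MDPREF).

An SVD biplot of ranking data: the N x k rank matrix is centered by the
overall mean rank (k+1)/2 and decomposed as X = U D V'.  Judges are plotted
as vectors (rows of sqrt(N-1) U) and items as points (rows of V D /
sqrt(N-1)); the perpendicular projection of the item points onto a judge's
vector approximates that judge's ranking when the retained dimensions
explain the data well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .rankcore import RankingTable

__all__ = ["PreferenceMap", "MDPREF", "mdpref"]


@dataclass
class PreferenceMap:
    """Item/judge coordinates and per-dimension explained variance."""

    item_coords: np.ndarray     # (k, d)
    judge_coords: np.ndarray    # (N, d)
    explain: np.ndarray         # (min(N, k),) proportions, all dimensions
    d: int

    @property
    def explained_retained(self) -> float:
        return float(self.explain[: self.d].sum())


class MDPREF(BaseEstimator):
    """SVD-based preference map of an individual ranking matrix.

    Parameters
    ----------
    n_components : int
        Retained dimensions (default 2).

    Attributes
    ----------
    item_coords_ : (k, n_components) item points, V D / sqrt(N-1)
    judge_coords_ : (N, n_components) judge vectors, sqrt(N-1) U
    explain_ : per-dimension proportion of variance, all dimensions
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, rankings):
        if isinstance(rankings, RankingTable):
            rankings = rankings.expand()
        X = np.asarray(rankings, dtype=float)
        if X.ndim != 2:
            raise ValueError("rankings must be an N x k matrix")
        N, k = X.shape
        if N < 2 or k < 2:
            raise ValueError("need at least two judges and two items")
        d = int(self.n_components)
        if not 1 <= d <= min(N, k):
            raise ValueError(f"n_components must be in 1..{min(N, k)}")
        Xc = X - (k + 1) / 2.0
        if np.allclose(Xc, 0):
            raise ValueError("no variance: all centered ranks are zero")
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-|loading| entry of each item axis positive
        for m in range(len(s)):
            j = np.argmax(np.abs(Vt[m]))
            if Vt[m, j] < 0:
                Vt[m] *= -1
                U[:, m] *= -1
        scale = np.sqrt(N - 1)
        self.n_, self.k_ = N, k
        self.singular_values_ = s
        self.judge_coords_ = scale * U[:, :d]
        self.item_coords_ = (Vt[:d].T * s[:d]) / scale
        self.explain_ = s**2 / np.sum(s**2)
        return self

    def fit_transform(self, rankings):
        """Fit and return the judge coordinates."""
        return self.fit(rankings).judge_coords_

    def to_map(self) -> PreferenceMap:
        return PreferenceMap(self.item_coords_, self.judge_coords_,
                             self.explain_, int(self.n_components))

    def plot(self, ax=None, scale_judges: bool = True, labels=None):
        """2D biplot: items as labelled points, judges as vectors.

        ``scale_judges`` shrinks the judge vectors to fit the item cloud
        (display only; returned coordinates are never rescaled).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        items = self.item_coords_[:, :2]
        judges = self.judge_coords_[:, :2]
        if scale_judges and np.abs(judges).max() > 0:
            judges = judges * (np.abs(items).max() / np.abs(judges).max())
        for v in judges:
            ax.plot([0, v[0]], [0, v[1]], color="grey", lw=0.5, alpha=0.5)
        ax.scatter(items[:, 0], items[:, 1], color="C3", zorder=3)
        names = labels if labels is not None else [str(i + 1) for i in range(self.k_)]
        for (x, y), name in zip(items, names):
            ax.annotate(name, (x, y), textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel(f"dim 1 ({100 * self.explain_[0]:.1f}%)")
        ax.set_ylabel(f"dim 2 ({100 * self.explain_[1]:.1f}%)")
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        return ax


def mdpref(rankings, d: int = 2) -> PreferenceMap:
    """Functional wrapper around :class:`MDPREF`."""
    return MDPREF(n_components=d).fit(rankings).to_map()
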
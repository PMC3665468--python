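"""Right-invariant distances between rankings and their weighted forms.

Four classical rank distances are provided, selected by a ``dtype`` string:

================  =======  ==================================================
dtype             symbol   definition for rankings pi, sigma of k items
================  =======  ==================================================
``tau``           T        number of discordant pairs (Kendall's tau)
``rho``           R        sqrt( sum_i (pi_i - sigma_i)^2 )   (Spearman rho)
``rho2``          R^2      sum_i (pi_i - sigma_i)^2
``foot``          F        sum_i |pi_i - sigma_i|             (footrule)
================  =======  ==================================================

Each admits a weighted generalization with a nonnegative weight per rank
position of the reference ranking sigma = pi0: positions that matter more to
the judges receive larger weights.  Kendall's tau weights enter as the
product w_{sigma(i)} w_{sigma(j)} of the two positions involved; the
Spearman/footrule family weights each item's displacement term by
w_{sigma(i)}.  With all-ones weights every weighted form reduces to its
unweighted counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rankcore import all_rankings, is_permutation

__all__ = ["DistanceSpec", "distance", "distance_matrix", "stage_counts", "DTYPES"]

DTYPES = ("tau", "rho", "rho2", "foot")

# accepted aliases for the Kendall distance
_ALIASES = {"kendall": "tau"}


@dataclass(frozen=True)
class DistanceSpec:
    """Which rank distance to use, optionally with rank-position weights.

    ``weights[j]`` is the weight of rank position j+1 under the reference
    ranking (the second argument of :func:`distance`).  Absent weights are
    equivalent to all ones.
    """

    kind: str = "tau"
    weights: tuple | None = None

    def __post_init__(self):
        kind = _ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in DTYPES:
            raise ValueError(f"unknown distance kind {self.kind!r}; choose from {DTYPES}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or not np.isfinite(w).all():
                raise ValueError("weights must be finite and nonnegative")
            object.__setattr__(self, "weights", tuple(w.tolist()))

    def weight_vector(self, k: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(k)
        w = np.asarray(self.weights, dtype=float)
        if len(w) != k:
            raise ValueError(f"weight vector has length {len(w)}, expected {k}")
        return w


def _check_pair(pi, sigma):
    pi = np.asarray(pi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if pi.shape != sigma.shape:
        raise ValueError("rankings must have the same length")
    if not (is_permutation(pi) and is_permutation(sigma)):
        raise ValueError("distances are defined for complete (untied) rankings")
    return pi, sigma


def distance(pi, sigma, spec: DistanceSpec | str = "tau", reference=None) -> float:
    """Distance between two complete rankings.

    When ``spec`` carries weights, each item's weight is the weight of the
    rank position it holds under the reference ranking pi0 — by default
    ``sigma`` itself (the usual model situation, where distances are taken
    to the modal ranking); pass ``reference`` to weight against a third
    ranking.  All values are returned as floats, including integral Kendall
    counts.
    """
    if isinstance(spec, str):
        spec = DistanceSpec(spec)
    pi, sigma = _check_pair(pi, sigma)
    k = len(pi)
    ref = sigma if reference is None else np.asarray(reference, dtype=float)
    if not is_permutation(ref):
        raise ValueError("reference must be a complete ranking")
    w = spec.weight_vector(k)
    wi = w[ref.astype(np.int64) - 1]         # weight attached to each item via pi0's rank
    if spec.kind == "tau":
        iu, ju = np.triu_indices(k, 1)
        disc = (pi[iu] - pi[ju]) * (sigma[iu] - sigma[ju]) < 0
        return float(np.sum(wi[iu] * wi[ju] * disc))
    diff = pi - sigma
    if spec.kind == "rho2":
        return float(np.sum(wi * diff**2))
    if spec.kind == "rho":
        return float(np.sqrt(np.sum(wi * diff**2)))
    return float(np.sum(wi * np.abs(diff)))  # foot


def distance_matrix(rankings, pi0, spec: DistanceSpec | str = "tau") -> np.ndarray:
    """Distances from each row of ``rankings`` to the reference ``pi0``, vectorized."""
    if isinstance(spec, str):
        spec = DistanceSpec(spec)
    R = np.asarray(rankings, dtype=float)
    if R.ndim == 1:
        R = R[None, :]
    pi0 = np.asarray(pi0, dtype=float)
    k = R.shape[1]
    w = spec.weight_vector(k)
    wi = w[pi0.astype(np.int64) - 1]
    if spec.kind == "tau":
        iu, ju = np.triu_indices(k, 1)
        disc = (R[:, iu] - R[:, ju]) * (pi0[iu] - pi0[ju]) < 0
        return disc @ (wi[iu] * wi[ju])
    diff = R - pi0
    if spec.kind == "rho2":
        return diff**2 @ wi
    if spec.kind == "rho":
        return np.sqrt(diff**2 @ wi)
    return np.abs(diff) @ wi


def stage_counts(pi, pi0) -> np.ndarray:
    """Kendall stage decomposition of ``pi`` against the reference ``pi0``.

    Stage i (1-based, i = 1..k-1) considers the item that pi0 ranks i-th;
    v_i counts the items ranked below it by pi0 but above it by pi — the
    adjacent transpositions ("mistakes") needed at that stage to sort pi
    into pi0.  The stage counts satisfy 0 <= v_i <= k-i and sum to the
    Kendall tau distance d(pi, pi0).
    """
    pi, pi0 = _check_pair(pi, pi0)
    k = len(pi)
    order0 = np.empty(k, dtype=np.int64)            # item (0-based) at each pi0 rank
    order0[pi0.astype(np.int64) - 1] = np.arange(k)
    v = np.zeros(k - 1, dtype=np.int64)
    for i in range(k - 1):
        item_i = order0[i]
        later = order0[i + 1:]
        v[i] = int(np.sum(pi[item_i] > pi[later]))
    return v


def kendall_max(k: int) -> float:
    """Largest attainable Kendall tau distance, C(k, 2)."""
    return k * (k - 1) / 2.0


def pairwise_tau_oracle(k: int) -> np.ndarray:
    """Brute-force k! x k! Kendall distance table (test oracle; k <= 5 sensible)."""
    perms = all_rankings(k)
    n = len(perms)
    out = np.zeros((n, n))
    for a in range(n):
        out[a] = distance_matrix(perms, perms[a], "tau")
    return out
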
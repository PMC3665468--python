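"""Synthetic ranking-data generation.

Exact samplers for each supported model family: sequential ("vase")
sampling for the Luce model, inverse-CDF sampling over the enumerated
permutation distribution for distance-based, stagewise, and weighted
distance-based models, and a covariate-driven generator for rank-ordered
logit fixtures.  Every function takes an integer seed (or a Generator) and
draws from its own stream; nothing touches global random state.

Enumeration sampling is exact rather than approximate and is the natural
choice here because the package caps item counts at k <= 8 (40320
permutations).
"""

from __future__ import annotations

import numpy as np

from .rankcore import all_rankings, ordering_to_ranking
from .rankdist import DistanceSpec, distance_matrix, stage_counts

__all__ = ["sample_luce", "sample_dbm", "sample_phicom", "sample_wdbm", "make_rol_fixture"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_luce(util, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` rankings from a Luce model with item utilities ``util``.

    Sequential sampling without replacement: the rank-1 item is drawn with
    probability proportional to its utility, removed, and the process
    repeats on the remaining items (the vase-model view of the Luce
    likelihood).  Returns an (n, k) integer ranking matrix.
    """
    v = np.asarray(util, dtype=float)
    if np.any(v <= 0) or not np.isfinite(v).all():
        raise ValueError("utilities must be positive and finite")
    k = len(v)
    rng = _rng(seed)
    out = np.empty((n, k), dtype=np.int64)
    for row in range(n):
        remaining = list(range(k))
        order = np.empty(k, dtype=np.int64)
        for j in range(k):
            p = v[remaining]
            idx = rng.choice(len(remaining), p=p / p.sum())
            order[j] = remaining.pop(idx) + 1
        out[row] = ordering_to_ranking(order)
    return out


def _enumerated_probs(pi0, spec: DistanceSpec, lam=None, lams=None) -> tuple[np.ndarray, np.ndarray]:
    pi0 = np.asarray(pi0, dtype=float)
    k = len(pi0)
    perms = all_rankings(k)
    if lams is not None:
        V = np.stack([stage_counts(p, pi0) for p in perms.astype(float)])
        energy = V @ np.asarray(lams, dtype=float)
    else:
        d = distance_matrix(perms, pi0, spec)
        energy = d if lam is None else lam * d
    logp = -energy
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return perms, p


def _inverse_cdf_sample(perms, p, n, rng) -> np.ndarray:
    idx = rng.choice(len(perms), size=n, p=p)
    return perms[idx].copy()


def sample_dbm(pi0, lam: float, n: int, dtype: str = "tau", seed=None) -> np.ndarray:
    """Draw ``n`` rankings from the distance-based model e^{-lam d(pi, pi0)}/C."""
    if lam < 0:
        raise ValueError("dispersion lam must be nonnegative")
    perms, p = _enumerated_probs(pi0, DistanceSpec(dtype), lam=lam)
    return _inverse_cdf_sample(perms, p, n, _rng(seed))


def sample_phicom(pi0, lams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` rankings from the stagewise (phi-component) model."""
    lams = np.asarray(lams, dtype=float)
    if np.any(lams < 0):
        raise ValueError("stage dispersions must be nonnegative")
    perms, p = _enumerated_probs(pi0, DistanceSpec("tau"), lams=lams)
    return _inverse_cdf_sample(perms, p, n, _rng(seed))


def sample_wdbm(pi0, weights, n: int, dtype: str = "foot", seed=None) -> np.ndarray:
    """Draw ``n`` rankings from the weighted distance-based model e^{-d_w}/C(w)."""
    spec = DistanceSpec(dtype, weights=tuple(np.asarray(weights, dtype=float)))
    perms, p = _enumerated_probs(pi0, spec)
    return _inverse_cdf_sample(perms, p, n, _rng(seed))


def make_rol_fixture(n: int, k: int, m: int, beta, seed=None, clusters=None,
                     cluster_sep: float = 5.0):
    """Covariates plus rankings from a rank-ordered logit process.

    ``beta`` is a (k, m+1) matrix of per-item intercepts and slopes (the last
    item is conventionally the zero reference row).  Judge covariates are
    standard normal, or, with ``clusters=c``, normal around c cluster centers
    placed ``+/- cluster_sep`` apart on every covariate axis.  Judge n ranks
    by a Luce draw with utilities exp(beta_0j + sum_m beta_jm x_nm).

    Returns ``(rankings, covariates)`` — an (n, k) ranking matrix and an
    (n, m) covariate matrix (plus cluster labels when clustered).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (k, m + 1):
        raise ValueError(f"beta must be (k, m+1) = ({k}, {m + 1}); got {beta.shape}")
    rng = _rng(seed)
    if clusters:
        labels = rng.integers(0, clusters, size=n)
        centers = (np.arange(clusters)[:, None] - (clusters - 1) / 2.0) * np.ones((clusters, max(m, 1))) * cluster_sep
        X = centers[labels][:, :m] + rng.standard_normal((n, m))
    else:
        labels = None
        X = rng.standard_normal((n, m))
    design = np.hstack([np.ones((n, 1)), X])
    logu = design @ beta.T                      # (n, k)
    rankings = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        rankings[i] = sample_luce(np.exp(logu[i] - logu[i].max()), 1, rng)[0]
    if clusters:
        return rankings, X, labels
    return rankings, X
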
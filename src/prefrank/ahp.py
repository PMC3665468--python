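"""Analytic Hierarchy Process: criterion weights and inconsistency indices.

A pairwise comparison matrix A is positive and reciprocal (a_ts = 1/a_st,
unit diagonal); its entries record how strongly criterion s is preferred
over criterion t on the 1/9..9 Saaty scale.  Weights are the normalized
principal right eigenvector of A.  Perfect consistency means
a_st * a_tu = a_su for every triad, in which case the principal eigenvalue
lambda_max equals k; two departures from it are quantified:

* Saaty's consistency ratio  (lambda_max - k) / ((k - 1) RI_k), with RI_k
  the expected (lambda_max - k)/(k - 1) of a random reciprocal matrix;
* Koczkodaj's index  max over triads of min(|1 - b/(ac)|, |1 - ac/b|).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._ri_table import RI_SEED, RI_SIM_REPS, RI_TABLE

__all__ = ["AhpResult", "ahp_weights", "simulate_ri", "validate_matrix",
           "random_reciprocal_matrix", "SAATY_SCALE"]

# the 17-point discrete Saaty scale: 1/9..1/2 and 1..9
SAATY_SCALE = np.concatenate([1.0 / np.arange(9, 1, -1), np.arange(1, 10, dtype=float)])


@dataclass
class AhpResult:
    weights: np.ndarray
    lambda_max: float
    saaty: float
    koczkodaj: float


def validate_matrix(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("comparison matrix must be square")
    if np.any(a <= 0) or not np.isfinite(a).all():
        raise ValueError("comparison matrix entries must be positive and finite")
    if not np.allclose(np.diag(a), 1.0, atol=1e-8):
        raise ValueError("comparison matrix must have unit diagonal")
    if not np.allclose(a * a.T, 1.0, rtol=1e-6):
        raise ValueError("comparison matrix must be reciprocal (a_ts = 1/a_st)")
    return a


def _principal_eig(a: np.ndarray, tol: float = 1e-12, max_iter: int = 10000):
    """Power iteration for the Perron eigenpair of a positive matrix."""
    k = a.shape[0]
    w = np.full(k, 1.0 / k)
    lam = 0.0
    for _ in range(max_iter):
        v = a @ w
        lam_new = v.sum() / w.sum()
        v /= v.sum()
        if np.max(np.abs(v - w)) < tol and abs(lam_new - lam) < tol:
            w, lam = v, lam_new
            break
        w, lam = v, lam_new
    ray = (a @ w) / w
    return w, float(ray.mean())


def koczkodaj_index(a) -> float:
    """Worst-triad inconsistency: max over s<t<u of min(|1-b/(ac)|, |1-ac/b|)
    with a = a_st, b = a_su, c = a_tu.  Zero iff the matrix is consistent."""
    a = validate_matrix(a)
    k = a.shape[0]
    if k < 3:
        raise ValueError("Koczkodaj's index needs at least 3 criteria (one triad)")
    worst = 0.0
    for s, t, u in itertools.combinations(range(k), 3):
        x, b, c = a[s, t], a[s, u], a[t, u]
        ratio = b / (x * c)
        worst = max(worst, min(abs(1 - ratio), abs(1 - 1 / ratio)))
    return float(worst)


def ahp_weights(a, ri: float | str = "table", ri_reps: int = 10000,
                seed: int = 0) -> AhpResult:
    """Weights and inconsistency indices of a pairwise comparison matrix.

    Parameters
    ----------
    a : (k, k) positive reciprocal matrix
    ri : "table", "simulate", or a positive float
        Source of the random index RI_k in Saaty's ratio: the bundled
        simulated table (default), a fresh seeded simulation, or an explicit
        value.
    """
    a = validate_matrix(a)
    k = a.shape[0]
    if not 3 <= k <= 15:
        raise ValueError("AHP analysis supports 3 to 15 criteria")
    w, lam = _principal_eig(a)
    if isinstance(ri, str):
        if ri == "table":
            ri_k = RI_TABLE[k]
        elif ri == "simulate":
            ri_k = simulate_ri(k, reps=ri_reps, seed=seed)
        else:
            raise ValueError("ri must be 'table', 'simulate', or a number")
    else:
        ri_k = float(ri)
        if ri_k <= 0:
            raise ValueError("explicit RI must be positive")
    saaty = (lam - k) / ((k - 1) * ri_k)
    return AhpResult(weights=w, lambda_max=lam, saaty=float(max(saaty, 0.0)),
                     koczkodaj=koczkodaj_index(a))


def random_reciprocal_matrix(k: int, rng) -> np.ndarray:
    """Random comparison matrix with upper-triangle entries uniform on the
    17-point Saaty scale, completed by reciprocity."""
    a = np.ones((k, k))
    iu, ju = np.triu_indices(k, 1)
    vals = rng.choice(SAATY_SCALE, size=len(iu))
    a[iu, ju] = vals
    a[ju, iu] = 1.0 / vals
    return a


def simulate_ri(k: int, reps: int = 10000, seed: int = 0) -> float:
    """Monte Carlo estimate of the random index RI_k.

    Mean of (lambda_max - k)/(k - 1) over ``reps`` random reciprocal
    matrices (Saaty-scale entries); seeded and reproducible.  The bundled
    RI table was produced this way with {reps} replicates per k and
    generator seeds {seed} + k.
    """
    if k < 3:
        raise ValueError("RI is defined for k >= 3")
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(k, 1)
    total = 0.0
    batch = 10000
    for start in range(0, reps, batch):
        b = min(batch, reps - start)
        a = np.ones((b, k, k))
        vals = rng.choice(SAATY_SCALE, size=(b, len(iu)))
        a[:, iu, ju] = vals
        a[:, ju, iu] = 1.0 / vals
        lam = np.linalg.eigvals(a).real.max(axis=1)
        total += ((lam - k) / (k - 1)).sum()
    return float(total / reps)


simulate_ri.__doc__ = simulate_ri.__doc__.format(seed=RI_SEED, reps=RI_SIM_REPS)
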
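"""Probability models for ranking data and their maximum-likelihood fits.

Five model families are supported:

* **Luce model** — independent positive utilities V_1..V_k; a ranking is
  built by repeatedly choosing the next-best item with probability
  proportional to the utilities still in play.  The log-likelihood is
  globally concave in log V.
* **Rank-ordered logit (ROL)** — the Luce model with judge covariates
  entering the utilities through a log-linear link,
  V_nj = exp(beta_j0 + sum_m beta_jm x_nm).
* **Distance-based model** — P(pi | lam, pi0) = exp(-lam d(pi, pi0)) / C(lam)
  for a right-invariant distance d; with Kendall's tau this is Mallows'
  phi-model and C(lam) has a closed form.
* **Phi-component model** — Kendall's tau decomposed into k-1 independent
  stages, each with its own dispersion lambda_i; the normalizing constant
  factorizes in closed form.
* **Weighted distance-based model** — the distance-based model with a
  rank-position weight vector w replacing (and absorbing) the single
  dispersion parameter: P(pi | w, pi0) = exp(-d_w(pi, pi0)) / C(w).

All fits return the maximized log-likelihood and a Pearson-residual
goodness-of-fit chi-square over the full permutation set (k <= 8).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .rankcore import RankingTable, all_rankings, rank_agg, ranking_to_ordering
from .rankdist import DistanceSpec, distance_matrix, stage_counts

__all__ = [
    "FitResult", "LuceModel", "RankOrderedLogit", "DistanceBasedModel",
    "PhiComponentModel", "WeightedDistanceModel",
    "luce_prob", "log_C", "mallows_log_C", "phi_log_C",
    "fit_luce", "fit_rol", "fit_dbm", "fit_phicom", "fit_wdbm",
    "goodness_of_fit", "select_model",
]

_LAM_MAX = 30.0     # dispersion upper bound; e^{-30} is numerically degenerate
_W_MAX = 30.0


# ---------------------------------------------------------------------------
# normalizing constants
# ---------------------------------------------------------------------------

def mallows_log_C(k: int, lam: float) -> float:
    """log C(lam) of Mallows' phi-model (Kendall distance), closed form.

    C(lam) = prod_{i=1}^{k-1} (1 - e^{-(k-i+1) lam}) / (1 - e^{-lam});
    lam -> 0 gives k! and lam -> inf gives 1.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam < 1e-12:
        return math.log(math.factorial(k))
    tot = 0.0
    for i in range(1, k):
        tot += np.log(-np.expm1(-(k - i + 1) * lam)) - np.log(-np.expm1(-lam))
    return float(tot)


def phi_log_C(k: int, lams) -> float:
    """log C(Lambda) of the phi-component model, closed form.

    C(Lambda) = prod_{i=1}^{k-1} (1 - e^{-(k-i+1) lam_i}) / (1 - e^{-lam_i}).
    """
    lams = np.asarray(lams, dtype=float)
    if len(lams) != k - 1:
        raise ValueError(f"need k-1 = {k - 1} stage dispersions, got {len(lams)}")
    if np.any(lams < 0):
        raise ValueError("stage dispersions must be nonnegative")
    tot = 0.0
    for i, lam in enumerate(lams, start=1):
        if lam < 1e-12:
            tot += math.log(k - i + 1)
        else:
            tot += np.log(-np.expm1(-(k - i + 1) * lam)) - np.log(-np.expm1(-lam))
    return float(tot)


def log_C(spec: DistanceSpec | str, k: int, lam: float | None = None) -> float:
    """log of the normalizing constant sum_pi exp(-lam d(pi, pi0)).

    By right invariance the constant does not depend on pi0, so the sum is
    taken against the identity reference.  For weighted specs ``lam`` must
    be omitted (the weights absorb the dispersion).  Enumerates S_k, hence
    limited to k <= 8.
    """
    if isinstance(spec, str):
        spec = DistanceSpec(spec)
    d = distance_matrix(all_rankings(k), np.arange(1, k + 1), spec)
    if spec.weights is None:
        if lam is None:
            raise ValueError("unweighted distances need a dispersion lam")
        if lam < 0:
            raise ValueError("lam must be nonnegative")
        return float(logsumexp(-lam * d))
    if lam is not None:
        raise ValueError("weighted distances have no separate lam (weights absorb it)")
    return float(logsumexp(-d))


# ---------------------------------------------------------------------------
# Luce likelihood machinery
# ---------------------------------------------------------------------------

def luce_prob(util, ordering=None, ranking=None) -> float:
    """Probability of one ranking under the Luce model.

    P = prod_{j=1}^{k-1} V_{pi^{-1}(j)} / sum_{i=j}^{k} V_{pi^{-1}(i)} —
    at each stage the next-ranked item is chosen among the remaining ones
    with probability proportional to utility.
    """
    v = np.asarray(util, dtype=float)
    if np.any(v <= 0):
        raise ValueError("utilities must be positive")
    if ordering is None:
        if ranking is None:
            raise ValueError("supply an ordering or a ranking")
        ordering = ranking_to_ordering(ranking)
    items = np.asarray(ordering, dtype=np.int64) - 1
    p = 1.0
    vv = v[items]
    denom = np.cumsum(vv[::-1])[::-1]
    for j in range(len(v) - 1):
        p *= vv[j] / denom[j]
    return float(p)


def _luce_loglik_grad(theta, orderings0, freq):
    """Log-likelihood and gradient w.r.t. per-row log-utilities.

    theta: (N, k) log-utilities per row; orderings0: (N, k) 0-based item
    indices by rank position; freq: (N,) row weights.  Returns (loglik,
    gradient of shape (N, k)).
    """
    N, k = orderings0.shape
    U = np.take_along_axis(theta, orderings0, axis=1)
    S = np.empty_like(U)
    S[:, -1] = U[:, -1]
    for j in range(k - 2, -1, -1):
        S[:, j] = np.logaddexp(U[:, j], S[:, j + 1])
    ll = float(freq @ (U[:, :-1] - S[:, :-1]).sum(axis=1))
    # gradient at rank position p: I[p <= k-2] - e^{U_p} * sum_{j<=min(p,k-2)} e^{-S_j}
    cum = np.cumsum(np.exp(-S[:, :-1]), axis=1)
    idx = np.minimum(np.arange(k), k - 2)
    gpos = (np.arange(k) <= k - 2).astype(float)[None, :] - np.exp(U) * cum[:, idx]
    gtheta = np.zeros_like(theta)
    np.put_along_axis(gtheta, orderings0, gpos * freq[:, None], axis=1)
    return ll, gtheta


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit of a ranking model."""

    family: str
    params: dict
    loglik: float
    n_params: int
    pi0: np.ndarray | None = None
    gof_chi2: float | None = None
    gof_df: int | None = None
    boundary: bool = False
    notes: list = field(default_factory=list)

    @property
    def gof_p_value(self) -> float | None:
        if self.gof_chi2 is None:
            return None
        return float(stats.chi2.sf(self.gof_chi2, self.gof_df))


def _coerce_table(rankings, freq) -> RankingTable:
    if isinstance(rankings, RankingTable):
        return rankings
    if freq is not None:
        return RankingTable(np.asarray(rankings, dtype=float), freq)
    return rank_agg(rankings)


def _require_strict(table: RankingTable, family: str) -> None:
    if not table.is_complete:
        raise ValueError(
            f"{family} fitting requires strict complete rankings; "
            "imputed tied rankings are accepted by descriptives only"
        )


def _attach_gof(model, table: RankingTable) -> None:
    chi2, df = goodness_of_fit(table, model)
    model.gof_chi2_ = chi2
    model.gof_df_ = df


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class LuceModel(BaseEstimator):
    """Maximum-likelihood Luce model.

    Parameters
    ----------
    ref_item : int or None
        1-based label of the item whose utility is fixed at 1 for
        identifiability; default the last item.
    n_restarts : int
        Extra random optimizer starts used to confirm the global optimum
        (the log-likelihood is concave in log-utilities, so all starts must
        agree).
    tol : float
        Convergence tolerance on the log-likelihood.
    random_state : int
        Seed for the random restarts.

    Attributes
    ----------
    util_ : (k,) positive utilities, reference item's utility = 1
    loglik_, gof_chi2_, gof_df_, n_params_, converged_, boundary_
    """

    def __init__(self, ref_item=None, n_restarts=2, tol=1e-8, random_state=0):
        self.ref_item = ref_item
        self.n_restarts = n_restarts
        self.tol = tol
        self.random_state = random_state

    def fit(self, rankings, freq=None):
        table = _coerce_table(rankings, freq)
        _require_strict(table, "Luce")
        k = table.k
        ref = (k if self.ref_item is None else int(self.ref_item)) - 1
        if not 0 <= ref < k:
            raise ValueError(f"ref_item must be in 1..{k}")
        ords = ranking_to_ordering(table.rankings.astype(np.int64)) - 1
        f = table.freq.astype(float)
        free = np.array([i for i in range(k) if i != ref])

        def negll(x):
            theta = np.zeros(k)
            theta[free] = x
            ll, g = _luce_loglik_grad(np.broadcast_to(theta, (len(ords), k)).copy(), ords, f)
            return -ll, -g.sum(axis=0)[free]

        rng = np.random.default_rng(self.random_state)
        sols = []
        for s in range(self.n_restarts + 1):
            x0 = np.zeros(k - 1) if s == 0 else rng.standard_normal(k - 1)
            res = optimize.minimize(negll, x0, jac=True, method="L-BFGS-B",
                                    options={"ftol": self.tol * 1e-2, "gtol": 1e-10})
            sols.append(res)
        best = min(sols, key=lambda r: r.fun)
        spread = max(abs(r.fun - best.fun) for r in sols)
        self.converged_ = bool(best.success and spread < 1e-4 * (1 + abs(best.fun)))
        theta = np.zeros(k)
        theta[free] = best.x
        self.boundary_ = bool(np.max(np.abs(theta)) > 15)
        if self.boundary_:
            warnings.warn(
                "Luce utilities at the numerical boundary (an item may be "
                "almost never / always ranked last); estimates may diverge",
                UserWarning, stacklevel=2,
            )
        self.k_ = k
        self.ref_ = ref + 1
        self.util_ = np.exp(theta)
        self.loglik_ = -float(best.fun)
        self.n_params_ = k - 1
        _attach_gof(self, table)
        return self

    def prob_table(self):
        """All k! rankings with their fitted probabilities."""
        perms = all_rankings(self.k_)
        p = np.array([luce_prob(self.util_, ranking=r) for r in perms])
        return perms, p

    def result(self) -> FitResult:
        return FitResult(
            family="luce", params={"util": self.util_, "ref_item": self.ref_},
            loglik=self.loglik_, n_params=self.n_params_,
            gof_chi2=self.gof_chi2_, gof_df=self.gof_df_, boundary=self.boundary_,
        )


class RankOrderedLogit(BaseEstimator):
    """Rank-ordered (exploded) logit: the Luce model with judge covariates.

    Judge n's utility for item j is V_nj = exp(beta_j0 + sum_m beta_jm x_nm);
    the reference item's coefficient row is fixed at zero.  Standard errors
    come from the observed information (numerical Hessian at the MLE) and
    p-values from Wald z statistics.

    Attributes
    ----------
    beta_ : (k, M+1) coefficient matrix (reference row zero)
    se_, z_, p_values_ : same shape; NaN on the reference row
    loglik_, n_params_, converged_
    """

    def __init__(self, ref_item=None, tol=1e-8, random_state=0):
        self.ref_item = ref_item
        self.tol = tol
        self.random_state = random_state

    def fit(self, rankings, X):
        R = np.asarray(rankings, dtype=np.int64)
        if R.ndim != 2:
            raise ValueError("rankings must be an N x k matrix (individual format)")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != R.shape[0]:
            raise ValueError("rankings and covariates must have one row per judge")
        N, k = R.shape
        M = X.shape[1]
        design = np.hstack([np.ones((N, 1)), X])
        self._check_collinear(design)
        ref = (k if self.ref_item is None else int(self.ref_item)) - 1
        ords = ranking_to_ordering(R) - 1
        f = np.ones(N)
        free = [i for i in range(k) if i != ref]
        P = (k - 1) * (M + 1)

        def unpack(x):
            beta = np.zeros((k, M + 1))
            beta[free] = x.reshape(k - 1, M + 1)
            return beta

        def negll(x):
            theta = design @ unpack(x).T          # (N, k) log-utilities
            ll, gtheta = _luce_loglik_grad(theta, ords, f)
            gbeta = gtheta.T @ design             # (k, M+1)
            return -ll, -gbeta[free].ravel()

        res = optimize.minimize(negll, np.zeros(P), jac=True, method="L-BFGS-B",
                                options={"ftol": self.tol * 1e-2, "gtol": 1e-10})
        self.converged_ = bool(res.success)
        beta = unpack(res.x)
        self.k_, self.m_, self.ref_ = k, M, ref + 1
        self.beta_ = beta
        self.loglik_ = -float(res.fun)
        self.n_params_ = P
        cov = self._observed_info_cov(negll, res.x)
        se = np.full((k, M + 1), np.nan)
        se[free] = np.sqrt(np.maximum(np.diag(cov), 0)).reshape(k - 1, M + 1)
        self.se_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z_ = self.beta_ / self.se_
        self.p_values_ = 2 * stats.norm.sf(np.abs(self.z_))
        return self

    @staticmethod
    def _check_collinear(design):
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            from scipy.linalg import qr
            _, r, piv = qr(design, mode="economic", pivoting=True)
            bad = sorted(piv[rank:])
            names = ["intercept" if j == 0 else f"covariate {j}" for j in bad]
            raise ValueError(f"collinear covariate columns: {', '.join(names)}")

    @staticmethod
    def _observed_info_cov(negll, xhat, h=1e-5):
        p = len(xhat)
        H = np.empty((p, p))
        for i in range(p):
            e = np.zeros(p)
            e[i] = h
            gp = negll(xhat + e)[1]
            gm = negll(xhat - e)[1]
            H[i] = (gp - gm) / (2 * h)
        H = (H + H.T) / 2
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)

    def predict_utilities(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.hstack([np.ones((len(X), 1)), X])
        return np.exp(design @ self.beta_.T)

    def predict(self, X):
        """Modal ranking per judge: items ordered by decreasing utility."""
        U = self.predict_utilities(X)
        return utilities_to_ranking(U)

    def result(self) -> FitResult:
        return FitResult(
            family="rol",
            params={"beta": self.beta_, "se": self.se_, "p_values": self.p_values_,
                    "ref_item": self.ref_},
            loglik=self.loglik_, n_params=self.n_params_,
        )


def utilities_to_ranking(U) -> np.ndarray:
    """Rankings induced by utility rows: rank 1 = largest utility.

    Ties are broken by item index (stable), making predictions deterministic.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[None, :]
    n, k = U.shape
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.argsort(-U[i], kind="stable")
        out[i, order] = np.arange(1, k + 1)
    return out


def _mean_rank_pi0(table: RankingTable) -> np.ndarray:
    m = table.freq.astype(float) @ table.rankings / table.n
    order = np.argsort(m, kind="stable")
    pi0 = np.empty(table.k, dtype=np.int64)
    pi0[order] = np.arange(1, table.k + 1)
    return pi0


def _pi0_candidates(table: RankingTable, objective, exhaustive_limit: int = 6):
    """Maximize ``objective(pi0)`` over modal rankings.

    Exhaustive for k <= exhaustive_limit; otherwise greedy local search over
    the pairwise-swap neighborhood seeded at the mean-rank ordering.
    Returns (best pi0, best value, ties) where ties lists co-optimal pi0s.
    """
    k = table.k
    if k <= exhaustive_limit:
        perms = all_rankings(k)
        vals = np.array([objective(p) for p in perms])
        best = float(vals.max())
        ties = [perms[i].copy() for i in np.flatnonzero(np.isclose(vals, best, atol=1e-9))]
        return ties[0], best, ties
    cur = _mean_rank_pi0(table)
    cur_val = objective(cur)
    improved = True
    while improved:
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                cand = cur.copy()
                cand[i], cand[j] = cand[j], cand[i]
                val = objective(cand)
                if val > cur_val + 1e-12:
                    cur, cur_val, improved = cand, val, True
    return cur, float(cur_val), [cur]


class DistanceBasedModel(BaseEstimator):
    """Distance-based ranking model P(pi) = exp(-lam d(pi, pi0)) / C(lam).

    ``dtype`` selects the right-invariant distance ("tau" gives Mallows'
    phi-model).  The modal ranking is found by exhaustive search for
    k <= 6 and by pairwise-swap local search (seeded at the mean-rank
    ordering) above that; for fixed pi0 the dispersion is a concave 1-D
    problem solved by bounded scalar optimization.
    """

    def __init__(self, dtype="tau", enum_limit=8, lam_max=_LAM_MAX):
        self.dtype = dtype
        self.enum_limit = enum_limit
        self.lam_max = lam_max

    def fit(self, rankings, freq=None):
        table = _coerce_table(rankings, freq)
        _require_strict(table, "distance-based model")
        k = table.k
        if k > self.enum_limit:
            raise ValueError(
                f"k = {k} exceeds the enumeration limit {self.enum_limit}; "
                "raise enum_limit explicitly to fit anyway"
            )
        spec = DistanceSpec(self.dtype)
        d_all = distance_matrix(all_rankings(k), np.arange(1, k + 1), spec)
        f = table.freq.astype(float)
        N = table.n

        # profile loglik decreases with the total data distance, so the MLE
        # of pi0 minimizes sum_i N_i d(pi_i, pi0)
        def objective(pi0):
            return -float(f @ distance_matrix(table.rankings, pi0, spec))

        pi0, neg_sum_d, ties = _pi0_candidates(table, objective)
        sum_d = -neg_sum_d
        self.ties_ = ties
        if len(ties) > 1:
            warnings.warn(f"{len(ties)} modal rankings tie at the optimum",
                          UserWarning, stacklevel=2)

        def negll(lam):
            return lam * sum_d + N * logsumexp(-lam * d_all)

        res = optimize.minimize_scalar(negll, bounds=(0.0, self.lam_max),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        lam = float(res.x)
        self.boundary_ = bool(lam > 0.98 * self.lam_max)
        if self.boundary_:
            warnings.warn("dispersion at the optimization bound (data nearly "
                          "degenerate on a single ranking)", UserWarning, stacklevel=2)
        self.k_ = k
        self.pi0_ = np.asarray(pi0, dtype=np.int64)
        self.lambda_ = lam
        self.logC_ = float(logsumexp(-lam * d_all))
        self.loglik_ = -float(res.fun)
        self.n_params_ = 1
        self._d_all = d_all
        _attach_gof(self, table)
        return self

    def prob_table(self):
        perms = all_rankings(self.k_)
        d = distance_matrix(perms, self.pi0_, DistanceSpec(self.dtype))
        logp = -self.lambda_ * d - self.logC_
        return perms, np.exp(logp)

    def result(self) -> FitResult:
        return FitResult(
            family=f"dbm({self.dtype})",
            params={"lambda": self.lambda_, "logC": self.logC_},
            loglik=self.loglik_, n_params=self.n_params_, pi0=self.pi0_,
            gof_chi2=self.gof_chi2_, gof_df=self.gof_df_, boundary=self.boundary_,
        )


class PhiComponentModel(BaseEstimator):
    """Stagewise Mallows extension with one dispersion per Kendall stage.

    P(pi | Lambda, pi0) = exp(-sum_i lam_i V_i(pi, pi0)) / C(Lambda) with
    V_i the stage counts of the Kendall decomposition.  The normalizing
    constant factorizes over stages, so for fixed pi0 each lam_i is an
    independent 1-D problem.  Constraining lam_1 = ... = lam_{k-1}
    recovers Mallows' phi-model.
    """

    def __init__(self, enum_limit=8, lam_max=_LAM_MAX):
        self.enum_limit = enum_limit
        self.lam_max = lam_max

    def fit(self, rankings, freq=None):
        table = _coerce_table(rankings, freq)
        _require_strict(table, "phi-component model")
        k = table.k
        if k > self.enum_limit:
            raise ValueError(f"k = {k} exceeds the enumeration limit {self.enum_limit}")
        f = table.freq.astype(float)
        N = table.n
        R = table.rankings.astype(float)

        def stage_sums(pi0):
            V = np.stack([stage_counts(r, pi0) for r in R])
            return f @ V                                     # (k-1,)

        def profile(pi0, return_lams=False):
            S = stage_sums(pi0)
            lams = np.empty(k - 1)
            total = 0.0
            for i in range(k - 1):
                def negll_i(lam, S_i=S[i], stage=i + 1):
                    if lam < 1e-12:
                        logf = math.log(k - stage + 1)
                    else:
                        logf = (np.log(-np.expm1(-(k - stage + 1) * lam))
                                - np.log(-np.expm1(-lam)))
                    return lam * S_i + N * logf
                res = optimize.minimize_scalar(negll_i, bounds=(0.0, self.lam_max),
                                               method="bounded", options={"xatol": 1e-10})
                lams[i] = res.x
                total -= res.fun
            if return_lams:
                return total, lams
            return total

        pi0, ll, ties = _pi0_candidates(table, profile)
        self.ties_ = ties
        _, lams = profile(pi0, return_lams=True)
        self.boundary_ = bool(np.any(lams > 0.98 * self.lam_max))
        if self.boundary_:
            warnings.warn("a stage dispersion hit the optimization bound",
                          UserWarning, stacklevel=2)
        self.k_ = k
        self.pi0_ = np.asarray(pi0, dtype=np.int64)
        self.lambdas_ = lams
        self.logC_ = phi_log_C(k, lams)
        self.loglik_ = float(ll)
        self.n_params_ = k - 1
        _attach_gof(self, table)
        return self

    def prob_table(self):
        perms = all_rankings(self.k_)
        V = np.stack([stage_counts(p.astype(float), self.pi0_) for p in perms])
        logp = -(V @ self.lambdas_) - self.logC_
        return perms, np.exp(logp)

    def result(self) -> FitResult:
        return FitResult(
            family="phicom",
            params={"lambdas": self.lambdas_, "logC": self.logC_},
            loglik=self.loglik_, n_params=self.n_params_, pi0=self.pi0_,
            gof_chi2=self.gof_chi2_, gof_df=self.gof_df_, boundary=self.boundary_,
        )


class WeightedDistanceModel(BaseEstimator):
    """Weighted distance-based model P(pi | w, pi0) = exp(-d_w(pi, pi0)) / C(w).

    The nonnegative rank-position weights w absorb the dispersion scale, so
    there is no separate lambda.  A large w_i means judges strongly agree on
    which item belongs at rank i of the modal ranking; w_i near zero makes
    that position irrelevant to the fit.
    """

    def __init__(self, dtype="foot", enum_limit=8, w_max=_W_MAX):
        self.dtype = dtype
        self.enum_limit = enum_limit
        self.w_max = w_max

    def fit(self, rankings, freq=None):
        table = _coerce_table(rankings, freq)
        _require_strict(table, "weighted distance-based model")
        k = table.k
        if k > self.enum_limit:
            raise ValueError(f"k = {k} exceeds the enumeration limit {self.enum_limit}")
        f = table.freq.astype(float)
        N = table.n
        perms = all_rankings(k)
        identity = np.arange(1, k + 1)

        def fit_w(pi0):
            def negll(w):
                spec = DistanceSpec(self.dtype, weights=tuple(w))
                data = f @ distance_matrix(table.rankings, pi0, spec)
                logc = logsumexp(-distance_matrix(perms, identity, spec))
                return data + N * logc
            res = optimize.minimize(negll, np.ones(k), method="L-BFGS-B",
                                    bounds=[(0.0, self.w_max)] * k,
                                    options={"ftol": 1e-12, "gtol": 1e-10})
            return -float(res.fun), res.x

        def objective(pi0):
            return fit_w(pi0)[0]

        pi0, ll, ties = _pi0_candidates(table, objective)
        self.ties_ = ties
        _, w = fit_w(pi0)
        self.boundary_ = bool(np.any(w > 0.98 * self.w_max))
        self.k_ = k
        self.pi0_ = np.asarray(pi0, dtype=np.int64)
        self.weights_ = w
        spec = DistanceSpec(self.dtype, weights=tuple(w))
        self.logC_ = float(logsumexp(-distance_matrix(perms, identity, spec)))
        self.loglik_ = float(ll)
        self.n_params_ = k
        _attach_gof(self, table)
        return self

    def prob_table(self):
        perms = all_rankings(self.k_)
        spec = DistanceSpec(self.dtype, weights=tuple(self.weights_))
        logp = -distance_matrix(perms, self.pi0_, spec) - self.logC_
        return perms, np.exp(logp)

    def result(self) -> FitResult:
        return FitResult(
            family=f"wdbm({self.dtype})",
            params={"weights": self.weights_, "logC": self.logC_},
            loglik=self.loglik_, n_params=self.n_params_, pi0=self.pi0_,
            gof_chi2=self.gof_chi2_, gof_df=self.gof_df_, boundary=self.boundary_,
        )


# ---------------------------------------------------------------------------
# goodness of fit and model selection
# ---------------------------------------------------------------------------

def goodness_of_fit(table: RankingTable, model) -> tuple[float, int]:
    """Pearson-residual chi-square over the full permutation set.

    chi2 = sum_i (O_i - E_i)^2 / E_i with E_i = N P(pi_i) for all k!
    rankings (O_i = 0 where unobserved); df = k! - 1 - n_params.  ``model``
    is any fitted estimator exposing ``prob_table()`` and ``n_params_``, or
    the string "uniform".
    """
    table = _coerce_table(table, None)
    k = table.k
    perms = all_rankings(k)
    if model == "uniform":
        probs = np.full(len(perms), 1.0 / len(perms))
        n_params = 0
    else:
        mperms, probs = model.prob_table()
        if not np.array_equal(mperms, perms):
            raise ValueError("model enumerates a different permutation set")
        n_params = model.n_params_
    E = table.n * probs
    if np.any(E <= 0):
        raise ValueError("zero expected frequency: Pearson residuals undefined")
    index = {tuple(p): i for i, p in enumerate(perms)}
    O = np.zeros(len(perms))
    for row, fr in zip(table.rankings.astype(np.int64), table.freq):
        O[index[tuple(row)]] = fr
    chi2 = float(np.sum((O - E) ** 2 / E))
    return chi2, len(perms) - 1 - n_params


def select_model(fits: list) -> "FitResult":
    """Pick the fit with the largest log-likelihood from a list of fits.

    Accepts FitResult objects or fitted estimators (anything with a loglik).
    """
    if not fits:
        raise ValueError("no fits to select from")

    def ll(f):
        return f.loglik if isinstance(f, FitResult) else f.loglik_

    best = max(fits, key=ll)
    return best if isinstance(best, FitResult) else best.result()


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_luce(table, freq=None, **kw) -> FitResult:
    return LuceModel(**kw).fit(table, freq).result()


def fit_rol(rankings, covariates, **kw) -> FitResult:
    return RankOrderedLogit(**kw).fit(rankings, covariates).result()


def fit_dbm(table, freq=None, dtype="tau", **kw) -> FitResult:
    return DistanceBasedModel(dtype=dtype, **kw).fit(table, freq).result()


def fit_phicom(table, freq=None, **kw) -> FitResult:
    return PhiComponentModel(**kw).fit(table, freq).result()


def fit_wdbm(table, freq=None, dtype="foot", **kw) -> FitResult:
    return WeightedDistanceModel(dtype=dtype, **kw).fit(table, freq).result()
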
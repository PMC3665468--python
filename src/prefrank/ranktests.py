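"""Chi-square tests for ranking data.

Uniformity of a ranking dataset (all k! rankings equally likely) can be
tested directly on ranking proportions only when N is large relative to k!.
The practical route is to test summary statistics instead — the mean rank
vector, the pair matrix, or the marginal matrix — whose deviations from
their uniform expectations ((k+1)/2, N/2 and N/k respectively) follow
asymptotic chi-square laws with k-1, C(k,2) and (k-1)^2 degrees of freedom.

Two datasets are compared with a standard two-sample contingency chi-square
after flattening the chosen summary into a q-vector per dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rankcore import Descriptives, RankingTable, all_rankings, destat

__all__ = [
    "TestResult",
    "test_uniform_mean_rank",
    "test_uniform_pairs",
    "test_uniform_marginals",
    "test_uniform_rankings",
    "compare_datasets",
    "pairs_statistic_ginv",
]


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    basis: str

    def __str__(self):
        return (f"chi-square test ({self.basis}): statistic = {self.statistic:.6g}, "
                f"df = {self.df}, p = {self.p_value:.6g}")


def _result(stat: float, df: int, basis: str) -> TestResult:
    stat = float(max(stat, 0.0))
    return TestResult(stat, int(df), float(stats.chi2.sf(stat, df)), basis)


def _require_complete(table: RankingTable, what: str) -> None:
    if not table.is_complete:
        raise ValueError(f"{what} requires complete integer rankings (no imputed ties)")


def test_uniform_mean_rank(table: RankingTable) -> TestResult:
    """Friedman-type uniformity test on the mean rank vector; df = k-1."""
    k = table.k
    if k < 2:
        raise ValueError("need at least two items")
    _require_complete(table, "mean-rank uniformity test")
    N = table.n
    m = destat(table).mean_rank
    stat = 12.0 * N / (k * (k + 1)) * np.sum((m - (k + 1) / 2.0) ** 2)
    return _result(stat, k - 1, "mean_rank")


def test_uniform_pairs(table: RankingTable) -> TestResult:
    """Uniformity test on pairwise preference frequencies; df = C(k,2).

    Equals the generalized-inverse quadratic form of the pair-proportion
    deviations under the exact uniform covariance of pair indicators
    (see :func:`pairs_statistic_ginv`).
    """
    k = table.k
    if k < 2:
        raise ValueError("need at least two items")
    _require_complete(table, "pairs uniformity test")
    N = table.n
    d = destat(table)
    iu, ju = np.triu_indices(k, 1)
    pair_dev = d.pair[ju, iu] / N - 0.5          # s > t entries
    mean_dev = d.mean_rank - (k + 1) / 2.0
    stat = 12.0 * N * (np.sum(pair_dev**2) - np.sum(mean_dev**2) / (k + 1))
    return _result(stat, k * (k - 1) // 2, "pairs")


def test_uniform_marginals(table: RankingTable) -> TestResult:
    """Uniformity test on the marginal (item x rank) matrix; df = (k-1)^2."""
    k = table.k
    if k < 2:
        raise ValueError("need at least two items")
    _require_complete(table, "marginals uniformity test")
    N = table.n
    M = destat(table).marginal
    stat = N * (k - 1) * np.sum((M / N - 1.0 / k) ** 2)
    return _result(stat, (k - 1) ** 2, "marginals")


def test_uniform_rankings(table: RankingTable, min_expected: float = 5.0) -> TestResult:
    """Direct chi-square on ranking proportions against expected N/k! per cell.

    Refused when the expected count per ranking falls below ``min_expected``
    (the sparse-cell regime in which the summary-statistic tests exist).
    """
    k = table.k
    perms = all_rankings(k)
    expected = table.n / len(perms)
    if expected < min_expected:
        raise ValueError(
            f"expected count per ranking is {expected:.3g} < {min_expected}; "
            "use the mean_rank/pairs/marginals tests instead"
        )
    index = {tuple(p): i for i, p in enumerate(perms)}
    obs = np.zeros(len(perms))
    for row, f in zip(table.rankings.astype(np.int64), table.freq):
        obs[index[tuple(row)]] = f
    stat = np.sum((obs - expected) ** 2 / expected)
    return _result(stat, len(perms) - 1, "rankings")


def _summary_vector(table: RankingTable, basis: str) -> np.ndarray:
    d = destat(table)
    k = table.k
    if basis == "pairs":
        iu, ju = np.triu_indices(k, 1)
        return d.pair[ju, iu]
    if basis == "marginals":
        return d.marginal.ravel()
    if basis == "mean_rank":
        # rank-sum totals per item play the role of frequencies
        return d.mean_rank * d.n
    raise ValueError("basis must be one of {'pairs', 'marginals', 'mean_rank'}")


def compare_datasets(a: RankingTable, b: RankingTable, basis: str = "marginals",
                     zeros: str = "drop") -> TestResult:
    """Two-sample chi-square comparison of two ranking datasets.

    The chosen summary (flattened pair matrix, flattened marginal matrix, or
    item rank sums) forms a 2 x q contingency table; the standard chi-square
    statistic with df = q - 1 tests whether the two datasets share a common
    preference structure.  Columns that are zero in both datasets carry no
    information and are dropped with a warning (``zeros="drop"``) or pooled
    into a single column (``zeros="pool"``).
    """
    if a.k != b.k:
        raise ValueError(f"item counts differ: {a.k} vs {b.k}")
    if zeros not in ("drop", "pool"):
        raise ValueError("zeros must be 'drop' or 'pool'")
    va = _summary_vector(a, basis)
    vb = _summary_vector(b, basis)
    tab = np.vstack([va, vb])
    empty = tab.sum(axis=0) == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} zero-frequency column(s) in the 2 x q table "
            f"({'dropped' if zeros == 'drop' else 'pooled'})",
            UserWarning, stacklevel=2,
        )
        if zeros == "drop":
            tab = tab[:, ~empty]
        else:
            tab = np.hstack([tab[:, ~empty], tab[:, empty].sum(axis=1, keepdims=True)])
    if np.allclose(va, vb):
        return _result(0.0, tab.shape[1] - 1, basis)
    stat, _, df, _ = stats.chi2_contingency(tab, correction=False)
    return _result(stat, df, basis)


def pairs_statistic_ginv(table: RankingTable) -> float:
    """Independent oracle for the pairs uniformity statistic.

    Builds the exact covariance of the C(k,2) pair indicators
    I[pi(s) > pi(t)] under a uniform random ranking by enumerating S_k, and
    evaluates N * d' Sigma^+ d on the observed pair-proportion deviations d.
    Enumeration-based: intended for k <= 5 test fixtures.
    """
    k = table.k
    N = table.n
    perms = all_rankings(k).astype(float)
    iu, ju = np.triu_indices(k, 1)
    ind = (perms[:, ju] > perms[:, iu]).astype(float)   # I[pi(s) > pi(t)], s > t
    mu = ind.mean(axis=0)
    sigma = (ind - mu).T @ (ind - mu) / len(perms)
    d = destat(table).pair[ju, iu] / N - mu
    return float(N * d @ np.linalg.pinv(sigma, rcond=1e-10) @ d)
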
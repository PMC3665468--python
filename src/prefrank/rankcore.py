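"""Core data structures for ranking data.

A *ranking* of k items is a length-k vector ``pi`` whose i-th entry is the
rank given to item i (1 = most preferred).  The inverse view, an *ordering*,
lists the items by rank position: ``ordering[j]`` is the item holding rank
j+1.  Datasets are held either as an N x k matrix of individual rankings
(one row per judge) or aggregated into a :class:`RankingTable` of distinct
rankings with frequencies.

Item labels are 1-based in all user-facing I/O; arrays returned by this
module contain rank *values* 1..k and item *labels* 1..k.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "RankingTable",
    "Descriptives",
    "rank_agg",
    "ranking_to_ordering",
    "ordering_to_ranking",
    "impute_partial",
    "destat",
    "all_rankings",
    "is_permutation",
]


@lru_cache(maxsize=None)
def _all_perms(k: int) -> np.ndarray:
    if k > 8:
        raise ValueError(
            f"enumeration of S_{k} ({math.factorial(k)} permutations) exceeds "
            "the k <= 8 limit; pass a smaller k or enumerate explicitly"
        )
    return np.array(list(itertools.permutations(range(1, k + 1))), dtype=np.int64)


def all_rankings(k: int) -> np.ndarray:
    """All k! rankings of k items, one per row, in lexicographic order.

    A row read as a ranking covers S_k exactly once, so the same array also
    enumerates all orderings.  Cached; limited to k <= 8.
    """
    return _all_perms(k).copy()


def is_permutation(row: np.ndarray) -> bool:
    """True if ``row`` is a permutation of 1..k (a complete untied ranking)."""
    row = np.asarray(row)
    k = row.shape[-1]
    return bool(
        np.issubdtype(np.asarray(row).dtype, np.number)
        and np.array_equal(np.sort(row), np.arange(1, k + 1))
    )


def _as_2d(rankings) -> np.ndarray:
    arr = np.asarray(rankings, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("rankings must be a 2D (N x k) array")
    return arr


@dataclass
class RankingTable:
    """Aggregated ranking data: distinct rankings with observed frequencies.

    Parameters
    ----------
    rankings : (R, k) array
        Distinct rankings, one per row; entry (i, j) is the rank that
        ranking i assigns to item j+1.  Integer permutations for complete
        data; mean-rank-imputed rows may carry tied fractional ranks.
    freq : (R,) array of positive ints
        Number of judges observed with each ranking.
    """

    rankings: np.ndarray
    freq: np.ndarray
    allow_ties: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.rankings = _as_2d(self.rankings)
        self.freq = np.asarray(self.freq, dtype=np.int64)
        if self.freq.ndim != 1 or len(self.freq) != len(self.rankings):
            raise ValueError("freq must be 1D with one entry per ranking row")
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be nonnegative")
        keep = self.freq > 0
        if not keep.all():
            self.rankings = self.rankings[keep]
            self.freq = self.freq[keep]
        if len(self.rankings) == 0:
            raise ValueError("no rankings")
        _validate_rows(self.rankings, allow_ties=self.allow_ties)
        if len({tuple(r) for r in self.rankings}) != len(self.rankings):
            raise ValueError("ranking rows must be pairwise distinct")
        if self.is_complete and np.allclose(self.rankings, np.round(self.rankings)):
            self.rankings = self.rankings.astype(np.int64).astype(float)

    @property
    def k(self) -> int:
        return self.rankings.shape[1]

    @property
    def n_distinct(self) -> int:
        return self.rankings.shape[0]

    @property
    def n(self) -> int:
        """Total number of judges aggregated."""
        return int(self.freq.sum())

    @property
    def is_complete(self) -> bool:
        """True if every row is an untied integer permutation of 1..k."""
        srt = np.sort(self.rankings, axis=1)
        return bool(np.array_equal(srt, np.tile(np.arange(1, self.k + 1), (len(srt), 1))))

    def expand(self) -> np.ndarray:
        """Individual-format (N x k) matrix with each ranking repeated freq times."""
        return np.repeat(self.rankings, self.freq, axis=0)

    @classmethod
    def from_individual(cls, rankings, allow_ties: bool = False) -> "RankingTable":
        return rank_agg(rankings, allow_ties=allow_ties)


def _validate_rows(arr: np.ndarray, allow_ties: bool) -> None:
    k = arr.shape[1]
    if not np.isfinite(arr).all():
        raise ValueError("rankings contain non-finite entries")
    if np.any(arr <= 0):
        raise ValueError("ranks must be positive")
    target = k * (k + 1) / 2.0
    for idx, row in enumerate(arr):
        if is_permutation(row):
            continue
        if allow_ties and np.isclose(row.sum(), target):
            continue
        raise ValueError(
            f"row {idx} is not a permutation of 1..{k}: {row.tolist()}"
            + ("" if allow_ties else " (pass allow_ties=True for imputed tied rankings)")
        )


def rank_agg(rankings, allow_ties: bool = False) -> RankingTable:
    """Aggregate an N x k individual ranking matrix into a :class:`RankingTable`.

    Rows are validated (permutations of 1..k, or tie-imputed rows summing to
    k(k+1)/2 when ``allow_ties``), deduplicated and counted; output rows are
    sorted lexicographically so the result is deterministic.
    """
    arr = _as_2d(rankings)
    if arr.size == 0:
        raise ValueError("no rankings")
    _validate_rows(arr, allow_ties=allow_ties)
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return RankingTable(uniq, counts, allow_ties=allow_ties)


def ranking_to_ordering(ranks) -> np.ndarray:
    """Invert a complete ranking: entry j of the result is the item with rank j+1.

    ``ranks (2,3,1) -> items (3,1,2)``: item 3 holds rank 1, item 1 rank 2.
    """
    r = np.asarray(ranks)
    if r.ndim == 2:
        return np.stack([ranking_to_ordering(row) for row in r])
    if not is_permutation(r):
        raise ValueError("ordering undefined for ties or incomplete rankings")
    k = len(r)
    items = np.empty(k, dtype=np.int64)
    items[np.asarray(r, dtype=np.int64) - 1] = np.arange(1, k + 1)
    return items


def ordering_to_ranking(items) -> np.ndarray:
    """Inverse of :func:`ranking_to_ordering` (the same array inversion)."""
    return ranking_to_ordering(items)


def impute_partial(partial) -> np.ndarray:
    """Complete a partial ranking by mean-rank imputation.

    The assigned ranks must form the prefix 1..t (each used once); every
    unranked item receives the mean of the unused ranks {t+1, ..., k}, so the
    result sums to k(k+1)/2.  NaN (or None) marks missing entries.
    """
    arr = np.array([np.nan if v is None else v for v in np.asarray(partial, dtype=object)],
                   dtype=float)
    k = len(arr)
    missing = np.isnan(arr)
    if not missing.any():
        return arr
    assigned = np.sort(arr[~missing])
    t = len(assigned)
    if not np.array_equal(assigned, np.arange(1, t + 1)):
        raise ValueError(
            f"assigned ranks must form the prefix 1..{t}, got {assigned.tolist()}"
        )
    mean_rest = (t + 1 + k) / 2.0
    out = arr.copy()
    out[missing] = mean_rest
    return out


@dataclass
class Descriptives:
    """Mean rank vector, pair matrix and marginal matrix of a ranking table.

    ``mean_rank[j]`` is the average rank of item j+1.  ``pair[s, t]`` counts
    judges for whom item s+1 has a larger rank number than item t+1 (with
    ``direction="greater"``, the literal indicator I[pi(s) > pi(t)]); hence
    pair[s, t] + pair[t, s] = N.  ``marginal[s, t]`` counts judges ranking
    item s+1 in position t+1; every row and column sums to N.
    """

    mean_rank: np.ndarray
    pair: np.ndarray | None
    marginal: np.ndarray | None
    n: int

    @property
    def k(self) -> int:
        return len(self.mean_rank)


def destat(table: RankingTable, direction: str = "greater") -> Descriptives:
    """Descriptive statistics of an aggregated ranking dataset.

    Parameters
    ----------
    table : RankingTable
    direction : {"greater", "preferred"}
        "greater" counts pair[s, t] when rank(s) > rank(t) (larger rank
        number, i.e. s *less* preferred than t); "preferred" counts the
        opposite, pair[s, t] when s is preferred over t.

    Pair and marginal matrices require complete integer rankings; for
    tie-imputed tables they are omitted (None) with a warning and only the
    mean rank is returned.
    """
    if direction not in ("greater", "preferred"):
        raise ValueError("direction must be 'greater' or 'preferred'")
    R, k = table.rankings.shape
    N = table.n
    w = table.freq.astype(float)
    mean_rank = w @ table.rankings / N

    if not table.is_complete:
        warnings.warn(
            "pair and marginal matrices require complete integer rankings; "
            "returning mean rank only", UserWarning, stacklevel=2,
        )
        return Descriptives(mean_rank, None, None, N)

    ranks = table.rankings
    gt = ranks[:, :, None] > ranks[:, None, :]          # (R, k, k)
    pair = np.einsum("r,rst->st", w, gt)
    if direction == "preferred":
        pair = pair.T.copy()
    # marginal[s, t] = sum of freq over rankings with rank(item s+1) == t+1
    marginal = np.zeros((k, k))
    ints = ranks.astype(np.int64)
    for r in range(R):
        marginal[np.arange(k), ints[r] - 1] += w[r]
    return Descriptives(mean_rank, pair, marginal, N)
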
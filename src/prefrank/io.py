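"""CSV input/output for ranking datasets, covariates and comparison matrices.

Two ranking layouts are supported:

* **individual** — a header row of item names and one row of integer ranks
  per judge;
* **aggregated** — the same k item columns plus a final column named ``n``
  holding the frequency of each distinct ranking.

All files are 1-based in both ranks and item labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rankcore import RankingTable, rank_agg

__all__ = ["read_rankings", "write_rankings", "read_covariates", "read_matrix"]


def _validate_frame(df: pd.DataFrame, path) -> None:
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no rankings")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        for i, row in df.iterrows():
            vals = pd.to_numeric(row, errors="coerce")
            if vals.isna().any():
                cols = list(row.index[vals.isna()])
                raise ValueError(
                    f"{path}: non-numeric value in row {i + 1}, column(s) {cols}: "
                    f"{[row[c] for c in cols]}"
                )


def read_rankings(path, mode: str = "individual", allow_ties: bool = False):
    """Read a ranking CSV.

    Returns an N x k integer matrix in "individual" mode and a
    :class:`RankingTable` in "aggregated" mode (requires the trailing
    ``n`` frequency column).  Malformed rows are reported by index.
    """
    if mode not in ("individual", "aggregated"):
        raise ValueError("mode must be 'individual' or 'aggregated'")
    df = pd.read_csv(path)
    if mode == "aggregated":
        if df.columns[-1].strip().lower() != "n":
            raise ValueError(f"{path}: aggregated format needs a final 'n' frequency column")
        _validate_frame(df, path)
        freq = df.iloc[:, -1].to_numpy()
        if not np.allclose(freq, np.round(freq)) or np.any(freq < 0):
            raise ValueError(f"{path}: frequencies must be nonnegative integers")
        try:
            return RankingTable(df.iloc[:, :-1].to_numpy(dtype=float),
                                freq.astype(np.int64), allow_ties=allow_ties)
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from e
    _validate_frame(df, path)
    arr = df.to_numpy(dtype=float)
    try:
        rank_agg(arr, allow_ties=allow_ties)   # row-level validation
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e
    if np.allclose(arr, np.round(arr)):
        arr = arr.astype(np.int64)
    return arr


def write_rankings(data, path, item_names=None) -> None:
    """Write rankings to CSV: a matrix in individual layout, a
    :class:`RankingTable` in aggregated layout (with the ``n`` column)."""
    if isinstance(data, RankingTable):
        k = data.k
        names = item_names or [f"item{j + 1}" for j in range(k)]
        df = pd.DataFrame(data.rankings, columns=names)
        if data.is_complete:
            df = df.astype(int)
        df["n"] = data.freq
    else:
        arr = np.asarray(data)
        names = item_names or [f"item{j + 1}" for j in range(arr.shape[1])]
        df = pd.DataFrame(arr, columns=names)
        if np.allclose(arr, np.round(arr)):
            df = df.astype(int)
    df.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Judge covariate table: header row, one numeric row per judge."""
    df = pd.read_csv(path)
    _validate_frame(df, path)
    return df.astype(float)


def read_matrix(path) -> np.ndarray:
    """Square pairwise comparison matrix, with or without a header row."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not pd.to_numeric(first.iloc[0], errors="coerce").notna().all()
    df = pd.read_csv(path, header=0 if has_header else None)
    _validate_frame(df, path)
    a = df.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{path}: matrix must be square, got {a.shape}")
    return a
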
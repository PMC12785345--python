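"""Kennard-Stone sample selection and the two deterministic split schemes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


def kennard_stone(X, k: int) -> np.ndarray:
    """Ordered maximin selection of ``k`` rows of ``X``.

    The first two picks are the mutually farthest pair; each later pick
    maximizes its minimum Euclidean distance to the picks so far.  Ties
    break to the lowest index, so the result is deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    D = cdist(X, X)
    if D.max() == 0:
        raise ValueError("all points identical: Kennard-Stone is degenerate")
    # argmax over the flattened matrix returns the first (lowest i, then j)
    # occurrence of the maximum.
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(i), int(j)]
    min_dist = np.minimum(D[i], D[j])
    for _ in range(k - 2):
        min_dist[selected] = -1.0
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(selected)


@dataclass(frozen=True)
class SplitResult:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        parts = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(parts)) != parts.size:
            raise ValueError("split subsets overlap")

    @property
    def n_samples(self) -> int:
        return self.train_idx.size + self.val_idx.size + self.test_idx.size


def _round(x: float) -> int:
    return int(np.floor(x + 0.5))


def _split_indices(X: np.ndarray, idx: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    """Successive Kennard-Stone selections; the residue is the last part."""
    remaining = idx
    parts = []
    for size in sizes:
        chosen = remaining[kennard_stone(X[remaining], size)]
        parts.append(np.sort(chosen))
        remaining = np.setdiff1d(remaining, chosen)
    parts.append(np.sort(remaining))
    return parts


def split_622(X, strata=None) -> SplitResult:
    """60/20/20 train/validation/test split by repeated Kennard-Stone.

    With ``strata`` (e.g. a genuine/adulterated flag) the selection runs
    independently inside each stratum so that every subset contains all
    strata.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("6:2:2 split needs at least 5 samples")
    groups = ([np.arange(n)] if strata is None else
              [np.flatnonzero(np.asarray(strata) == s)
               for s in np.unique(np.asarray(strata))])
    train, val, test = [], [], []
    for idx in groups:
        m = idx.size
        tr, va, te = _split_indices(X, idx, [_round(0.6 * m), _round(0.2 * m)])
        train.append(tr)
        val.append(va)
        test.append(te)
    return SplitResult(np.sort(np.concatenate(train)),
                       np.sort(np.concatenate(val)),
                       np.sort(np.concatenate(test)), "6:2:2")


def split_73(X) -> SplitResult:
    """70/30 calibration/prediction split by Kennard-Stone."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("7:3 split needs at least 5 samples")
    cal, pred = _split_indices(X, np.arange(n), [_round(0.7 * n)])
    return SplitResult(cal, np.array([], dtype=int), pred, "7:3")
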
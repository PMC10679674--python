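"""SPXY sample-set partitioning.

Splits samples into calibration (train) and prediction (test) folds by
joint predictor-response distance coverage: pairwise Euclidean
distances on the spectra and absolute differences on the response are
each normalized by their maximum and summed; the training fold is grown
greedily so that it spans that joint space (Galvao's SPXY, a Y-aware
Kennard-Stone).  Deterministic: ties are broken by the smallest sample
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class SplitIndices:
    train_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test folds overlap")


def spxy_split(X: np.ndarray, y: np.ndarray, train_fraction: float = 0.7) -> SplitIndices:
    """Partition samples with the SPXY max-min procedure.

    The two mutually farthest samples (joint distance) seed the training
    fold; samples are then added one at a time, each the candidate whose
    minimum joint distance to the current training fold is largest,
    until ``floor(train_fraction * n)`` members are reached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.std(ddof=1) == 0:
        raise ValueError("response has zero spread")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")

    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    if dx.max() == 0:
        raise ValueError("all spectra identical: SPXY distance degenerate")
    d = dx / dx.max() + dy / (dy.max() if dy.max() > 0 else 1.0)

    n_train = int(np.floor(train_fraction * n))
    # seed with the mutually farthest pair (smallest indices on ties)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    train = [min(i, j), max(i, j)]
    in_train = np.zeros(n, dtype=bool)
    in_train[train] = True
    dmin = np.minimum(d[train[0]], d[train[1]])
    dmin[in_train] = -np.inf
    while len(train) < n_train:
        best = np.flatnonzero(dmin == dmin.max()).min()  # smallest id on ties
        train.append(int(best))
        in_train[best] = True
        dmin = np.minimum(dmin, d[best])
        dmin[in_train] = -np.inf
    train_ids = np.array(sorted(train))
    test_ids = np.setdiff1d(np.arange(n), train_ids)
    return SplitIndices(train_ids=train_ids, test_ids=test_ids)
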
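"""Dynamic time warping between windowed feature sequences.

Classic unconstrained DTW: Euclidean local cost between per-window feature
vectors, boundary-anchored dynamic programming with steps {(1,0), (0,1),
(1,1)} and no global band.  The inner recursion is JIT-compiled with numba;
the first call pays a one-off compilation cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .features import FeatureSequence

__all__ = ["dtw_distance"]


@njit(cache=True)
def _dtw_dp(cost: np.ndarray) -> float:
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost[i, j] + best
    return acc[n - 1, m - 1]


def _as_matrix(seq) -> np.ndarray:
    if isinstance(seq, FeatureSequence):
        seq = seq.values
    a = np.asarray(seq, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def dtw_distance(a, b) -> float:
    """Optimal cumulative alignment cost between two feature sequences.

    Accepts :class:`FeatureSequence` objects or plain (n_windows, dims)
    arrays; both must be nonempty with matching feature dimensionality.
    """
    A, B = _as_matrix(a), _as_matrix(b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("sequences must be nonempty")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    # pairwise Euclidean local cost
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    cost = np.sqrt(np.maximum(d2, 0.0))
    return float(_dtw_dp(cost))
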
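"""Independent oracles for the test suite.

The warping-path oracle never uses the package's DP code: it enumerates
every admissible monotone path from (0, 0) to (m-1, n-1) explicitly and
minimises the summed pointwise distances over them.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def enumerate_paths(m: int, n: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All monotone warping paths (steps (1,0), (0,1), (1,1)) through an
    m x n grid, endpoints fixed at the corners."""
    if m == 1 and n == 1:
        return (((0, 0),),)
    paths = []
    if m > 1:
        for p in enumerate_paths(m - 1, n):
            paths.append(p + ((m - 1, n - 1),))
    if n > 1:
        for p in enumerate_paths(m, n - 1):
            paths.append(p + ((m - 1, n - 1),))
    if m > 1 and n > 1:
        for p in enumerate_paths(m - 1, n - 1):
            paths.append(p + ((m - 1, n - 1),))
    return tuple(paths)


def path_incidence(m: int, n: int) -> np.ndarray:
    """0/1 matrix (n_paths x m*n): which cells each warping path visits."""
    paths = enumerate_paths(m, n)
    P = np.zeros((len(paths), m * n))
    for r, p in enumerate(paths):
        for i, j in p:
            P[r, i * n + j] = 1.0
    return P


def brute_force_dtw(x: np.ndarray, y: np.ndarray) -> float:
    """Scalar DTW distance by exhaustive path enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    D = np.abs(x[:, None] - y[None, :])
    best = np.inf
    for p in enumerate_paths(len(x), len(y)):
        cost = sum(D[i, j] for i, j in p)
        best = min(best, cost)
    return best


def batched_brute_force(
    X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Oracle distances for all pairs of rows of X (N_x x m) and Y (N_y x n).

    Vectorised: pointwise-distance tensors are multiplied against the path
    incidence matrix and minimised over paths. Returns (N_x, N_y).
    """
    m, n = X.shape[1], Y.shape[1]
    P = path_incidence(m, n)  # (n_paths, m*n)
    D = np.abs(X[:, None, :, None] - Y[None, :, None, :])  # (Nx, Ny, m, n)
    flat = D.reshape(X.shape[0] * Y.shape[0], m * n)
    sums = flat @ P.T
    return sums.min(axis=1).reshape(X.shape[0], Y.shape[0])


def batched_dp(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Textbook DP evaluated with numpy over all row pairs (re-implemented
    here so acceptance can cross-check the package kernel at scale)."""
    m, n = X.shape[1], Y.shape[1]
    D = np.abs(X[:, None, :, None] - Y[None, :, None, :]).reshape(-1, m, n)
    C = np.empty_like(D)
    C[:, 0, 0] = D[:, 0, 0]
    for i in range(1, m):
        C[:, i, 0] = D[:, i, 0] + C[:, i - 1, 0]
    for j in range(1, n):
        C[:, 0, j] = D[:, 0, j] + C[:, 0, j - 1]
    for i in range(1, m):
        for j in range(1, n):
            C[:, i, j] = D[:, i, j] + np.minimum(
                np.minimum(C[:, i - 1, j], C[:, i, j - 1]), C[:, i - 1, j - 1]
            )
    return C[:, -1, -1].reshape(X.shape[0], Y.shape[0])


def all_sequences(max_len: int, values: tuple[int, ...] = (0, 1, 2)):
    """All sequences over ``values`` grouped by length: {length: array}."""
    out = {}
    for L in range(1, max_len + 1):
        grids = np.meshgrid(*([np.array(values)] * L), indexing="ij")
        out[L] = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    return out


def macro_f1_from_confusion(cm: np.ndarray) -> float:
    """Macro F1 by definition from a confusion matrix (rows = true)."""
    f1s = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return float(np.mean(f1s))
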
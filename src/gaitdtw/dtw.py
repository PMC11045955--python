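"""Dynamic time warping core.

Implements the classic DP: a pointwise distance matrix ``D`` (single-point
Euclidean distance between samples), the cumulative matrix ``C`` with
``C[i,j] = D[i,j] + min(C[i-1,j], C[i,j-1], C[i-1,j-1])`` and cumulative-sum
boundaries, and backtracking of the optimal warping path. The multichannel
extension ("dependent" strategy) warps vector-valued samples along one shared
path; the "independent" strategy warps each channel separately and sums the
per-channel distances.

The DTW distance is the raw cumulative cost ``C[m-1, n-1]`` (no path-length
normalisation): templates compared against a query all have equal status, so
normalisation would not change the argmin.

Hot loops are numba-compiled; a module-level distance entry point that skips
matrix materialisation (:func:`dtw_distance_only`) is used by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ParameterError


@dataclass
class DtwResult:
    """Distance, cumulative cost matrix and optimal warping path.

    ``path`` is 0-based, starts at (0, 0) and ends at (m-1, n-1), with steps
    in {(1,0), (0,1), (1,1)}. For the independent multichannel strategy the
    per-channel paths are in ``channel_paths`` and ``path``/``cumulative``
    are those of the first channel.
    """

    distance: float
    cumulative: np.ndarray | None = None
    path: list[tuple[int, int]] | None = None
    channel_paths: list[list[tuple[int, int]]] | None = None


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2:
        raise ParameterError("sequences must be 1-D or (channels x samples) 2-D")
    if x.shape[1] < 1:
        raise ParameterError("sequences must have at least one sample")
    if np.isnan(x).any():
        raise ParameterError("sequences must not contain NaN")
    return x


def distance_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pointwise distance matrix D[i, j] = ||x_i - y_j|| over channels.

    For 1-channel input this is the absolute difference.
    """
    x, y = _as_2d(x), _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ParameterError(
            f"channel count mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    diff = x[:, :, np.newaxis] - y[:, np.newaxis, :]
    return np.sqrt(np.einsum("dij,dij->ij", diff, diff))


@njit(cache=False)
def _cumulative(D: np.ndarray) -> np.ndarray:
    m, n = D.shape
    C = np.empty((m, n))
    C[0, 0] = D[0, 0]
    for i in range(1, m):
        C[i, 0] = D[i, 0] + C[i - 1, 0]
    for j in range(1, n):
        C[0, j] = D[0, j] + C[0, j - 1]
    for i in range(1, m):
        for j in range(1, n):
            c = C[i - 1, j - 1]
            if C[i - 1, j] < c:
                c = C[i - 1, j]
            if C[i, j - 1] < c:
                c = C[i, j - 1]
            C[i, j] = D[i, j] + c
    return C


@njit(cache=False)
def _distance_dep(x: np.ndarray, y: np.ndarray) -> float:
    """Dependent mDTW distance without materialising D or C (row-rolling DP)."""
    d, m = x.shape
    n = y.shape[1]
    prev = np.empty(n)
    cur = np.empty(n)
    for j in range(n):
        s = 0.0
        for c in range(d):
            diff = x[c, 0] - y[c, j]
            s += diff * diff
        dist = np.sqrt(s)
        prev[j] = dist if j == 0 else dist + prev[j - 1]
    for i in range(1, m):
        for j in range(n):
            s = 0.0
            for c in range(d):
                diff = x[c, i] - y[c, j]
                s += diff * diff
            dist = np.sqrt(s)
            if j == 0:
                cur[0] = dist + prev[0]
            else:
                best = prev[j - 1]
                if prev[j] < best:
                    best = prev[j]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                cur[j] = dist + best
        prev, cur = cur, prev
    return prev[n - 1]


def cumulative_matrix(D: np.ndarray) -> np.ndarray:
    """Cumulative cost matrix from a nonnegative pointwise distance matrix."""
    D = np.ascontiguousarray(D, dtype=float)
    if D.ndim != 2:
        raise ParameterError("distance matrix must be 2-D")
    if (D < 0).any():
        raise ParameterError("distance matrix must be nonnegative")
    return _cumulative(D)


def backtrack(C: np.ndarray) -> list[tuple[int, int]]:
    """Optimal warping path from a cumulative matrix, (0,0) .. (m-1,n-1).

    Ties between predecessors are broken diagonal-first, then vertical, then
    horizontal (deterministic, favours short paths).
    """
    C = np.asarray(C, dtype=float)
    m, n = C.shape
    i, j = m - 1, n - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = C[i - 1, j - 1], C[i - 1, j], C[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def dtw(x: np.ndarray, y: np.ndarray) -> DtwResult:
    """Full scalar/vector DTW with matrices and path (dependent alignment)."""
    D = distance_matrix(x, y)
    C = cumulative_matrix(D)
    path = backtrack(C)
    return DtwResult(distance=float(C[-1, -1]), cumulative=C, path=path)


def mdtw_distance(
    x: np.ndarray, y: np.ndarray, strategy: str = "dependent"
) -> DtwResult:
    """Multidimensional DTW between channels x samples sequences.

    dependent
        one warping path over vector-valued samples with Euclidean pointwise
        cost (the default: all channels constrain the same alignment).
    independent
        scalar DTW per channel; distances summed, paths reported per channel.

    Both reduce exactly to scalar DTW for 1-channel input.
    """
    x, y = _as_2d(x), _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ParameterError(
            f"channel count mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    if strategy == "dependent":
        return dtw(x, y)
    if strategy == "independent":
        total = 0.0
        paths: list[list[tuple[int, int]]] = []
        first: DtwResult | None = None
        for c in range(x.shape[0]):
            r = dtw(x[c], y[c])
            total += r.distance
            paths.append(r.path)
            if first is None:
                first = r
        return DtwResult(
            distance=total,
            cumulative=first.cumulative,
            path=first.path,
            channel_paths=paths,
        )
    raise ParameterError(f"unknown mDTW strategy {strategy!r}")


def dtw_distance_only(x: np.ndarray, y: np.ndarray, strategy: str = "dependent") -> float:
    """Distance-only fast path (no matrices kept); used in classification."""
    x, y = _as_2d(x), _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ParameterError(
            f"channel count mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    x = np.ascontiguousarray(x)
    y = np.ascontiguousarray(y)
    if strategy == "dependent":
        return float(_distance_dep(x, y))
    if strategy == "independent":
        return float(
            sum(_distance_dep(x[c : c + 1], y[c : c + 1]) for c in range(x.shape[0]))
        )
    raise ParameterError(f"unknown mDTW strategy {strategy!r}")
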
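"""Dynamic time warping of parallel acoustic feature sequences.

Parallel utterances (same sentence, different speakers) differ in timing;
voice-conversion training needs frame-paired sequences.  DTW finds the
monotone alignment path minimising the summed Euclidean frame distance
under the step set {(1,0), (0,1), (1,1)}, and the source sequence is then
warped onto the target's time base by averaging the source frames aligned
to each target frame.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _dtw_table(dist: np.ndarray) -> np.ndarray:
    n, m = dist.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = dist[i - 1, j - 1] + best
    return acc


def dtw_align(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal alignment path and total cost between two (T, D) sequences.

    Returns ``(path, cost)`` where ``path`` is an (L, 2) integer array of
    (source, target) frame indices starting at (0, 0) and ending at
    (T_s − 1, T_t − 1), monotone with steps in {(1,0),(0,1),(1,1)}.
    """
    source = np.atleast_2d(np.asarray(source, dtype=np.float64))
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if source.shape[0] == 0 or target.shape[0] == 0:
        raise ValueError("cannot align empty sequences")
    if source.shape[1] != target.shape[1]:
        raise ValueError("sequences must share the feature dimension")
    dist = cdist(source, target, metric="euclidean")
    acc = _dtw_table(dist)
    # backtrack
    i, j = dist.shape
    path = [(i - 1, j - 1)]
    while i > 1 or j > 1:
        moves = []
        if i > 1 and j > 1:
            moves.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 1:
            moves.append((acc[i - 1, j], i - 1, j))
        if j > 1:
            moves.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(moves)
        path.append((i - 1, j - 1))
    path.reverse()
    return np.asarray(path, dtype=np.intp), float(acc[-1, -1])


def warp_to_target(source: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Warp source frames onto the target time base of an alignment path.

    Each output frame j is the mean of the source frames aligned to j; the
    output has as many frames as the path's target side covers.
    """
    source = np.atleast_2d(np.asarray(source, dtype=np.float64))
    path = np.asarray(path)
    if path.ndim != 2 or path.shape[1] != 2:
        raise ValueError("path must be (L, 2)")
    if path[:, 0].max() >= source.shape[0]:
        raise ValueError("path indexes beyond the source sequence")
    n_target = int(path[:, 1].max()) + 1
    out = np.zeros((n_target, source.shape[1]))
    counts = np.zeros(n_target)
    np.add.at(out, path[:, 1], source[path[:, 0]])
    np.add.at(counts, path[:, 1], 1.0)
    if np.any(counts == 0):
        raise ValueError("path does not cover every target frame")
    return out / counts[:, None]


def dtw_cost_bruteforce(source: np.ndarray, target: np.ndarray) -> float:
    """Minimum alignment cost by exhaustive path enumeration (oracle, T ≤ ~6)."""
    source = np.atleast_2d(np.asarray(source, dtype=np.float64))
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    dist = cdist(source, target, metric="euclidean")
    n, m = dist.shape
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += dist[i, j]
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return float(best[0])
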
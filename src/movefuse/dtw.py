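"""Dynamic time warping for vectors, matrices, and cuboids.

A warping path ``W = {w(1)..w(K)}``, ``w(k) = (i(k), j(k))``, aligns two
sequences subject to endpoint (``w(1) = (1,1)``, ``w(K) = (n_X, n_Y)``),
monotonicity, and continuity constraints; the allowed moves are
``(1,0), (0,1), (1,1)`` with unit weights.  The discrepancy between two
sequences is the path-length-normalized total local cost
``A_XY = (1/K) * sum_k d[w(k)]`` of the optimal alignment.

The same dynamic program covers all three input ranks: the local cost is
the distance between scalars (vectors), between columns (matrices with
equal row counts), or between depth-frames (cuboids with equal rows and
depth).  Frame-wise Euclidean cost on a cuboid equals column-wise cost on
the matrix obtained by stacking its depth-frames, so cuboid alignment is
implemented as matrix alignment of the stacked form.

Objective note: the dynamic program minimizes the path *sum* and then
normalizes by the realized path length ``K``; among minimal-sum paths the
shortest (then lexicographically smallest) path is reported.  Minimizing
the normalized cost directly is a different (non-Markovian) objective;
:func:`brute_force_align` can evaluate both on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = [
    "METRICS",
    "WarpingPath",
    "Discrepancy",
    "local_cost",
    "cost_matrix",
    "dtw_align",
    "dtw_value",
    "brute_force_align",
    "cuboid_as_matrix",
]

METRICS = ("euclidean", "manhattan", "sq_euclidean")
_CDIST_NAME = {"euclidean": "euclidean", "manhattan": "cityblock",
               "sq_euclidean": "sqeuclidean"}


@dataclass(frozen=True)
class WarpingPath:
    """An admissible alignment: ``steps[k] = (i, j)`` (0-based) and the
    per-step local costs."""

    steps: np.ndarray      # (K, 2) int
    costs: np.ndarray      # (K,) float

    @property
    def K(self) -> int:
        return self.steps.shape[0]

    def is_admissible(self, n_x: int, n_y: int) -> bool:
        s = self.steps
        if tuple(s[0]) != (0, 0) or tuple(s[-1]) != (n_x - 1, n_y - 1):
            return False
        d = np.diff(s, axis=0)
        return bool(np.all(d >= 0) and np.all(d <= 1) and np.all(d.sum(axis=1) >= 1))


@dataclass(frozen=True)
class Discrepancy:
    """Normalized optimal-alignment cost ``A_XY`` with its attaining path."""

    value: float
    path: WarpingPath | None
    metric: str
    total_cost: float
    K: int


# ---------------------------------------------------------------------------
# Local costs
# ---------------------------------------------------------------------------

def local_cost(col_x: np.ndarray, col_y: np.ndarray, metric: str = "euclidean") -> float:
    """Distance between two aligned elements (scalars, columns, or flattened
    depth-frames)."""
    x = np.atleast_1d(np.asarray(col_x, dtype=float)).ravel()
    y = np.atleast_1d(np.asarray(col_y, dtype=float)).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d = x - y
    if metric == "euclidean":
        return float(np.sqrt(d @ d))
    if metric == "manhattan":
        return float(np.abs(d).sum())
    if metric == "sq_euclidean":
        return float(d @ d)
    raise ValueError(f"unknown metric {metric!r}")


def _as_columns(X) -> np.ndarray:
    """Canonical (n_steps, dim) element array for a vector/matrix/cuboid."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X[:, None]
    if X.ndim == 2:
        return X.T                      # columns are the aligned elements
    if X.ndim == 3:
        return cuboid_as_matrix(X).T    # depth-frames, flattened
    raise ValueError("inputs must be 1-, 2-, or 3-dimensional")


def cost_matrix(X, Y, metric: str = "euclidean") -> np.ndarray:
    """All pairwise local costs ``c[i, j] = d(X_i, Y_j)``."""
    cx, cy = _as_columns(X), _as_columns(Y)
    if cx.shape[1] != cy.shape[1]:
        raise ValueError(
            f"row/depth mismatch: elements have dims {cx.shape[1]} vs {cy.shape[1]}"
        )
    if cx.shape[0] == 0 or cy.shape[0] == 0:
        raise ValueError("empty sequence")
    if metric not in _CDIST_NAME:
        raise ValueError(f"unknown metric {metric!r}")
    return cdist(cx, cy, metric=_CDIST_NAME[metric])


def cuboid_as_matrix(X: np.ndarray) -> np.ndarray:
    """Stack the depth-frames of an ``(M, N, G)`` cuboid into an
    ``(M*G, N)`` matrix whose column-wise Euclidean cost equals the
    cuboid's frame-wise cost."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a 3-d cuboid")
    m, n, g = X.shape
    return X.transpose(2, 0, 1).reshape(m * g, n)


# ---------------------------------------------------------------------------
# Dynamic program
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dp_suffix(c):  # pragma: no cover - exercised via dtw_align
    """Suffix tables: minimal total cost D and, among minimal-cost suffix
    paths, minimal node count L, from each cell to the bottom-right cell."""
    n, m = c.shape
    D = np.empty((n, m))
    L = np.empty((n, m), dtype=np.int64)
    D[n - 1, m - 1] = c[n - 1, m - 1]
    L[n - 1, m - 1] = 1
    for j in range(m - 2, -1, -1):
        D[n - 1, j] = c[n - 1, j] + D[n - 1, j + 1]
        L[n - 1, j] = 1 + L[n - 1, j + 1]
    for i in range(n - 2, -1, -1):
        D[i, m - 1] = c[i, m - 1] + D[i + 1, m - 1]
        L[i, m - 1] = 1 + L[i + 1, m - 1]
        for j in range(m - 2, -1, -1):
            # successors in lexicographic order: (i, j+1), (i+1, j), (i+1, j+1)
            bd = D[i, j + 1]
            bl = L[i, j + 1]
            if D[i + 1, j] < bd or (D[i + 1, j] == bd and L[i + 1, j] < bl):
                bd = D[i + 1, j]
                bl = L[i + 1, j]
            if D[i + 1, j + 1] < bd or (D[i + 1, j + 1] == bd and L[i + 1, j + 1] < bl):
                bd = D[i + 1, j + 1]
                bl = L[i + 1, j + 1]
            D[i, j] = c[i, j] + bd
            L[i, j] = 1 + bl
    return D, L


def _walk_path(c: np.ndarray, D: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Forward walk choosing, at ties of (cost, length), the lexicographically
    smallest successor; yields the unique reported optimal path."""
    n, m = c.shape
    steps = [(0, 0)]
    i = j = 0
    while (i, j) != (n - 1, m - 1):
        cand = []
        if j + 1 < m:
            cand.append((i, j + 1))
        if i + 1 < n:
            cand.append((i + 1, j))
        if i + 1 < n and j + 1 < m:
            cand.append((i + 1, j + 1))
        best = min(cand, key=lambda ij: (D[ij], L[ij], ij))
        steps.append(best)
        i, j = best
    return np.asarray(steps, dtype=np.int64)


def dtw_align(X, Y, metric: str = "euclidean", return_path: bool = True) -> Discrepancy:
    """Optimal DTW alignment of two vectors, matrices, or cuboids.

    Matrices must have equal row counts; cuboids equal rows and depth.
    Returns the normalized discrepancy, the total cost, and (optionally)
    the attaining warping path.
    """
    c = cost_matrix(X, Y, metric)
    D, L = _dp_suffix(c)
    total = float(D[0, 0])
    K = int(L[0, 0])
    path = None
    if return_path:
        steps = _walk_path(c, D, L)
        path = WarpingPath(steps, c[steps[:, 0], steps[:, 1]])
        assert path.K == K
    return Discrepancy(total / K, path, metric, total, K)


def dtw_value(X, Y, metric: str = "euclidean") -> float:
    """Normalized discrepancy only (no path; the classifiers' fast path)."""
    c = cost_matrix(X, Y, metric)
    D, L = _dp_suffix(c)
    return float(D[0, 0]) / int(L[0, 0])


# ---------------------------------------------------------------------------
# Exhaustive oracle (tests only)
# ---------------------------------------------------------------------------

def _all_paths(n: int, m: int):
    """Every admissible path from (0,0) to (n-1,m-1), in lexicographic order."""
    stack = [[(0, 0)]]
    while stack:
        path = stack.pop()
        i, j = path[-1]
        if (i, j) == (n - 1, m - 1):
            yield path
            continue
        succ = []
        if j + 1 < m:
            succ.append((i, j + 1))
        if i + 1 < n:
            succ.append((i + 1, j))
        if i + 1 < n and j + 1 < m:
            succ.append((i + 1, j + 1))
        for s in reversed(succ):  # pop order == lexicographic order
            stack.append(path + [s])


def brute_force_align(
    X, Y, metric: str = "euclidean", max_len: int = 6, objective: str = "sum"
) -> Discrepancy:
    """Exhaustive enumeration of all admissible warping paths.

    ``objective="sum"`` reproduces :func:`dtw_align`'s two-stage rule
    (minimal total cost, then minimal K, then lexicographically smallest
    path) by independent enumeration; ``objective="normalized"`` minimizes
    ``(1/K) * sum`` directly, which can differ.  Refuses sequences longer
    than ``max_len``.
    """
    c = cost_matrix(X, Y, metric)
    n, m = c.shape
    if n > max_len or m > max_len:
        raise ValueError(f"brute force limited to length <= {max_len}")
    best = None
    best_key = None
    for path in _all_paths(n, m):
        steps = np.asarray(path, dtype=np.int64)
        costs = c[steps[:, 0], steps[:, 1]]
        total = float(costs.sum())
        K = len(path)
        key = (total, K) if objective == "sum" else (total / K,)
        if best_key is None or key < best_key:  # strict: first (lexicographic) wins
            best_key = key
            best = (total, K, steps, costs)
    total, K, steps, costs = best
    return Discrepancy(total / K, WarpingPath(steps, costs), metric, total, K)
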
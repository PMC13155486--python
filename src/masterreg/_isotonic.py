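"""Weighted isotonic projections on small grids.

The monotone factorial model constrains the cell-mean array of each gene to be
monotone along the ordered dose and time axes (direction free per gene) and,
for cell-cycle marker genes, maximal in the marker's own phase.  Each of these
constraint families is a closed convex cone whose Euclidean (weighted)
projection is a classic isotonic regression; their intersection is handled by
Dykstra's alternating-projection algorithm, which converges to the exact
projection onto the intersection of closed convex cones.

All primitives here are vectorised over the leading axis so that thousands of
genes are projected simultaneously; chain lengths are the number of dose/time
levels (small), so the exact O(L^2) minimax form of isotonic regression is
used instead of sequential pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "isotonic_rows",
    "max_at_index",
    "project_grid_monotone",
]


def isotonic_rows(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted nondecreasing isotonic regression applied row-wise.

    Parameters
    ----------
    x : (M, L) array
        Each row is an independent chain.
    w : (M, L) or (L,) array
        Strictly positive weights.

    Returns
    -------
    (M, L) array: argmin_y sum_k w_k (x_k - y_k)^2 s.t. y_0 <= ... <= y_{L-1},
    computed exactly via the minimax representation
    y_k = max_{i<=k} min_{j>=k} mean_w(x_i..x_j).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (rows are chains)")
    M, L = x.shape
    if L == 1:
        return x.copy()
    w = np.broadcast_to(np.asarray(w, dtype=float), x.shape)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    cw = np.cumsum(w, axis=1)
    cxw = np.cumsum(w * x, axis=1)
    zeros = np.zeros((M, 1))
    cw0 = np.concatenate([zeros, cw], axis=1)   # cw0[:, i] = sum w[:i]
    cxw0 = np.concatenate([zeros, cxw], axis=1)

    # A[:, i, j] = weighted mean of x[i..j]  (j >= i)
    num = cxw0[:, None, 1:] - cxw0[:, :-1, None]  # [m, i, j]
    den = cw0[:, None, 1:] - cw0[:, :-1, None]
    # entries with j < i have den <= 0; mask them out before the min
    with np.errstate(invalid="ignore", divide="ignore"):
        A = num / den
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    A[:, ii > jj] = np.inf

    # B[:, i, k] = min over j >= k of A[:, i, j]  -> reverse cumulative min
    B = np.minimum.accumulate(A[:, :, ::-1], axis=2)[:, :, ::-1]
    B[:, ii > jj] = -np.inf
    # y[:, k] = max over i <= k of B[:, i, k]
    y = np.maximum.accumulate(B, axis=1)[:, np.arange(L), np.arange(L)]
    return y


def max_at_index(x: np.ndarray, w: np.ndarray, imax: np.ndarray) -> np.ndarray:
    """Project rows onto the cone ``{y : y[imax] >= y[j] for all j}``.

    Used for the phase-marker constraint: a marker gene's fitted level must be
    maximal in its own cell-cycle phase.  ``imax`` gives the designated-maximum
    column per row.  Weighted projection by pooling: the designated entry is
    averaged with the largest offending entries until no entry exceeds the
    pooled mean (same exchange argument as PAVA on a star order).
    """
    x = np.asarray(x, dtype=float)
    M, L = x.shape
    w = np.broadcast_to(np.asarray(w, dtype=float), x.shape)
    imax = np.broadcast_to(np.asarray(imax, dtype=int), (M,))

    rows = np.arange(M)
    # reorder columns so the designated max is first, others sorted descending
    others_val = x.copy()
    others_val[rows, imax] = np.inf  # sorts first; dropped below
    order = np.argsort(-others_val, axis=1)  # column 0 == imax
    xs = np.take_along_axis(x, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)

    # prefix pooled means m_k = mean_w(xs[0], xs[1..k])
    cxw = np.cumsum(xs * ws, axis=1)
    cw = np.cumsum(ws, axis=1)
    m = cxw / cw  # m[:, k] pools designated + k largest others
    # smallest k such that next sorted other (xs[:, k+1]) <= m[:, k]
    nxt = np.concatenate([xs[:, 1:], np.full((M, 1), -np.inf)], axis=1)
    feasible = nxt <= m
    k = np.argmax(feasible, axis=1)  # first True; always True at L-1

    pooled = m[rows, k]
    ys = xs.copy()
    mask = np.arange(L)[None, :] <= k[:, None]
    ys = np.where(mask, pooled[:, None], ys)
    # scatter back to original column order
    y = np.empty_like(ys)
    np.put_along_axis(y, order, ys, axis=1)
    return y


def _project_axis(beta, w, axis, sign):
    """Isotonic projection along one grid axis (sign=+1 nondecreasing)."""
    b = np.moveaxis(beta, axis, -1)
    shape = b.shape
    L = shape[-1]
    b2 = b.reshape(-1, L)
    w2 = np.moveaxis(np.broadcast_to(w, beta.shape), axis, -1).reshape(-1, L)
    if sign < 0:
        b2 = b2[:, ::-1]
        w2 = w2[:, ::-1]
    y = isotonic_rows(b2, w2)
    if sign < 0:
        y = y[:, ::-1]
    return np.moveaxis(y.reshape(shape), -1, axis)


def project_grid_monotone(
    means: np.ndarray,
    weights: np.ndarray,
    axes_signs: list[tuple[int, int]],
    marker_phase: np.ndarray | None = None,
    phase_axis: int = -1,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """Weighted projection of per-gene cell-mean grids onto monotone cones.

    Parameters
    ----------
    means : (G, ...) array
        Per-gene grid of weighted group means (gene axis first).
    weights : array broadcastable to ``means`` (without requiring the gene
        axis) of strictly positive group weights.
    axes_signs : list of (axis, sign)
        Axes of ``means`` (>=1, i.e. not the gene axis) along which chain
        monotonicity is imposed; sign +1 nondecreasing, -1 nonincreasing.
    marker_phase : (G,) int array, optional
        If given, additionally require the grid to be maximal at this phase
        index along ``phase_axis`` for every other coordinate (phase-marker
        constraint).
    tol, max_iter : Dykstra stopping rule (max abs change over one full cycle).

    Returns
    -------
    Array like ``means``: the weighted least-squares projection onto the
    intersection of the requested cones.  With a single constraint family the
    first cycle is already exact (plain isotonic regression).
    """
    means = np.asarray(means, dtype=float)
    w = np.broadcast_to(np.asarray(weights, dtype=float), means.shape)

    projections = []
    for axis, sign in axes_signs:
        projections.append(("axis", axis, sign))
    if marker_phase is not None:
        projections.append(("marker", phase_axis, None))

    if len(projections) == 1 and projections[0][0] == "axis":
        _, axis, sign = projections[0]
        return _project_axis(means, w, axis, sign)

    y = means.copy()
    increments = [np.zeros_like(means) for _ in projections]
    for _ in range(max_iter):
        y_start = y.copy()
        for idx, proj in enumerate(projections):
            z = y + increments[idx]
            if proj[0] == "axis":
                _, axis, sign = proj
                y = _project_axis(z, w, axis, sign)
            else:
                _, paxis, _ = proj
                zb = np.moveaxis(z, paxis, -1)
                shp = zb.shape
                G = shp[0]
                L = shp[-1]
                z2 = zb.reshape(G, -1, L)
                wb = np.moveaxis(w, paxis, -1).reshape(G, -1, L)
                im = np.repeat(marker_phase, z2.shape[1])
                y2 = max_at_index(
                    z2.reshape(-1, L), wb.reshape(-1, L), im
                ).reshape(shp)
                y = np.moveaxis(y2, -1, paxis)
            increments[idx] = z - y
        if np.max(np.abs(y - y_start)) < tol:
            break
    return y
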
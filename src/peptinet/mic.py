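"""Maximal Information Coefficient (MIC).

MIC scores the association between two real-valued samples by searching
over two-dimensional grids: for every grid with at most B(n) = n^alpha
cells, the mutual information of the induced discrete distribution is
normalized by log min(#columns, #rows), and MIC is the maximum of these
normalized values. It equals 1 for noiseless functional relationships
(linear or not) and tends to 0 for independent data.

The search uses the standard approximation: one axis is equipartitioned
into rows, and the other axis partition is optimized by dynamic
programming over "clumps" (maximal runs of consecutive points falling in
the same row; points with tied abscissae are atomic). When the number of
clumps exceeds c * x_max they are first coarsened into superclumps. Both
axis orientations are searched. All logarithms cancel in the ratio, so
natural logs are used internally.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["mic_score"]


def _equipartition(v: np.ndarray, k: int) -> np.ndarray:
    """Assign each point to one of <= k rows of near-equal size, keeping
    tied values in the same row. Returns the per-point row label."""
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    assign = np.empty(n, dtype=np.int64)
    sorted_v = v[order]
    # tie groups over sorted positions
    boundaries = np.flatnonzero(np.diff(sorted_v) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    row, in_row, placed = 0, 0, 0
    desired = n / k
    for s, e in zip(starts, ends):
        size = e - s
        if in_row > 0 and abs(in_row + size - desired) >= abs(in_row - desired) and row < k - 1:
            row += 1
            in_row = 0
            desired = (n - placed) / (k - row)
        assign[order[s:e]] = row
        in_row += size
        placed += size
    return assign


def _clump_counts(x: np.ndarray, rows: np.ndarray, n_rows: int) -> np.ndarray:
    """Row-count matrix (one row per clump) of the x-sorted point stream.

    A clump is a maximal run of consecutive points (by x, ties atomic)
    sharing a single row label; tie groups spanning several rows form
    their own clump.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    labels = rows[order]
    n = len(x)
    boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    clumps: list[np.ndarray] = []
    prev_pure: int | None = None
    for s, e in zip(starts, ends):
        grp = labels[s:e]
        counts = np.bincount(grp, minlength=n_rows).astype(float)
        pure = int(grp[0]) if (grp == grp[0]).all() else None
        if pure is not None and prev_pure == pure:
            clumps[-1] += counts
        else:
            clumps.append(counts)
        prev_pure = pure
    return np.array(clumps)


def _superclumps(counts: np.ndarray, k_hat: int) -> np.ndarray:
    """Coarsen clumps to at most k_hat superclumps of near-equal size."""
    m = counts.shape[0]
    if m <= k_hat:
        return counts
    sizes = counts.sum(axis=1)
    n = sizes.sum()
    merged: list[np.ndarray] = []
    in_cur, placed, slot = 0.0, 0.0, 0
    desired = n / k_hat
    for i in range(m):
        if in_cur > 0 and abs(in_cur + sizes[i] - desired) >= abs(in_cur - desired) and slot < k_hat - 1:
            slot += 1
            in_cur = 0.0
            desired = (n - placed) / (k_hat - slot)
        if in_cur == 0.0:
            merged.append(counts[i].copy())
        else:
            merged[-1] += counts[i]
        in_cur += sizes[i]
        placed += sizes[i]
    return np.array(merged)


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    pos = a > 0
    out[pos] = a[pos] * np.log(a[pos])
    return out


def _best_mi_per_columns(counts: np.ndarray, x_max: int) -> np.ndarray:
    """Max of sum_cols [sum_r n_cr log n_cr - n_c log n_c] over partitions
    of the clump sequence into l columns, for l = 1..x_max (index l-1).

    This additive objective equals n * (H(P) - H(P,Q)); adding H(Q) and
    dividing by n yields the mutual information of the grid.
    """
    m = counts.shape[0]
    cum = np.vstack([np.zeros(counts.shape[1]), np.cumsum(counts, axis=0)])  # (m+1, R)
    # A[s, t] = objective of one column spanning clumps s..t-1 (s < t)
    seg = cum[None, :, :] - cum[:, None, :]  # (m+1, m+1, R)
    seg_tot = seg.sum(axis=2)
    a = _xlogx(seg).sum(axis=2) - _xlogx(seg_tot)
    a[np.tril_indices(m + 1)] = -np.inf  # only s < t valid

    l_max = min(x_max, m)
    best = np.full(x_max, -np.inf)
    g = a[0, :].copy()  # g[t]: best for clumps 0..t-1 in current l columns
    best[0] = g[m]
    for l in range(2, l_max + 1):
        g = np.max(g[:, None] + a, axis=0)
        best[l - 1] = g[m]
    return best


def _char_values(x: np.ndarray, y: np.ndarray, b: int, c: int) -> float:
    """Max normalized mutual information over grids with rows from y and
    optimized columns on x."""
    n = len(x)
    score = 0.0
    for y_bins in range(2, b // 2 + 1):
        x_max = b // y_bins
        if x_max < 2:
            break
        rows = _equipartition(y, y_bins)
        n_rows = int(rows.max()) + 1
        row_counts = np.bincount(rows, minlength=n_rows).astype(float)
        h_q = -np.sum(_xlogx(row_counts / n))
        counts = _clump_counts(x, rows, n_rows)
        counts = _superclumps(counts, max(2, c * x_max))
        best = _best_mi_per_columns(counts, x_max)
        for l in range(2, x_max + 1):
            if not np.isfinite(best[l - 1]):
                continue
            mi = h_q + best[l - 1] / n
            score = max(score, mi / np.log(min(l, y_bins)))
    return score


def mic_score(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """MIC of two equal-length samples with grid bound B = n^alpha and
    clump factor c. Constant input returns 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: MIC set to 0", stacklevel=2)
        return 0.0
    b = max(4, int(np.floor(n**alpha)))
    score = max(_char_values(x, y, b, c), _char_values(y, x, b, c))
    return float(min(1.0, score))
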
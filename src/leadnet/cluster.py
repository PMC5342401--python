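"""Exact one-dimensional k-means by dynamic programming.

For scalar data the optimal k-means partition is contiguous in sorted order,
so the globally optimal clustering is found exactly by dynamic programming
over split points (the Ckmeans.1d.dp construction), in O(k n^2) with
vectorised inner loops.  This makes class assignment deterministic and
seed-independent, unlike Lloyd iterations.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def kmeans_1d(values, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal k-means clustering of scalar values.

    Parameters
    ----------
    values : array-like of float
    k : int
        Number of clusters; must not exceed the number of distinct values.

    Returns
    -------
    labels : ndarray of int
        Cluster index (0-based, ordered by ascending cluster mean) per input
        value, aligned with the input order.
    centers : ndarray of float
        Cluster means in ascending order.
    wcss : float
        Within-cluster sum of squares attained (the global optimum).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValidationError("cannot cluster an empty value set")
    if k < 1:
        raise ValidationError("k must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValidationError(
            f"k={k} exceeds the number of distinct values ({n_distinct})"
        )

    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    pref = np.concatenate(([0.0], np.cumsum(xs)))
    prefsq = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def interval_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSQ of xs[i..j] inclusive, vectorised over i
        cnt = j - i + 1
        s = pref[j + 1] - pref[i]
        sq = prefsq[j + 1] - prefsq[i]
        return np.maximum(sq - s * s / cnt, 0.0)

    D = np.full((k, n), np.inf)
    B = np.zeros((k, n), dtype=int)
    idx_all = np.arange(n)
    counts = idx_all + 1.0
    D[0, :] = np.maximum(prefsq[1:] - pref[1:] ** 2 / counts, 0.0)
    for c in range(1, k):
        for j in range(c, n):
            i = idx_all[c : j + 1]
            cand = D[c - 1, i - 1] + interval_cost(i, j)
            best = int(np.argmin(cand))
            D[c, j] = cand[best]
            B[c, j] = i[best]

    # backtrack split starts
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    j = n - 1
    for c in range(k - 1, -1, -1):
        start = B[c, j] if c > 0 else 0
        bounds[c] = start
        j = start - 1

    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for c in range(k):
        lo, hi = bounds[c], bounds[c + 1]
        labels_sorted[lo:hi] = c
        centers[c] = xs[lo:hi].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers, float(max(D[k - 1, n - 1], 0.0))


def _sum_abs_dist(points: np.ndarray, arr: np.ndarray, pref: np.ndarray) -> np.ndarray:
    """Sum of |p - a| over sorted arr, vectorised over points, via prefix sums."""
    pos = np.searchsorted(arr, points, side="right")
    left = points * pos - pref[pos]
    right = (pref[-1] - pref[pos]) - points * (arr.size - pos)
    return left + right


def mean_silhouette_1d(values, labels) -> float:
    """Mean silhouette coefficient for a 1-D clustering, in O(n log n).

    Singleton clusters contribute a silhouette of 0 for their point.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette requires >= 2 clusters")
    sorted_by_cluster = {}
    for c in uniq:
        arr = np.sort(x[labels == c])
        sorted_by_cluster[c] = (arr, np.concatenate(([0.0], np.cumsum(arr))))

    s = np.zeros(x.size)
    for c in uniq:
        mask = labels == c
        pts = x[mask]
        arr_c, pref_c = sorted_by_cluster[c]
        n_c = arr_c.size
        if n_c == 1:
            s[mask] = 0.0
            continue
        a = _sum_abs_dist(pts, arr_c, pref_c) / (n_c - 1)
        b = np.full(pts.size, np.inf)
        for other in uniq:
            if other == c:
                continue
            arr_o, pref_o = sorted_by_cluster[other]
            b = np.minimum(b, _sum_abs_dist(pts, arr_o, pref_o) / arr_o.size)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            si = np.where(denom > 0, (b - a) / denom, 0.0)
        s[mask] = si
    return float(s.mean())


def select_k_silhouette(values, k_max: int = 6) -> int:
    """Silhouette-based choice of k over 2..min(k_max, n_distinct); ties -> smaller k."""
    x = np.asarray(values, dtype=float)
    n_distinct = np.unique(x).size
    upper = min(k_max, n_distinct)
    if upper < 2:
        raise ValidationError("auto k selection needs >= 2 distinct values")
    best_k, best_s = None, -np.inf
    for k in range(2, upper + 1):
        labels, _, _ = kmeans_1d(x, k)
        s = mean_silhouette_1d(x, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k
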
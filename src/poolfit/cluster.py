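"""Hierarchical clustering of fitness profiles, Cluster 3.0 style.

Rows (genes) are filtered for informative change, compared with the
uncentered correlation similarity (a cosine without mean-centering, so
profiles of the same shape *and* sign cluster together), and merged by
average linkage: the distance between two clusters is the unweighted mean
of 1 - similarity over all cross-pair leaf combinations.  Ties in the
minimum distance are broken on the lexicographically smallest pair of
cluster representatives (each cluster represented by its smallest original
row index), which makes the merge sequence deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PoolfitError


@dataclass
class Dendrogram:
    """Merge list over node ids: leaves are 0..n-1, the k-th merge creates
    node n+k.  ``leaf_order`` is the left-to-right leaf permutation."""

    n_leaves: int
    merges: list[tuple[int, int, float]]
    leaf_order: list[int]


def filter_rows(
    matrix: pd.DataFrame,
    mode: str = "any_change",
    level: float = 1.0,
    frac: float = 0.5,
    absolute: bool = True,
) -> pd.DataFrame:
    """Remove uninformative profiles before clustering.

    ``any_change`` keeps rows with at least one cell at or beyond ``level``
    (in absolute value by default; set ``absolute=False`` for a signed
    reading); ``half_significant`` keeps rows at or beyond ``level`` in at
    least ``frac`` of their non-missing cells.
    """
    vals = matrix.to_numpy(float)
    mag = np.abs(vals) if absolute else vals
    hit = mag >= level
    if mode == "any_change":
        keep = np.nansum(hit, axis=1) >= 1
    elif mode == "half_significant":
        present = ~np.isnan(vals)
        n_present = present.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            keep = np.where(
                n_present > 0, (hit & present).sum(axis=1) / n_present >= frac, False
            )
    else:
        raise PoolfitError(f"unknown filter mode: {mode!r}")
    out = matrix[keep]
    if len(out) == 0:
        import warnings

        warnings.warn("row filter removed every profile", stacklevel=2)
    return out


def uncentered_correlation(x, y) -> float:
    """Uncentered correlation sum(x*y)/sqrt(sum(x^2)*sum(y^2)) over the
    pairwise non-missing positions of the two profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    if not both.any():
        raise PoolfitError("profiles share no non-missing positions")
    xs, ys = x[both], y[both]
    nx = float(np.dot(xs, xs))
    ny = float(np.dot(ys, ys))
    if nx == 0.0 or ny == 0.0:
        raise PoolfitError("zero-norm profile on the shared positions")
    return float(np.dot(xs, ys) / np.sqrt(nx * ny))


def distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - uncentered correlation; errors name the offending rows."""
    vals = matrix.to_numpy(float)
    n = len(vals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                sim = uncentered_correlation(vals[i], vals[j])
            except PoolfitError as exc:
                raise PoolfitError(
                    f"similarity undefined between rows "
                    f"{matrix.index[i]!r} and {matrix.index[j]!r}: {exc}"
                ) from exc
            d[i, j] = d[j, i] = 1.0 - sim
    return d


def average_linkage(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering on the uncentered-
    correlation distance (UPGMA on the precomputed matrix)."""
    n = len(matrix)
    if n < 2:
        raise PoolfitError("need at least 2 rows to cluster")
    d = distance_matrix(matrix)

    # active cluster state: id -> (representative leaf index, size, leaves)
    active: dict[int, tuple[int, int, list[int]]] = {
        i: (i, 1, [i]) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    orders: dict[int, list[int]] = {i: [i] for i in range(n)}

    next_id = n
    while len(active) > 1:
        # minimum distance; ties broken on smallest (rep_a, rep_b)
        best = None
        for (i, j), dij in dist.items():
            ri, rj = active[i][0], active[j][0]
            key = (dij, min(ri, rj), max(ri, rj))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        ri, si, li = active[i]
        rj, sj, lj = active[j]
        a, b = (i, j) if ri < rj else (j, i)
        merges.append((a, b, dij))
        orders[next_id] = orders[a] + orders[b]

        new_rep = min(ri, rj)
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            # Lance-Williams average update == mean over all cross leaf pairs
            dnew = (si * dik + sj * djk) / (si + sj)
            dist[(k, next_id)] = dnew
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del active[i], active[j]
        active[next_id] = (new_rep, si + sj, li + lj)
        next_id += 1

    root = next(iter(active))
    return Dendrogram(n_leaves=n, merges=merges, leaf_order=orders[root])
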
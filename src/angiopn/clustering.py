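"""Hierarchical clustering of t-invariant supports with MSS model selection.

t-invariants are grouped into *t-clusters* — sets of invariants whose
supports are similar, interpreted as interacting subprocesses.  Because no
single distance metric / linkage / cluster count is canonically right, the
module evaluates a whole grid of combinations, scoring each clustering by the
number of singleton clusters and a Mean Split Silhouette (MSS) style index.

Distances operate on the binary occurrence vectors (rows of the support
matrix).  The implemented MSS assigns each element the classical silhouette
width of the top-level partition, with elements of singleton clusters
contributing 0; the per-cluster value is the mean over members and the global
value the mean over all elements (equivalently the size-weighted mean of the
per-cluster values).  This is a documented approximation of the recursive
split-silhouette index from the model-selection literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .invariants import SupportMatrix

__all__ = [
    "METRICS",
    "LINKAGES",
    "DistanceMatrix",
    "Dendrogram",
    "distance_matrix",
    "agglomerate",
    "cut_dendrogram",
    "silhouette_widths",
    "mean_split_silhouette",
    "evaluate_grid",
]

#: metric name -> scipy pdist metric (None = special-cased)
METRICS = {
    "binary": "jaccard",
    "canberra": "canberra",
    "correlation": None,
    "uncentered": None,
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "maximum": "chebyshev",
    "minkowski": "minkowski",
}

LINKAGES = (
    "single",
    "complete",
    "average",  # UPGMA
    "mcquitty",  # WPGMA
    "centroid",  # UPGMC
    "median",  # WPGMC
    "ward",  # ward.D2 (squared-distance Lance-Williams)
    "ward_d",  # classic ward.D update on raw dissimilarities
)


@dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray
    labels: tuple[str, ...]
    metric: str

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape/label mismatch")
        if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: clusters 0..N-1 are leaves, merge i creates N+i."""

    merges: tuple[tuple[int, int, float], ...]
    leaf_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.merges) != max(len(self.leaf_labels) - 1, 0):
            raise ValueError("a dendrogram over N leaves has N-1 merges")


def _correlation_like(rows: np.ndarray, centered: bool) -> np.ndarray:
    """1 - Pearson r (centered) or 1 - cosine (uncentered), with a defined
    fallback for rows of zero norm/variance: distance 0 to an identical row,
    1 otherwise."""
    X = rows.astype(float)
    if centered:
        X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            "constant/zero rows under a correlation metric; using the "
            "identical->0 / different->1 fallback for them",
            stacklevel=3,
        )
    safe = np.where(degenerate, 1.0, norms)
    U = X / safe[:, None]
    d = 1.0 - U @ U.T
    n = len(rows)
    for i in np.nonzero(degenerate)[0]:
        for j in range(n):
            same = bool((rows[i] == rows[j]).all())
            d[i, j] = d[j, i] = 0.0 if same else 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def distance_matrix(
    matrix: SupportMatrix | np.ndarray,
    metric: str,
    minkowski_p: float = 2.0,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise distances between the rows of a support matrix.

    ``binary`` is the Jaccard-style fraction of discordant nonzero coordinates
    among coordinates where either row is nonzero; ``canberra`` skips 0/0
    coordinates; ``correlation`` is 1 - Pearson r, ``uncentered`` 1 - cosine;
    the remaining metrics are the standard norms.
    """
    if isinstance(matrix, SupportMatrix):
        rows = np.asarray(matrix.entries, dtype=float)
        labels = matrix.row_labels
    else:
        rows = np.asarray(matrix, dtype=float)
        labels = tuple(labels or (f"r{i}" for i in range(len(rows))))
    if len(rows) < 2:
        raise ValueError("need at least two rows to compute distances")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if metric == "correlation":
        d = _correlation_like(rows, centered=True)
    elif metric == "uncentered":
        d = _correlation_like(rows, centered=False)
    elif metric == "binary":
        d = squareform(pdist(rows != 0, metric="jaccard"))
    elif metric == "minkowski":
        d = squareform(pdist(rows, metric="minkowski", p=minkowski_p))
    else:
        d = squareform(pdist(rows, metric=METRICS[metric]))
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, tuple(labels), metric)


# ---------------------------------------------------------------------------
# Lance-Williams agglomeration
# ---------------------------------------------------------------------------

#: linkage -> (uses squared dissimilarities, coefficient function)
def _lw_coeffs(method: str, ni: int, nj: int, nk: int):
    if method == "single":
        return 0.5, 0.5, 0.0, -0.5
    if method == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if method == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if method == "mcquitty":
        return 0.5, 0.5, 0.0, 0.0
    if method == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if method == "median":
        return 0.5, 0.5, -0.25, 0.0
    if method in ("ward", "ward_d"):
        s = ni + nj + nk
        return (ni + nk) / s, (nj + nk) / s, -nk / s, 0.0
    raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")


def agglomerate(d: DistanceMatrix, linkage: str) -> Dendrogram:
    """Hierarchical agglomeration of ``d`` under a Lance-Williams linkage.

    Deterministic tie-break: among all minimal-distance pairs, the pair with
    the smallest (i, j) cluster indices (creation order) is merged.  The
    ``centroid``, ``median``, and ``ward`` updates run on squared
    dissimilarities with heights reported on the original scale; ``ward_d``
    applies the Ward update to the dissimilarities as given.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    squared = linkage in ("centroid", "median", "ward")
    n = len(d)
    dm = d.values.astype(float).copy()
    if squared:
        dm = dm**2
    active = list(range(n))  # cluster ids, in creation order
    sizes = {i: 1 for i in range(n)}
    index = {i: i for i in range(n)}  # cluster id -> row in dm
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                ci, cj = active[a_pos], active[b_pos]
                dist = dm[index[ci], index[cj]]
                if best is None or dist < best[0]:
                    best = (dist, ci, cj)
        dist, ci, cj = best
        ri, rj = index[ci], index[cj]
        ni, nj = sizes[ci], sizes[cj]
        # update row ri in place to represent the merged cluster
        for ck in active:
            if ck in (ci, cj):
                continue
            rk = index[ck]
            ai, aj, beta, gamma = _lw_coeffs(linkage, ni, nj, sizes[ck])
            val = (
                ai * dm[ri, rk]
                + aj * dm[rj, rk]
                + beta * dm[ri, rj]
                + gamma * abs(dm[ri, rk] - dm[rj, rk])
            )
            dm[ri, rk] = dm[rk, ri] = val
        height = float(np.sqrt(dist)) if squared else float(dist)
        merges.append((ci, cj, height))
        active.remove(ci)
        active.remove(cj)
        sizes[next_id] = ni + nj
        index[next_id] = ri
        active.append(next_id)
        next_id += 1
    return Dendrogram(tuple(merges), d.labels)


def cut_dendrogram(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition into ``k`` clusters by undoing the last k-1 merges.

    Returns element label -> cluster number 1..k, clusters numbered by first
    appearance in leaf order.
    """
    n = len(dend.leaf_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _h) in enumerate(dend.merges[: n - k]):
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    assign: dict[str, int] = {}
    for leaf, label in enumerate(dend.leaf_labels):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assign[label] = roots[r]
    return assign


# ---------------------------------------------------------------------------
# Silhouettes and MSS
# ---------------------------------------------------------------------------

def silhouette_widths(
    assign: Mapping[str, int], d: DistanceMatrix
) -> dict[str, float]:
    """Classical silhouette width per element; singleton-cluster elements get 0.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean within-cluster
    distance and b(i) the smallest mean distance to another cluster.
    """
    labels = d.labels
    if set(assign) != set(labels):
        raise ValueError("assignment labels do not match the distance matrix")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(assign[lab], []).append(i)
    if len(clusters) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    out: dict[str, float] = {}
    for i, lab in enumerate(labels):
        own = clusters[assign[lab]]
        if len(own) == 1:
            out[lab] = 0.0
            continue
        a = d.values[i, [j for j in own if j != i]].mean()
        b = min(
            d.values[i, members].mean()
            for c, members in clusters.items()
            if c != assign[lab]
        )
        denom = max(a, b)
        out[lab] = 0.0 if denom == 0 else float((b - a) / denom)
    return out


def mean_split_silhouette(
    assign: Mapping[str, int], d: DistanceMatrix
) -> tuple[float, dict[int, float]]:
    """Global and per-cluster mean silhouette of a flat clustering.

    The global value is the mean over all elements, identical to the
    size-weighted mean of the per-cluster values.  Values are not rounded
    here; round only when reporting.
    """
    widths = silhouette_widths(assign, d)
    per_cluster: dict[int, list[float]] = {}
    for lab, s in widths.items():
        per_cluster.setdefault(assign[lab], []).append(s)
    per = {c: float(np.mean(v)) for c, v in sorted(per_cluster.items())}
    return float(np.mean(list(widths.values()))), per


def evaluate_grid(
    matrix: SupportMatrix,
    metrics: Sequence[str] = tuple(METRICS),
    linkages: Sequence[str] = ("single", "complete", "average", "mcquitty", "centroid", "median", "ward"),
    k_range: Sequence[int] = range(2, 21),
    minkowski_p: float = 2.0,
) -> pd.DataFrame:
    """One row per (metric, linkage, k): singleton count and global MSS."""
    rows = []
    for metric in metrics:
        d = distance_matrix(matrix, metric, minkowski_p=minkowski_p)
        for linkage in linkages:
            dend = agglomerate(d, linkage)
            for k in k_range:
                assign = cut_dendrogram(dend, k)
                sizes = pd.Series(list(assign.values())).value_counts()
                mss, _ = mean_split_silhouette(assign, d)
                rows.append(
                    {
                        "metric": metric,
                        "linkage": linkage,
                        "k": k,
                        "singletons": int((sizes == 1).sum()),
                        "mss": mss,
                    }
                )
    return pd.DataFrame(rows)
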
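"""Friedman-Rafsky minimal-spanning-tree two-sample test and cluster
matching across two single-cell datasets.

The FR statistic R counts MST edges joining points of the two samples on
the pooled point set: few cross edges mean the samples are separated. The
null is generated by permuting sample labels on the fixed pooled MST, and
the one-sided p-value is small when R is small. Cluster pairs whose test
fails to separate them (p > alpha) are match candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist


def minimum_spanning_tree(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean MST by Kruskal's algorithm with deterministic tie-breaks.

    Candidate edges are sorted by (weight, i, j) lexicographically, so the
    returned tree is unique even with tied or zero distances (duplicate
    points are allowed). Returns ``(edges, weights)`` with ``edges`` of
    shape (N-1, 2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points in a 2-D array")
    n = pts.shape[0]
    d = pdist(pts)
    ii, jj = np.triu_indices(n, k=1)
    order = np.lexsort((jj, ii, d))

    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    edges = np.empty((n - 1, 2), dtype=int)
    weights = np.empty(n - 1)
    k = 0
    for e in order:
        i, j = int(ii[e]), int(jj[e])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
            edges[k] = (i, j)
            weights[k] = d[e]
            k += 1
            if k == n - 1:
                break
    return edges, weights


def fr_statistic(a: np.ndarray, b: np.ndarray) -> int:
    """Number of pooled-MST edges joining a point of ``a`` to one of ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both samples must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share a feature space")
    pooled = np.vstack([a, b])
    edges, _ = minimum_spanning_tree(pooled)
    labels = np.zeros(pooled.shape[0], dtype=bool)
    labels[a.shape[0]:] = True
    return int((labels[edges[:, 0]] != labels[edges[:, 1]]).sum())


def _fr_moments(edges: np.ndarray, n_nodes: int, m: int, n: int) -> tuple[float, float]:
    """Permutation-null mean and variance of R on a fixed tree.

    Classical closed form for two-sample MST run statistics; C is the
    number of edge pairs sharing a node.
    """
    N = m + n
    deg = np.bincount(edges.ravel(), minlength=n_nodes)
    C = float((deg * (deg - 1) // 2).sum())
    mean = 2.0 * m * n / N
    var = (2.0 * m * n / (N * (N - 1.0))) * (
        (2.0 * m * n - N) / N
        + ((C - N + 2.0) / ((N - 2.0) * (N - 3.0))) * (N * (N - 1.0) - 4.0 * m * n + 2.0)
    )
    return mean, var


@dataclass(frozen=True)
class FRMatchResult:
    """Outcome of one Friedman-Rafsky comparison."""

    cluster_a: object
    cluster_b: object
    n_a: int
    n_b: int
    r: int
    p_value: float
    n_permutations: int
    matched: bool
    #: asymptotic-normal z-score of R, reported as a diagnostic only
    z: float

    def __post_init__(self) -> None:
        if not 1 <= self.r <= self.n_a + self.n_b - 1:
            raise ValueError("R outside its attainable range")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def fr_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    cluster_a: object = "a",
    cluster_b: object = "b",
) -> FRMatchResult:
    """Permutation Friedman-Rafsky test on the fixed pooled MST.

    Labels are shuffled ``n_perm`` times over the pooled tree and cross
    edges recounted; p = (1 + #{perm R <= observed R}) / (n_perm + 1).
    Small p means the samples are separated (NOT the same type);
    ``matched`` is the complementary call p > alpha.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share a feature space")
    m, n = a.shape[0], b.shape[0]
    if m + n < 4:
        raise ValueError("need at least 4 pooled points")
    pooled = np.vstack([a, b])
    edges, _ = minimum_spanning_tree(pooled)
    labels = np.zeros(m + n, dtype=bool)
    labels[m:] = True
    r_obs = int((labels[edges[:, 0]] != labels[edges[:, 1]]).sum())

    rng = np.random.default_rng(seed)
    perm = np.tile(labels, (n_perm, 1))
    rng.permuted(perm, axis=1, out=perm)
    r_perm = (perm[:, edges[:, 0]] != perm[:, edges[:, 1]]).sum(axis=1)
    p = (1.0 + (r_perm <= r_obs).sum()) / (n_perm + 1.0)

    mean, var = _fr_moments(edges, m + n, m, n)
    z = (r_obs - mean) / np.sqrt(var) if var > 0 else 0.0
    return FRMatchResult(
        cluster_a=cluster_a,
        cluster_b=cluster_b,
        n_a=m,
        n_b=n,
        r=r_obs,
        p_value=float(p),
        n_permutations=n_perm,
        matched=bool(p > alpha),
        z=float(z),
    )


def match_clusters(
    expr_a: pd.DataFrame,
    labels_a: np.ndarray | pd.Series,
    expr_b: pd.DataFrame,
    labels_b: np.ndarray | pd.Series,
    shared_genes: list[str],
    n_cells_cap: int = 200,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs FR matching of clusters between two datasets.

    ``expr_a``/``expr_b`` are cells x genes tables of log-normalized
    expression; both are projected onto ``shared_genes`` (typically the
    union of per-cluster marker genes of both datasets). Each cluster pair
    is subsampled to at most ``n_cells_cap`` cells per side and tested;
    the pair is a match candidate when the test cannot separate it
    (p > alpha). Returns (p-value matrix, boolean match matrix) indexed by
    clusters of dataset A (rows) and B (columns). A cluster may match
    nothing.
    """
    if len(shared_genes) == 0:
        raise ValueError("shared gene set must be non-empty")
    for name, expr in (("A", expr_a), ("B", expr_b)):
        missing = set(shared_genes) - set(expr.columns)
        if missing:
            raise ValueError(f"dataset {name} lacks shared genes: {sorted(missing)[:5]}")
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    clusters_a = sorted(pd.unique(la))
    clusters_b = sorted(pd.unique(lb))
    Xa = expr_a.loc[:, shared_genes].to_numpy(dtype=float)
    Xb = expr_b.loc[:, shared_genes].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    pvals = pd.DataFrame(np.nan, index=clusters_a, columns=clusters_b)
    matched = pd.DataFrame(False, index=clusters_a, columns=clusters_b)
    for ca in clusters_a:
        ia = np.flatnonzero(la == ca)
        if ia.size > n_cells_cap:
            ia = rng.choice(ia, n_cells_cap, replace=False)
        for cb in clusters_b:
            ib = np.flatnonzero(lb == cb)
            if ib.size > n_cells_cap:
                ib = rng.choice(ib, n_cells_cap, replace=False)
            res = fr_test(
                Xa[ia],
                Xb[ib],
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                alpha=alpha,
                cluster_a=ca,
                cluster_b=cb,
            )
            pvals.loc[ca, cb] = res.p_value
            matched.loc[ca, cb] = res.matched
    return pvals, matched
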
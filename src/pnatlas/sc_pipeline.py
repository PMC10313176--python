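"""Single-cell pipeline: QC filtering, log-normalization, PCA, graph
clustering, marker discovery, and the pseudotime Kolmogorov-Smirnov
comparison between genotypes.

Cells are kept when they express at least ``min_genes_per_cell`` genes and
their mitochondrial UMI fraction is strictly below ``max_mito_fraction``.
Normalization is global log-normalization, log(1 + scale * count / library).
Clustering is modularity-based community detection (Leiden) on a shared
nearest-neighbor graph built in the top principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FilterParams:
    """QC thresholds: minimum detected genes, maximum mitochondrial share."""

    min_genes_per_cell: int = 1000
    max_mito_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Embedding:
    """PCA coordinates with per-component variance fractions."""

    coords: np.ndarray  # cells x n_components
    variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        if self.coords.shape[1] != self.variance_ratio.shape[0]:
            raise ValueError("coords and variance_ratio disagree on n_components")
        if np.any(np.diff(self.variance_ratio) > 1e-12):
            raise ValueError("components must be ordered by decreasing variance")


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label per cell (contiguous small integers, largest first)."""

    labels: pd.Series  # cell id -> int
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def filter_cells(counts: ad.AnnData, params: FilterParams | None = None) -> ad.AnnData:
    """Retain cells passing both QC thresholds; genes are unchanged."""
    if params is None:
        params = FilterParams()
    if "is_mito" not in counts.var:
        raise ValueError("gene metadata must carry an 'is_mito' flag")
    X = counts.X
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, counts.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
    keep = (n_genes >= params.min_genes_per_cell) & (mito_frac < params.max_mito_fraction)
    if not keep.any():
        raise ValueError("no cells survive QC filtering")
    return counts[keep].copy()


def normalize_log(counts: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log(1 + scale * count / library) per cell (natural log).

    Returns a new AnnData with float values; raw counts are kept in
    ``layers['counts']``.
    """
    X = np.asarray(counts.X, dtype=float)
    lib = X.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("cells with zero library size cannot be normalized")
    out = counts.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(scale * X / lib[:, None])
    return out


def embed_pca(
    normalized: ad.AnnData | np.ndarray,
    n_components: int = 30,
    scale_genes: bool = True,
    clip: float = 10.0,
) -> Embedding:
    """PCA of the normalized matrix; genes centered and unit-scaled.

    Unit-scaled values are clipped at ``clip`` standard deviations, the
    convention of the standard single-cell pipeline this mirrors. The sign
    of each component is fixed so its largest-magnitude loading is
    positive, making the embedding deterministic.
    """
    X = normalized.X if isinstance(normalized, ad.AnnData) else normalized
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 cells")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {min(X.shape)}"
        )
    Xc = X - X.mean(axis=0)
    if scale_genes:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = np.clip(Xc / sd, -clip, clip)
        Xc = Xc - Xc.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Xc)
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return Embedding(coords=coords * flip, variance_ratio=pca.explained_variance_ratio_)


def snn_graph(coords: np.ndarray, k_graph: int = 20) -> igraph.Graph:
    """Shared nearest-neighbor graph with Jaccard edge weights.

    Each cell is connected to its ``k_graph`` nearest Euclidean neighbors
    (including itself); edge weight is the Jaccard overlap of the two
    neighbor sets. Edges with overlap below 1/15 are pruned.
    """
    n = coords.shape[0]
    if k_graph <= 0:
        raise ValueError("k_graph must be positive")
    if k_graph >= n:
        raise ValueError("k_graph must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_graph).fit(coords)
    idx = nn.kneighbors(return_distance=False)
    idx = np.hstack([np.arange(n)[:, None], idx])  # include self
    sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            w = inter / union
            if w >= 1 / 15:
                edges.append((i, int(j)))
                weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    g.simplify(combine_edges="max")
    return g


def cluster_graph(
    embedding: Embedding | np.ndarray,
    k_graph: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    min_cluster_size: int = 10,
    cell_ids: pd.Index | None = None,
) -> ClusterAssignment:
    """Leiden modularity clustering of the SNN graph.

    Communities smaller than ``min_cluster_size`` (isolated outlier cells
    whose SNN edges were pruned) are dissolved and their cells assigned to
    the nearest retained cluster centroid, mirroring the singleton
    grouping of the standard pipeline. Labels are relabeled to contiguous
    integers ordered by cluster size (largest cluster = 0). Deterministic
    for a fixed seed.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    g = snn_graph(coords, k_graph=k_graph)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    big = sizes.index[sizes >= min_cluster_size].to_numpy()
    if big.size == 0:
        big = sizes.index[:1].to_numpy()
    small_cells = np.flatnonzero(~np.isin(raw, big))
    if small_cells.size:
        centroids = np.stack([coords[raw == c].mean(axis=0) for c in big])
        d = np.linalg.norm(coords[small_cells, None, :] - centroids[None], axis=2)
        raw = raw.copy()
        raw[small_cells] = big[d.argmin(axis=1)]
    order = pd.Series(raw).value_counts().index.to_numpy()
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in raw])
    if cell_ids is None:
        cell_ids = pd.RangeIndex(coords.shape[0])
    return ClusterAssignment(
        labels=pd.Series(labels, index=cell_ids, name="cluster"),
        resolution=resolution,
    )


def rank_sum_de(
    X: np.ndarray, in_group: np.ndarray, pseudocount: float = 1e-9
) -> pd.DataFrame:
    """Vectorized one-vs-rest Wilcoxon rank-sum over genes.

    ``X`` holds log-normalized values; log2FC compares group means on the
    de-logged (expm1) scale with a small pseudocount.
    """
    a, b = X[in_group], X[~in_group]
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    frac_a = (a > 0).mean(axis=0)
    frac_b = (b > 0).mean(axis=0)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pct_in": frac_a,
            "pct_out": frac_b,
            "pval": res.pvalue,
        }
    )


def find_markers(
    normalized: ad.AnnData,
    clusters: ClusterAssignment,
    top_n: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top up-regulated genes per cluster by one-vs-rest rank-sum test.

    Genes passing BH-adjusted p < ``alpha`` are ranked by log2 fold change
    (descending) and the top ``top_n`` per cluster returned. Clusters with
    fewer than 3 cells are untestable and yield no rows.
    """
    labels = clusters.labels.to_numpy()
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("marker discovery needs at least 2 clusters")
    X = np.asarray(normalized.X, dtype=float)
    frames = []
    for cl in uniq:
        in_group = labels == cl
        if in_group.sum() < 3 or (~in_group).sum() < 3:
            continue
        tab = rank_sum_de(X, in_group)
        tab["gene"] = normalized.var_names
        tab["padj"] = multipletests(tab["pval"], method="fdr_bh")[1]
        tab = tab[(tab["padj"] < alpha) & (tab["log2fc"] > 0)]
        tab = tab.sort_values(["log2fc", "gene"], ascending=[False, True]).head(top_n)
        tab = tab.assign(cluster=cl, rank=np.arange(1, len(tab) + 1))
        frames.append(tab)
    cols = ["cluster", "rank", "gene", "log2fc", "pct_in", "pct_out", "pval", "padj"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def path_pseudotime(
    coords: np.ndarray, states: np.ndarray, state_order: list[str]
) -> np.ndarray:
    """Project cells onto the piecewise-linear path through state centroids.

    The path visits the centroid of each state in ``state_order``; each
    cell maps to its closest point on the path, and positions are arc
    lengths rescaled to [0, 1].
    """
    centroids = np.array(
        [coords[states == s].mean(axis=0) for s in state_order]
    )
    seg_vec = np.diff(centroids, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        return np.zeros(coords.shape[0])
    best_d = np.full(coords.shape[0], np.inf)
    best_t = np.zeros(coords.shape[0])
    for k in range(len(seg_vec)):
        v = seg_vec[k]
        denom = max(seg_len[k] ** 2, 1e-300)
        t = np.clip((coords - centroids[k]) @ v / denom, 0.0, 1.0)
        proj = centroids[k] + t[:, None] * v
        d = np.linalg.norm(coords - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_t[better] = cum[k] + t[better] * seg_len[k]
    return best_t / total


def pseudotime_ks(
    embedding: Embedding | np.ndarray,
    state_order: list[str],
    cell_states: np.ndarray | pd.Series,
    genotype: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Two-sample KS test of the pseudotime distributions of two genotypes.

    Pseudotime is the centroid-path projection along ``state_order``.
    Returns ``(D, p)``.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    states = np.asarray(cell_states)
    geno = np.asarray(genotype)
    groups = np.unique(geno)
    if groups.size != 2:
        raise ValueError(f"expected exactly 2 genotypes, got {groups.size}")
    pt = path_pseudotime(coords, states, state_order)
    a, b = pt[geno == groups[0]], pt[geno == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each genotype needs at least 2 cells")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
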
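"""K-nearest-neighbor transfer of scRNA-seq subtype labels to ISH tiles.

Each cell's nine-transcript profile (the ISH panel extracted from the
log-normalized expression matrix) is normalized and used, with its
subtype label, to train a KNN classifier. K is selected by stratified
sixfold cross-validation; tiles inside the pontine boundary are then
classified by majority vote of their K nearest training vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .spatial_tiling import BoundaryMask, TileGrid


def _normalize_vectors(V: np.ndarray, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    """Normalize rows; returns (normalized, keep_mask) dropping zero rows."""
    V = np.asarray(V, dtype=float)
    if scheme == "unit":
        norms = np.linalg.norm(V, axis=1)
        keep = norms > 0
        out = V[keep] / norms[keep, None]
    elif scheme == "minmax":
        vmax = V.max(axis=1)
        keep = vmax > 0
        sub = V[keep]
        vmin = sub.min(axis=1, keepdims=True)
        rng = sub.max(axis=1, keepdims=True) - vmin
        rng[rng == 0] = 1.0
        out = (sub - vmin) / rng
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    return out, keep


@dataclass(frozen=True)
class TrainingSet:
    """Normalized per-cell panel vectors with subtype labels."""

    vectors: np.ndarray  # cells x n_panel
    labels: np.ndarray  # subtype per cell
    panel: tuple[str, ...]
    scheme: str
    n_dropped: int  # all-zero cells removed during normalization

    @property
    def n_cells(self) -> int:
        return self.vectors.shape[0]

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != self.labels.shape[0]:
            raise ValueError("vectors and labels disagree on cell count")
        if np.unique(self.labels).size < 2:
            raise ValueError("training set needs at least 2 classes")


def build_training(
    normalized: ad.AnnData,
    labels: pd.Series | np.ndarray,
    panel: list[str],
    scheme: str = "unit",
) -> TrainingSet:
    """Extract and normalize per-cell panel vectors.

    ``labels`` gives each cell's subtype (cluster identity); all-zero
    panel vectors are dropped and counted in ``n_dropped``.
    """
    missing = [t for t in panel if t not in normalized.var_names]
    if missing:
        raise ValueError(f"panel transcripts absent from gene set: {missing}")
    V = np.asarray(normalized[:, list(panel)].X, dtype=float)
    y = np.asarray(labels)
    if y.shape[0] != V.shape[0]:
        raise ValueError("labels must align with cells")
    out, keep = _normalize_vectors(V, scheme)
    return TrainingSet(
        vectors=out,
        labels=y[keep],
        panel=tuple(panel),
        scheme=scheme,
        n_dropped=int((~keep).sum()),
    )


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote KNN with a deterministic tie-break chain.

    Ties on the vote are broken by the smallest summed neighbor distance
    among tied classes, then by the smallest label. Returns
    ``(predicted_labels, vote_fractions)``.
    """
    if k > train_X.shape[0]:
        raise ValueError("k exceeds the training-set size")
    classes, y_idx = np.unique(train_y, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=k).fit(train_X)
    dist, idx = nn.kneighbors(query)
    neigh = y_idx[idx]  # (n_query, k)
    n_q, n_c = query.shape[0], classes.size
    votes = np.zeros((n_q, n_c))
    dsum = np.zeros((n_q, n_c))
    rows = np.repeat(np.arange(n_q), k)
    np.add.at(votes, (rows, neigh.ravel()), 1.0)
    np.add.at(dsum, (rows, neigh.ravel()), dist.ravel())
    max_votes = votes.max(axis=1, keepdims=True)
    tied = votes == max_votes
    # among tied classes prefer the smallest summed distance, then label order
    dsum_masked = np.where(tied, dsum, np.inf)
    winner = dsum_masked.argmin(axis=1)
    return classes[winner], (max_votes.ravel() / k)


def select_k_cv(
    training: TrainingSet,
    k_grid: list[int] | None = None,
    folds: int = 6,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Choose K by stratified cross-validated accuracy.

    Accuracy per K is the mean over folds of the correctly classified
    fraction; the best K is the argmax, ties going to the smallest K.
    K values not smaller than the training size are rejected. Returns
    ``(best_k, mean_accuracy_per_k)``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if k_grid is None:
        k_grid = [25]
    _, class_counts = np.unique(training.labels, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    valid = [k for k in k_grid if 0 < k < training.n_cells]
    if not valid:
        raise ValueError("no valid K in k_grid")
    # canonicalize row order so CV folds do not depend on how the
    # training set happened to be assembled
    key = np.lexsort(
        tuple(training.vectors.T) + (training.labels.astype(str),)
    )
    X, y = training.vectors[key], training.labels[key]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = {k: [] for k in valid}
    for train_idx, test_idx in skf.split(X, y):
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        for k in valid:
            kk = min(k, Xtr.shape[0])
            pred, _ = knn_predict(Xtr, ytr, Xte, kk)
            acc[k].append(float((pred == yte).mean()))
    mean_acc = pd.Series({k: float(np.mean(v)) for k, v in acc.items()}).sort_index()
    best_k = int(mean_acc.index[mean_acc.to_numpy().argmax()])
    # ties -> smallest K
    best = mean_acc.max()
    best_k = int(min(k for k, v in mean_acc.items() if v == best))
    return best_k, mean_acc


@dataclass(frozen=True)
class SubtypeMap:
    """Predicted subtype per in-boundary tile of one section."""

    section_index: int
    assignments: pd.DataFrame  # tile center um, label, vote fraction
    k: int
    boundary: BoundaryMask


def predict_tiles(
    training: TrainingSet,
    grid: TileGrid,
    boundary: BoundaryMask,
    k: int = 25,
) -> SubtypeMap:
    """Classify every tile whose center lies inside the pontine boundary.

    Tile panel vectors (cross-section normalized) are re-normalized by the
    training scheme; all-zero tiles are labeled ``"unassigned"``.
    """
    if grid.normalized is None:
        raise ValueError("tile grid must be normalized across sections first")
    if k > training.n_cells:
        raise ValueError("k exceeds the training-set size")
    order = [grid.transcripts.index(t) for t in training.panel]
    V = grid.normalized[:, order]
    cy = (grid.tiles["center_y_um"] / grid.pixel_size_um).to_numpy().astype(int)
    cx = (grid.tiles["center_x_um"] / grid.pixel_size_um).to_numpy().astype(int)
    cy = np.clip(cy, 0, boundary.mask.shape[0] - 1)
    cx = np.clip(cx, 0, boundary.mask.shape[1] - 1)
    inside = boundary.mask[cy, cx]

    sub = V[inside]
    normed, keep = _normalize_vectors(sub, training.scheme)
    labels = np.full(sub.shape[0], "unassigned", dtype=object)
    votes = np.full(sub.shape[0], np.nan)
    if normed.shape[0]:
        pred, frac = knn_predict(training.vectors, training.labels, normed, k)
        labels[keep] = pred
        votes[keep] = frac
    assignments = grid.tiles.loc[inside, ["tile_row", "tile_col", "center_y_um", "center_x_um"]].copy()
    assignments["subtype"] = labels
    assignments["vote_fraction"] = votes
    return SubtypeMap(
        section_index=grid.section_index,
        assignments=assignments.reset_index(drop=True),
        k=k,
        boundary=boundary,
    )
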
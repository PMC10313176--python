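"""Quantification of multiplexed ISH images in physical-unit tiles,
cross-section normalization, pontine boundary detection, and Manders
colocalization.

Images are max-projected over z, binned into 34 um x 31 um tiles
(width x height) whose values are mean pixel intensities, and each
transcript is normalized by its maximum tile value across all imaged
sections, so normalized expression spans [0, 1] over the section series.
The pontine boundary is segmented from the across-transcript maximum by
Gaussian smoothing (SD 35 um), mean thresholding, morphological closing
with a 5 um x 5 um structuring element, and keeping the largest connected
region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label
from skimage.morphology import closing

from .synthetic_data import ISHStack

DEFAULT_TILE_H_UM = 31.0
DEFAULT_TILE_W_UM = 34.0


def max_project(stack: ISHStack | np.ndarray) -> np.ndarray:
    """Pixelwise maximum-intensity projection over z."""
    vox = stack.voxels if isinstance(stack, ISHStack) else np.asarray(stack)
    if vox.ndim != 3 or vox.shape[0] < 1:
        raise ValueError("need a non-empty (z, y, x) stack")
    return vox.max(axis=0)


@dataclass(frozen=True)
class TileGrid:
    """Per-section tile grid with raw (and optionally normalized) values.

    ``tiles`` has one row per tile: pixel bounds (half-open), physical
    center (um, y down / x right from the image top-left) and a
    ``partial`` flag for ragged right/bottom remainder tiles. ``raw`` and
    ``normalized`` are (n_tiles, n_transcripts) arrays.
    """

    section_index: int
    transcripts: tuple[str, ...]
    tiles: pd.DataFrame
    raw: np.ndarray
    pixel_size_um: float
    tile_h_um: float = DEFAULT_TILE_H_UM
    tile_w_um: float = DEFAULT_TILE_W_UM
    normalized: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per tile with per-transcript columns."""
        out = self.tiles.copy()
        for k, t in enumerate(self.transcripts):
            out[f"raw_{t}"] = self.raw[:, k]
            if self.normalized is not None:
                out[f"norm_{t}"] = self.normalized[:, k]
        return out


def tile_expression(
    images: dict[str, np.ndarray],
    pixel_size_um: float,
    tile_h_um: float = DEFAULT_TILE_H_UM,
    tile_w_um: float = DEFAULT_TILE_W_UM,
    section_index: int = 0,
) -> TileGrid:
    """Bin per-transcript images into physical-unit tiles of mean intensity.

    Tile size in pixels is ``round(tile_um / pixel_size_um)`` per axis.
    Remainder tiles at the right/bottom edges are retained and flagged
    ``partial``.
    """
    if not images:
        raise ValueError("need at least one transcript image")
    transcripts = tuple(images)
    shapes = {images[t].shape for t in transcripts}
    if len(shapes) != 1:
        raise ValueError("all transcript images must share a shape")
    (ny, nx) = shapes.pop()
    th = int(round(tile_h_um / pixel_size_um))
    tw = int(round(tile_w_um / pixel_size_um))
    if th < 1 or tw < 1:
        raise ValueError("tile smaller than one pixel")

    y_edges = list(range(0, ny, th)) + [ny]
    x_edges = list(range(0, nx, tw)) + [nx]
    y_edges = sorted(set(y_edges))
    x_edges = sorted(set(x_edges))

    rows = []
    values = []
    arrays = [np.asarray(images[t], dtype=float) for t in transcripts]
    for r in range(len(y_edges) - 1):
        y0, y1 = y_edges[r], y_edges[r + 1]
        for c in range(len(x_edges) - 1):
            x0, x1 = x_edges[c], x_edges[c + 1]
            partial = (y1 - y0 != th) or (x1 - x0 != tw)
            rows.append(
                {
                    "tile_row": r,
                    "tile_col": c,
                    "y0": y0,
                    "y1": y1,
                    "x0": x0,
                    "x1": x1,
                    "center_y_um": (y0 + y1) / 2 * pixel_size_um,
                    "center_x_um": (x0 + x1) / 2 * pixel_size_um,
                    "n_pixels": (y1 - y0) * (x1 - x0),
                    "partial": partial,
                }
            )
            values.append([a[y0:y1, x0:x1].mean() for a in arrays])
    return TileGrid(
        section_index=section_index,
        transcripts=transcripts,
        tiles=pd.DataFrame(rows),
        raw=np.asarray(values, dtype=float),
        pixel_size_um=pixel_size_um,
        tile_h_um=tile_h_um,
        tile_w_um=tile_w_um,
    )


def normalize_across_sections(
    grids: list[TileGrid], include_partial: bool = False
) -> list[TileGrid]:
    """Divide each transcript by its maximum tile value over all sections.

    Partial edge tiles are excluded from the maximum by default (their
    means are noisy) but are themselves normalized. An all-zero transcript
    stays all-zero.
    """
    if not grids:
        raise ValueError("need at least one tile grid")
    panel = grids[0].transcripts
    if any(g.transcripts != panel for g in grids):
        raise ValueError("all grids must share the transcript panel")
    full = [
        g.raw if include_partial else g.raw[~g.tiles["partial"].to_numpy()]
        for g in grids
    ]
    stacked = np.vstack([f for f in full if f.size] or [np.zeros((1, len(panel)))])
    divisor = stacked.max(axis=0)
    divisor[divisor == 0] = 1.0
    return [replace(g, normalized=g.raw / divisor) for g in grids]


@dataclass(frozen=True)
class BoundaryMask:
    """Pontine boundary of one section: mask, edge pixels, physical area."""

    section_index: int
    mask: np.ndarray  # bool, single connected foreground region
    boundary: np.ndarray  # bool, edge of that region
    area_um2: float

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.boundary.dtype != bool:
            raise ValueError("mask and boundary must be boolean")
        if (self.boundary & ~self.mask).any():
            raise ValueError("boundary must be a subset of the mask")


def detect_boundary(
    images: dict[str, np.ndarray],
    pixel_size_um: float,
    smooth_sigma_um: float = 35.0,
    closing_um: float = 5.0,
    section_index: int = 0,
) -> BoundaryMask:
    """Segment the pontine region from the per-transcript images.

    Pipeline: pixelwise maximum across transcripts; Gaussian blur with
    ``smooth_sigma_um``; strict mean thresholding; morphological closing
    with a rectangular ``closing_um`` structuring element (at least 1 px);
    largest 8-connected component. The boundary is the set of foreground
    pixels with at least one 4-connected background neighbor (the image
    border counts as background).
    """
    if not images:
        raise ValueError("need at least one transcript image")
    stack = np.stack([np.asarray(v, dtype=float) for v in images.values()])
    composite = stack.max(axis=0)
    blurred = gaussian_filter(composite, smooth_sigma_um / pixel_size_um, mode="reflect")
    binary = blurred > blurred.mean()
    if not binary.any():
        raise ValueError("constant image: no pixel exceeds the mean")
    side = max(1, int(round(closing_um / pixel_size_um)))
    closed = closing(binary, footprint=np.ones((side, side), dtype=bool))
    comps = cc_label(closed, connectivity=2)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    mask = comps == sizes.argmax()

    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    area = float(mask.sum()) * pixel_size_um**2
    return BoundaryMask(
        section_index=section_index, mask=mask, boundary=boundary, area_um2=area
    )


def manders_overlap(
    image_a: np.ndarray, image_b: np.ndarray, threshold_b: float
) -> float:
    """Manders M1: fraction of channel-A intensity where B exceeds threshold.

    Defined as 0 when channel A carries no intensity.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if threshold_b < 0:
        raise ValueError("threshold_b must be >= 0")
    total = a.sum()
    if total == 0:
        return 0.0
    return float(a[b > threshold_b].sum() / total)
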
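"""Plain-text and TIFF interchange for the pipeline's data objects.

Counts travel as Matrix Market (.mtx) plus TSV sidecars (cells.tsv,
genes.tsv); ISH stacks as multi-page TIFF per (section, transcript) with a
JSON sidecar recording pixel size, z-step and section order; tile grids
and result tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .synthetic_data import ISHStack


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + cells.tsv + genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(np.asarray(adata.X)))
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read the matrix.mtx + TSV sidecar dialect written by write_counts."""
    indir = Path(indir)
    X = spio.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    for col in ("true_state", "true_subtype"):
        if col in obs:
            obs[col] = obs[col].where(obs[col].notna(), None)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_stacks(stacks: list[ISHStack], outdir: str | Path) -> None:
    """One multi-page TIFF per (section, transcript) plus metadata.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in stacks:
        name = f"section{s.section_index:02d}_{s.transcript_id}.tif"
        tifffile.imwrite(outdir / name, s.voxels.astype(np.float32))
        meta.append(
            {
                "file": name,
                "section_index": s.section_index,
                "transcript_id": s.transcript_id,
                "pixel_size_um": list(s.pixel_size_um),
                "z_step_um": s.z_step_um,
            }
        )
    (outdir / "metadata.json").write_text(json.dumps({"stacks": meta}, indent=1))


def read_stacks(indir: str | Path) -> list[ISHStack]:
    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    out = []
    for m in meta["stacks"]:
        vox = tifffile.imread(indir / m["file"]).astype(float)
        if vox.ndim == 2:
            vox = vox[None]
        out.append(
            ISHStack(
                section_index=m["section_index"],
                transcript_id=m["transcript_id"],
                voxels=vox,
                pixel_size_um=tuple(m["pixel_size_um"]),
                z_step_um=m["z_step_um"],
            )
        )
    return out


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))
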
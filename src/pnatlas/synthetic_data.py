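"""Seeded synthetic scRNA-seq counts and multiplexed ISH image stacks.

Every output is a pure function of the :class:`~pnatlas.config.SyntheticConfig`
seed. Counts follow a gamma-Poisson (negative binomial) model with a shared
dispersion; cells are assigned to states/subtypes by per-replicate
multinomial draws whose probabilities carry logistic-normal jitter; marker
genes of a cell's group are elevated ``2**marker_log2fc``-fold. ISH stacks
render Gaussian spots at a density proportional to the local subtype's
panel signature, on top of clipped Gaussian background noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .config import (
    PANEL,
    STATE_NAMED_MARKERS,
    STATES,
    SUBTYPE_PANEL_MARKERS,
    SUBTYPES,
    ImageConfig,
    SyntheticConfig,
    child_rng,
)

# fixed stream keys for seed derivation
_STREAM_GENES = 0
_STREAM_CELLS = 1
_STREAM_IMAGE = 2
_STREAM_ANNOTATION = 3

#: relative base weight of panel transcripts (well-detected selective
#: markers) and of the pan-PN transcript, in units of the median gene.
_PANEL_BASE_WEIGHT = 6.0
_PAN_BASE_WEIGHT = 8.0


@dataclass(frozen=True)
class ISHStack:
    """One z-stack: a single transcript imaged in a single section."""

    section_index: int
    transcript_id: str
    voxels: np.ndarray  # (z, y, x), non-negative
    pixel_size_um: tuple[float, float]  # (dy, dx)
    z_step_um: float

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a (z, y, x) array")
        if self.pixel_size_um[0] <= 0 or self.pixel_size_um[1] <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be >= 0")


def _gene_model(config: SyntheticConfig):
    """Gene identities, base weights, and per-group marker index sets.

    Gene-level randomness depends only on the configuration seed, never on
    the genotype, so all datasets drawn from one config share a genome.
    """
    rng = child_rng(config.seed, _STREAM_GENES)
    n = config.n_genes
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n)

    names = np.array([f"gene_{i:04d}" for i in range(n)], dtype=object)
    groups = list(STATES) + list(SUBTYPES)
    marker_of = np.full(n, None, dtype=object)

    # marker blocks occupy the front of the gene list; panel transcripts and
    # classic stage markers provide the named members of each block.
    pos = 0
    marker_idx: dict[str, np.ndarray] = {}
    for group in groups:
        idx = np.arange(pos, pos + config.n_marker_genes_per_group)
        marker_idx[group] = idx
        marker_of[idx] = group
        pos += config.n_marker_genes_per_group
    for state, name in STATE_NAMED_MARKERS.items():
        names[marker_idx[state][0]] = name
    for subtype, panel_names in SUBTYPE_PANEL_MARKERS.items():
        for j, name in enumerate(panel_names):
            gi = marker_idx[subtype][j]
            names[gi] = name
            weights[gi] = _PANEL_BASE_WEIGHT
    # the pan-PN panel transcript is not a marker of any subtype
    pan_i = pos
    names[pan_i] = "Cdh8"
    weights[pan_i] = _PAN_BASE_WEIGHT
    pos += 1

    # mitochondrial genes: a small, fixed share of every library
    n_mito = int(round(config.mito_gene_fraction * n))
    mito_idx = np.arange(pos, pos + n_mito)
    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito_idx] = True
    for k, gi in enumerate(mito_idx):
        names[gi] = f"mt-gene_{k:02d}"
    if n_mito and config.mito_share > 0:
        w_m = weights[mito_idx].sum()
        w_rest = weights.sum() - w_m
        target = config.mito_share
        weights[mito_idx] *= (target / (1.0 - target)) * w_rest / w_m

    var = pd.DataFrame(
        {"is_mito": is_mito, "marker_of": marker_of},
        index=pd.Index(names, name="gene"),
    )
    return weights, var, marker_idx


def sample_group_counts(
    rng: np.random.Generator,
    proportions: np.ndarray,
    n_cells: int,
    logit_sd: float,
) -> np.ndarray:
    """Multinomial group counts for one replicate with logistic-normal jitter.

    Zero-probability groups stay at exactly zero regardless of jitter.
    """
    p = np.asarray(proportions, dtype=float)
    if logit_sd > 0:
        live = p > 0
        z = np.log(p[live]) + rng.normal(0.0, logit_sd, size=live.sum())
        q = np.zeros_like(p)
        q[live] = np.exp(z - z.max())
        p = q / q.sum()
    return rng.multinomial(n_cells, p)


def simulate_counts(config: SyntheticConfig, genotype: str) -> ad.AnnData:
    """Simulate one genotype's cells-by-genes count matrix.

    Returns an :class:`anndata.AnnData` with integer counts in ``X``,
    per-cell metadata (``replicate``, ``genotype``, ``true_state``,
    ``true_subtype``) in ``obs`` and gene metadata (``is_mito``,
    ``marker_of``) in ``var``.
    """
    if genotype not in config.state_proportions:
        raise ValueError(
            f"genotype {genotype!r} has no state_proportions entry "
            f"(known: {sorted(config.state_proportions)})"
        )
    weights, var, marker_idx = _gene_model(config)
    genotype_index = list(config.state_proportions).index(genotype)
    state_p = np.asarray(config.state_proportions[genotype], dtype=float)
    subtype_p = np.asarray(config.subtype_proportions, dtype=float)
    lfc_factor = 2.0 ** config.marker_log2fc

    blocks = []
    obs_frames = []
    for rep in range(config.n_replicates_per_genotype):
        rng = child_rng(config.seed, _STREAM_CELLS, genotype_index, rep)
        n_cells = config.n_cells_per_replicate

        true_state = np.full(n_cells, None, dtype=object)
        true_subtype = np.full(n_cells, None, dtype=object)
        if config.dataset_style in ("E14.5", "E18.5"):
            counts_per_state = sample_group_counts(
                rng, state_p, n_cells, config.replicate_logit_sd
            )
            true_state = np.repeat(np.array(STATES, dtype=object), counts_per_state)
            rng.shuffle(true_state)
            if config.dataset_style == "E18.5":
                diff = true_state == "differentiated"
                n_diff = int(diff.sum())
                counts_per_subtype = rng.multinomial(n_diff, subtype_p)
                labels = np.repeat(np.array(SUBTYPES, dtype=object), counts_per_subtype)
                rng.shuffle(labels)
                true_subtype[diff] = labels
        else:  # P5: terminal subtypes only
            counts_per_subtype = sample_group_counts(
                rng, subtype_p, n_cells, config.replicate_logit_sd
            )
            true_subtype = np.repeat(np.array(SUBTYPES, dtype=object), counts_per_subtype)
            rng.shuffle(true_subtype)

        w = np.tile(weights, (n_cells, 1))
        for group, idx in marker_idx.items():
            if group in STATES:
                cells = np.flatnonzero(true_state == group)
            else:
                cells = np.flatnonzero(true_subtype == group)
            if cells.size:
                w[np.ix_(cells, idx)] *= lfc_factor

        # optional spiked cells with an elevated mitochondrial share
        n_spike = int(round(config.mito_spike_fraction * n_cells))
        if n_spike:
            mito = var["is_mito"].to_numpy()
            odds = (config.mito_spike_share / (1 - config.mito_spike_share)) / (
                config.mito_share / (1 - config.mito_share)
            )
            spike_cells = rng.choice(n_cells, size=n_spike, replace=False)
            w[np.ix_(spike_cells, np.flatnonzero(mito))] *= odds

        p = w / w.sum(axis=1, keepdims=True)
        lib = rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, n_cells)
        mu = lib[:, None] * p
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu * config.nb_dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam)
        blocks.append(counts)
        obs_frames.append(
            pd.DataFrame(
                {
                    "replicate": f"{genotype}_rep{rep}",
                    "genotype": genotype,
                    "true_state": true_state,
                    "true_subtype": true_subtype,
                }
            )
        )

    obs = pd.concat(obs_frames, ignore_index=True)
    obs.index = pd.Index(
        [f"{genotype}_c{i:06d}" for i in range(len(obs))], name="cell"
    )
    adata = ad.AnnData(
        X=np.vstack(blocks).astype(np.int64), obs=obs, var=var.copy()
    )
    return adata


def simulate_dataset(config: SyntheticConfig) -> ad.AnnData:
    """Concatenate all genotypes of one config into a single AnnData."""
    parts = [simulate_counts(config, g) for g in config.state_proportions]
    if len(parts) == 1:
        return parts[0]
    joined = ad.concat(parts, join="outer", merge="same")
    joined.var = parts[0].var.copy()
    return joined


def ish_signature(config: SyntheticConfig) -> pd.DataFrame:
    """Panel-transcript intensity signature per subtype.

    Mirrors the count model: a transcript selective for a subtype is
    ``2**marker_log2fc``-fold elevated in its territory; the pan-PN
    transcript is uniformly elevated by ``image.pan_signature``.
    """
    sig = pd.DataFrame(1.0, index=pd.Index(PANEL, name="transcript"), columns=SUBTYPES)
    for subtype, markers in SUBTYPE_PANEL_MARKERS.items():
        for m in markers:
            sig.loc[m, subtype] = 2.0 ** config.marker_log2fc
    sig.loc["Cdh8", :] = config.image.pan_signature
    return sig


def _rect_to_px(
    rect: tuple[float, float, float, float], pixel_size: float, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    y0, y1, x0, x1 = rect
    return (
        max(0, int(round(y0 / pixel_size))),
        min(shape[0], int(round(y1 / pixel_size))),
        max(0, int(round(x0 / pixel_size))),
        min(shape[1], int(round(x1 / pixel_size))),
    )


def territory_masks(image: ImageConfig) -> dict[str, np.ndarray]:
    """Ground-truth territory masks in pixel coordinates (one per subtype)."""
    shape = image.shape_px
    masks: dict[str, np.ndarray] = {}
    for subtype, rect in image.territories():
        m = masks.setdefault(subtype, np.zeros(shape, dtype=bool))
        py0, py1, px0, px1 = _rect_to_px(rect, image.pixel_size_um, shape)
        m[py0:py1, px0:px1] = True
    return masks


def simulate_ish_stacks(
    config: SyntheticConfig,
) -> tuple[list[ISHStack], dict[str, np.ndarray]]:
    """Render the multiplexed ISH stacks plus ground-truth territory masks.

    For each section and each panel transcript, spots are drawn at a
    Poisson rate ``spot_density_per_um2 * signature`` inside each subtype
    territory, deposited into a random z-slice, blurred with a Gaussian of
    ``spot_sigma_um``, and clipped Gaussian background noise is added. A
    ``TdTom`` reporter stack covering the union of territories is appended.

    Returns ``(stacks, masks)`` where ``masks`` maps each subtype to its
    boolean pixel mask, plus key ``"union"``.
    """
    from scipy.ndimage import gaussian_filter

    image = config.image
    territories = image.territories()
    for _, (y0, y1, x0, x1) in territories:
        h, w = image.field_size_um
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w or y1 <= y0 or x1 <= x0:
            raise ValueError(f"territory {(y0, y1, x0, x1)} lies outside the field")

    shape = image.shape_px
    sig = ish_signature(config)
    sigma_px = image.spot_sigma_um / image.pixel_size_um
    masks = territory_masks(image)
    masks["union"] = np.logical_or.reduce(list(masks.values())) if masks else np.zeros(
        shape, dtype=bool
    )

    channels = list(PANEL) + ["TdTom"]
    stacks: list[ISHStack] = []
    for section in range(image.n_sections):
        rng = child_rng(config.seed, _STREAM_IMAGE, section)
        for transcript in channels:
            vox = np.zeros((image.n_z,) + shape, dtype=np.float32)
            for subtype, rect in territories:
                y0, y1, x0, x1 = rect
                area = (y1 - y0) * (x1 - x0)
                density = image.spot_density_per_um2 * (
                    image.pan_signature
                    if transcript == "TdTom"
                    else float(sig.loc[transcript, subtype])
                )
                n_spots = rng.poisson(density * area)
                if n_spots == 0:
                    continue
                ys = rng.uniform(y0, y1, n_spots) / image.pixel_size_um
                xs = rng.uniform(x0, x1, n_spots) / image.pixel_size_um
                zs = rng.integers(0, image.n_z, n_spots)
                yi = np.clip(ys.astype(int), 0, shape[0] - 1)
                xi = np.clip(xs.astype(int), 0, shape[1] - 1)
                np.add.at(vox, (zs, yi, xi), image.spot_intensity)
            for z in range(image.n_z):
                vox[z] = gaussian_filter(vox[z], sigma_px, mode="reflect")
            if image.background_sd > 0:
                vox += rng.normal(0.0, image.background_sd, vox.shape)
            np.clip(vox, 0.0, None, out=vox)
            stacks.append(
                ISHStack(
                    section_index=section,
                    transcript_id=transcript,
                    voxels=vox,
                    pixel_size_um=(image.pixel_size_um, image.pixel_size_um),
                    z_step_um=image.z_step_um,
                )
            )
    return stacks, masks


def simulate_binding_annotation(
    counts: ad.AnnData,
    planted_degs: set[str] | list[str],
    enrichment_odds: float,
    background_peak_rate: float = 0.2,
    seed: int = 0,
) -> pd.Series:
    """Gene -> has_peak annotation with a planted DEG/peak odds ratio.

    The peak probability of planted DEGs is set so the population odds
    ratio against background genes equals ``enrichment_odds``.
    """
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    genes = counts.var_names
    planted = set(planted_degs)
    unknown = planted - set(genes)
    if unknown:
        raise ValueError(f"planted DEGs not in gene set: {sorted(unknown)[:5]}")
    p0 = background_peak_rate
    odds1 = enrichment_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    rng = child_rng(seed, _STREAM_ANNOTATION)
    prob = np.where(np.isin(genes, list(planted)), p1, p0)
    return pd.Series(rng.random(len(genes)) < prob, index=genes, name="has_peak")
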
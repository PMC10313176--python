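"""Configuration objects for the synthetic pontine-nucleus study.

The generator emulates the statistical structure of a developmental
single-cell study of pontine nuclei (PN) neurons: five cell states along
the differentiation trajectory at embryonic stages, six terminal PN
subtypes postnatally, a genotype-dependent shift of the state composition
in the *Atoh1* hypomorph, and a nine-transcript multiplexed RNA-ISH panel
whose territories tile the pons in physical (micrometer) units.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Cell states along the PN differentiation trajectory (rostral-lip exit order).
STATES: tuple[str, ...] = (
    "progenitor",
    "intermediate_progenitor",
    "migrating_1",
    "migrating_2",
    "differentiated",
)

#: Terminal PN subtypes resolved at P5.
SUBTYPES: tuple[str, ...] = ("PN1", "PN2", "PN3", "PN4", "PN5", "PN6")

#: The nine-transcript ISH panel. Names are labels only; no sequence content.
PANEL: tuple[str, ...] = (
    "Sst",
    "Ntng1",
    "Prox1",
    "Ephb1",
    "Cdkn1c",
    "Hoxb5",
    "Slc17a6",
    "Etv1",
    "Cdh8",
)

#: Panel transcripts selectively elevated in each subtype. Cdh8 is the
#: pan-PN transcript and belongs to no subtype.
SUBTYPE_PANEL_MARKERS: dict[str, tuple[str, ...]] = {
    "PN1": ("Sst", "Ntng1"),
    "PN2": ("Prox1", "Ephb1"),
    "PN3": ("Cdkn1c",),
    "PN4": ("Hoxb5",),
    "PN5": ("Slc17a6",),
    "PN6": ("Etv1",),
}

#: Named first marker per state (classic stage markers).
STATE_NAMED_MARKERS: dict[str, str] = {
    "progenitor": "Ccnd1",
    "intermediate_progenitor": "Atoh1",
    "migrating_1": "Nhlh1",
    "migrating_2": "Nhlh2",
    "differentiated": "Mapt",
}

#: E14.5-stage state composition per genotype. The progenitor fraction
#: rises 9.3% -> 31% and migrating-2 falls 29.3% -> 19.7% in the mutant;
#: the intermediate-progenitor share is unchanged.
E14_STATE_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "control": (0.093, 0.150, 0.300, 0.293, 0.164),
    "mutant": (0.310, 0.150, 0.243, 0.197, 0.100),
}

#: E18.5-stage composition: mostly differentiated neurons with small
#: residual progenitor/migratory pools.
E18_STATE_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "control": (0.030, 0.040, 0.060, 0.080, 0.790),
    "mutant": (0.060, 0.040, 0.055, 0.065, 0.780),
}

#: Terminal subtype shares at P5; PN5 and PN6 are the smallest populations.
DEFAULT_SUBTYPE_PROPORTIONS: tuple[float, ...] = (0.24, 0.21, 0.18, 0.17, 0.11, 0.09)


def _check_proportions(name: str, p: tuple[float, ...], n: int) -> None:
    if len(p) != n:
        raise ValueError(f"{name} must have {n} entries, got {len(p)}")
    if any(x < 0 for x in p):
        raise ValueError(f"{name} entries must be non-negative")
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(p)!r})")


@dataclass(frozen=True)
class ImageConfig:
    """Geometry and noise model of the synthetic multiplexed ISH stacks.

    All physical quantities are micrometers. ``field_size_um`` is
    (height, width) with y increasing downward from the image top-left,
    matching image-array convention.
    """

    pixel_size_um: float = 2.0
    field_size_um: tuple[float, float] = (700.0, 1000.0)
    n_z: int = 10
    z_step_um: float = 0.9
    n_sections: int = 5
    #: (subtype, (y0, y1, x0, x1) in um) rectangles, applied to every section.
    territory_spec: tuple[tuple[str, tuple[float, float, float, float]], ...] | None = None
    spot_intensity: float = 40.0
    spot_sigma_um: float = 3.0
    #: expected spots per um^2 at unit panel signature.
    spot_density_per_um2: float = 0.02
    background_sd: float = 1.0
    #: intensity signature of the pan-PN transcript relative to base.
    pan_signature: float = 1.5

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_z < 1 or self.n_sections < 1:
            raise ValueError("n_z and n_sections must be >= 1")
        if self.spot_intensity <= 0:
            raise ValueError("spot_intensity must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")

    def territories(self) -> tuple[tuple[str, tuple[float, float, float, float]], ...]:
        """Territory rectangles; defaults to a 2 x 3 grid of the six subtypes."""
        if self.territory_spec is not None:
            return self.territory_spec
        return default_territories(self.field_size_um)

    @property
    def shape_px(self) -> tuple[int, int]:
        h, w = self.field_size_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))


def default_territories(
    field_size_um: tuple[float, float],
    margin_um: float = 120.0,
    gap_um: float = 20.0,
) -> tuple[tuple[str, tuple[float, float, float, float]], ...]:
    """Six rectangular subtype territories arranged in a 2 x 3 grid."""
    h, w = field_size_um
    inner_h = h - 2 * margin_um
    inner_w = w - 2 * margin_um
    cell_h = (inner_h - gap_um) / 2
    cell_w = (inner_w - 2 * gap_um) / 3
    out = []
    for i, subtype in enumerate(SUBTYPES):
        r, c = divmod(i, 3)
        y0 = margin_um + r * (cell_h + gap_um)
        x0 = margin_um + c * (cell_w + gap_um)
        out.append((subtype, (y0, y0 + cell_h, x0, x0 + cell_w)))
    return tuple(out)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the synthetic scRNA-seq + ISH study.

    The defaults are the standard study conditions: negative-binomial
    (gamma-Poisson) counts with a shared dispersion, log-normal library
    sizes, ten marker genes per group elevated ``2**marker_log2fc``-fold,
    mitochondrial genes holding a sub-1% share of each library, and a
    logistic-normal between-replicate jitter of the composition.
    """

    seed: int = 0
    n_cells_per_replicate: int = 2000
    n_replicates_per_genotype: int = 3
    n_genes: int = 2000
    n_marker_genes_per_group: int = 10
    state_proportions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(E14_STATE_PROPORTIONS)
    )
    subtype_proportions: tuple[float, ...] = DEFAULT_SUBTYPE_PROPORTIONS
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size_log_mean: float = math.log(6000.0)
    library_size_log_sd: float = 0.25
    mito_gene_fraction: float = 0.02
    #: expected mitochondrial share of a normal cell's library.
    mito_share: float = 0.004
    #: fraction of cells per replicate spiked to a >1% mitochondrial share.
    mito_spike_fraction: float = 0.0
    mito_spike_share: float = 0.03
    #: SD of the logistic-normal jitter applied to per-replicate composition.
    replicate_logit_sd: float = 0.1
    #: which ground-truth labels cells carry: "E14.5" (states only),
    #: "P5" (subtypes only) or "E18.5" (states; differentiated cells also
    #: carry subtypes).
    dataset_style: str = "E14.5"
    image: ImageConfig = field(default_factory=ImageConfig)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.dataset_style not in ("E14.5", "E18.5", "P5"):
            raise ValueError(f"unknown dataset_style {self.dataset_style!r}")
        for genotype, props in self.state_proportions.items():
            _check_proportions(f"state_proportions[{genotype!r}]", tuple(props), len(STATES))
        _check_proportions("subtype_proportions", tuple(self.subtype_proportions), len(SUBTYPES))
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ValueError("mito_gene_fraction must be in [0, 1]")
        n_groups = len(STATES) + len(SUBTYPES)
        if self.n_marker_genes_per_group * n_groups > self.n_genes:
            raise ValueError(
                "n_marker_genes_per_group x number of groups exceeds n_genes"
            )

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def p5_config(seed: int = 0, n_cells_per_replicate: int = 3500) -> SyntheticConfig:
    """The standard P5-style fixture: two pooled replicates, six subtypes,
    about 7000 cells in total."""
    return SyntheticConfig(
        seed=seed,
        n_cells_per_replicate=n_cells_per_replicate,
        n_replicates_per_genotype=2,
        state_proportions={"control": (0.0, 0.0, 0.0, 0.0, 1.0)},
        dataset_style="P5",
    )


def e18_config(seed: int = 0, n_cells_per_replicate: int = 1200) -> SyntheticConfig:
    """E18.5-style fixture: states plus subtypes on differentiated cells."""
    return SyntheticConfig(
        seed=seed,
        n_cells_per_replicate=n_cells_per_replicate,
        state_proportions=dict(E18_STATE_PROPORTIONS),
        dataset_style="E18.5",
    )


def load_config(path: str | Path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a TOML file.

    Top-level keys map to config fields; an optional ``[image]`` table maps
    to :class:`ImageConfig`. ``state_proportions`` is a table of
    genotype -> list.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    image_raw = raw.pop("image", None)
    if "state_proportions" in raw:
        raw["state_proportions"] = {
            g: tuple(v) for g, v in raw["state_proportions"].items()
        }
    if "subtype_proportions" in raw:
        raw["subtype_proportions"] = tuple(raw["subtype_proportions"])
    if image_raw is not None:
        if "field_size_um" in image_raw:
            image_raw["field_size_um"] = tuple(image_raw["field_size_um"])
        if "territory_spec" in image_raw:
            image_raw["territory_spec"] = tuple(
                (s, tuple(r)) for s, r in image_raw["territory_spec"]
            )
        raw["image"] = ImageConfig(**image_raw)
    return SyntheticConfig(**raw)


def child_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic child generator for stream ``spawn_key`` of ``seed``.

    Independent streams (genes, per-replicate cells, per-section images,
    annotations) use fixed integer spawn keys so that every output is a
    pure function of the configuration seed.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))
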
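"""Per-state genotype differential expression and transcription-factor
binding-target enrichment.

Genes detected in at least ``min_pct`` of cells of either genotype are
compared by a two-sample Wilcoxon rank-sum test on log-normalized values;
p-values are BH-corrected. DEGs pass |log2FC| > 0.25 and FDR < 0.05
(strict inequalities). Enrichment of DEGs among annotated binding targets
uses Fisher's exact test with a conditional-MLE odds ratio, exact 95% CI,
and Bonferroni adjustment over the tested cell states.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .sc_pipeline import rank_sum_de


def de_test(
    normalized: ad.AnnData,
    state: str,
    min_pct: float = 0.10,
    state_col: str = "true_state",
    genotype_col: str = "genotype",
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Mutant-vs-control differential expression within one cell state.

    ``groups`` orders the contrast as (test, reference); by default the
    second genotype in the metadata (typically the mutant) is tested
    against the first. Returns one row per tested gene with log2FC,
    expressing fractions, raw p and FDR.
    """
    meta = normalized.obs
    in_state = meta[state_col].to_numpy() == state
    geno = meta[genotype_col].to_numpy()
    if groups is None:
        uniq = pd.unique(geno)
        if len(uniq) != 2:
            raise ValueError(f"expected 2 genotypes, found {len(uniq)}")
        groups = (uniq[1], uniq[0])
    test_g, ref_g = groups
    sel_test = in_state & (geno == test_g)
    sel_ref = in_state & (geno == ref_g)
    if sel_test.sum() < 3 or sel_ref.sum() < 3:
        raise ValueError(
            f"state {state!r} needs >= 3 cells in both genotypes "
            f"(got {int(sel_test.sum())} {test_g!r}, {int(sel_ref.sum())} {ref_g!r})"
        )
    X = np.asarray(normalized.X, dtype=float)
    Xt, Xr = X[sel_test], X[sel_ref]
    frac_t = (Xt > 0).mean(axis=0)
    frac_r = (Xr > 0).mean(axis=0)
    tested = (frac_t >= min_pct) | (frac_r >= min_pct)
    if not tested.any():
        raise ValueError("no gene passes the min_pct detection filter")
    sub = np.concatenate([Xt[:, tested], Xr[:, tested]], axis=0)
    in_group = np.zeros(sub.shape[0], dtype=bool)
    in_group[: Xt.shape[0]] = True
    tab = rank_sum_de(sub, in_group)
    tab.index = normalized.var_names[tested]
    tab.index.name = "gene"
    tab = tab.rename(columns={"pct_in": f"pct_{test_g}", "pct_out": f"pct_{ref_g}"})
    tab["fdr"] = multipletests(tab["pval"], method="fdr_bh")[1]
    return tab


def filter_degs(
    results: pd.DataFrame, lfc_min: float = 0.25, fdr_max: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split DEGs into (up, down) gene sets by strict thresholds.

    A gene qualifies when |log2FC| > ``lfc_min`` and FDR < ``fdr_max``;
    the sign of log2FC assigns the direction.
    """
    if results.empty:
        return set(), set()
    sig = results["fdr"] < fdr_max
    up = results.index[sig & (results["log2fc"] > lfc_min)]
    down = results.index[sig & (results["log2fc"] < -lfc_min)]
    return set(up), set(down)


@dataclass(frozen=True)
class EnrichmentResult:
    """Binding-target enrichment of one state's DEGs."""

    state: str
    n_degs: int
    n_degs_with_peak: int
    percent_bound: float
    odds_ratio: float  # conditional MLE; NaN when a margin is zero
    ci_low: float
    ci_high: float
    pval: float
    pval_bonferroni: float


def binding_enrichment(
    degs: set[str],
    background: set[str],
    annotation: pd.Series,
    n_tests: int = 1,
    state: str = "",
) -> EnrichmentResult:
    """Fisher's exact test of DEG / binding-peak association.

    ``background`` is the set of genes tested for differential expression
    (DEGs included); ``annotation`` maps gene -> has_peak. The 2x2 table
    crosses DEG membership with peak status over the background. With a
    zero peak margin the odds ratio is undefined (NaN) and p = 1.
    """
    if not degs <= background:
        raise ValueError("DEGs must be a subset of the background gene set")
    missing = background - set(annotation.index)
    if missing:
        raise ValueError(
            f"annotation missing {len(missing)} background genes, e.g. "
            f"{sorted(missing)[:3]}"
        )
    bg = sorted(background)
    peak = annotation.loc[bg].astype(bool).to_numpy()
    is_deg = np.isin(bg, sorted(degs))
    a = int((is_deg & peak).sum())
    b = int((is_deg & ~peak).sum())
    c = int((~is_deg & peak).sum())
    d = int((~is_deg & ~peak).sum())
    n_degs = a + b
    pct = 100.0 * a / n_degs if n_degs else float("nan")
    table = [[a, b], [c, d]]
    if (a + c == 0) or (b + d == 0) or n_degs == 0 or (c + d == 0):
        return EnrichmentResult(
            state, n_degs, a, pct, float("nan"), float("nan"), float("nan"), 1.0, 1.0
        )
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    orr = _odds_ratio(table, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return EnrichmentResult(
        state=state,
        n_degs=n_degs,
        n_degs_with_peak=a,
        percent_bound=pct,
        odds_ratio=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        pval=p,
        pval_bonferroni=min(1.0, p * n_tests),
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Stack per-state enrichment results into a DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results]).set_index("state")
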
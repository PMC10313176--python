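"""Cell-state composition analysis: per-replicate proportions and a
propeller-style differential abundance test between genotypes.

Replicate proportions are variance-stabilized (arcsin-square-root by
default, logit optionally), compared by a pooled two-sample t-test per
state, and corrected across states by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class StateProportionTable:
    """Per-(replicate, genotype) cell-count fractions over states.

    ``counts`` and ``proportions`` share an index of (replicate, genotype)
    pairs and columns of state/subtype labels; each proportion row sums
    to 1.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.proportions.index):
            raise ValueError("counts and proportions must share an index")
        row_sums = self.proportions.sum(axis=1).to_numpy()
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("each proportion row must sum to 1")


def state_proportions(
    assignments: pd.Series | np.ndarray,
    cell_meta: pd.DataFrame,
    states: list[str] | None = None,
) -> StateProportionTable:
    """Tabulate per-replicate state fractions.

    ``assignments`` gives each cell's state/subtype/cluster label;
    ``cell_meta`` must carry ``replicate`` and ``genotype`` columns aligned
    with it. Zero-count states are reported as 0.
    """
    if "replicate" not in cell_meta or "genotype" not in cell_meta:
        raise ValueError("cell metadata must carry 'replicate' and 'genotype'")
    labels = np.asarray(assignments)
    if pd.isna(labels).any():
        raise ValueError("every cell must carry a state label")
    df = pd.DataFrame(
        {
            "state": labels,
            "replicate": cell_meta["replicate"].to_numpy(),
            "genotype": cell_meta["genotype"].to_numpy(),
        }
    )
    counts = (
        df.groupby(["replicate", "genotype"], observed=True)["state"]
        .value_counts()
        .unstack(fill_value=0)
    )
    if states is not None:
        counts = counts.reindex(columns=list(states), fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("replicate with zero cells")
    return StateProportionTable(counts=counts, proportions=counts.div(totals, axis=0))


def _transform(p: np.ndarray, method: str) -> np.ndarray:
    if method == "arcsin":
        return np.arcsin(np.sqrt(p))
    if method == "logit":
        eps = 1e-6
        q = np.clip(p, eps, 1 - eps)
        return np.log(q / (1 - q))
    raise ValueError(f"unknown transform {method!r}")


def differential_abundance(
    table: StateProportionTable, transform: str = "arcsin"
) -> pd.DataFrame:
    """Propeller-style test of composition shifts between two genotypes.

    Per state: transform each replicate's proportion, pooled two-sample
    t-test between genotypes, BH FDR across states. States absent from
    every replicate are excluded with a warning. Returns one row per state
    with group means, the transformed-scale difference, t, p and FDR.
    """
    props = table.proportions
    genotypes = props.index.get_level_values("genotype")
    groups = sorted(pd.unique(genotypes))
    if len(groups) != 2:
        raise ValueError(f"expected 2 genotypes, found {len(groups)}")
    g1, g2 = groups  # alphabetical; the difference is transform(g1) - transform(g2)
    n1 = int((genotypes == g1).sum())
    n2 = int((genotypes == g2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per genotype")

    rows = []
    for state in props.columns:
        p = props[state]
        if table.counts[state].sum() == 0:
            warnings.warn(f"state {state!r} absent everywhere; excluded from testing")
            continue
        a = _transform(p[genotypes == g1].to_numpy(), transform)
        b = _transform(p[genotypes == g2].to_numpy(), transform)
        diff = a.mean() - b.mean()
        pooled_var = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / (n1 + n2 - 2)
        if pooled_var == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
            pval = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
            t = diff / se
            pval = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
        rows.append(
            {
                "state": state,
                f"mean_{g1}": p[genotypes == g1].mean(),
                f"mean_{g2}": p[genotypes == g2].mean(),
                "diff_transformed": diff,
                "t": t,
                "pval": pval,
            }
        )
    out = pd.DataFrame(rows).set_index("state")
    out["fdr"] = multipletests(out["pval"], method="fdr_bh")[1]
    return out
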
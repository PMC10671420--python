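"""Module x gene-set over-representation with Fisher's exact test.

Every (module, gene set) pair is tested one-sided ("greater": enrichment,
not depletion) on the 2x2 table

    a = |module ∩ set|      b = |module \\ set|
    c = |set \\ module|      d = |universe \\ (module ∪ set)|

conditioned on the analysis universe (by default every gene in the final
expression matrix; grey genes count toward the universe but form no
module).  Raw p-values drive module selection by default, mirroring the
usual -log10(p) heatmap presentation; Benjamini-Hochberg q-values are
reported alongside and selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneAnnotationTable
from .modules import ModulePartition

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class EnrichmentResult:
    """One row per (module, set): contingency counts and test statistics."""

    table: pd.DataFrame  # columns: module, set, a, b, c, d, odds_ratio, p, q, neglog10_p
    universe_size: int

    def pairs(self) -> pd.DataFrame:
        return self.table

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fisher_test_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (greater) Fisher exact p and odds ratio for a 2x2 table."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p), float(odds)


def fisher_enrichment(
    partition: ModulePartition,
    annotation: GeneAnnotationTable,
    universe: Sequence[str] | None = None,
    set_names: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Test every module against every gene set over the analysis universe.

    ``universe`` defaults to all genes in the partition (the analyzed
    matrix).  Sets with no gene in the universe are skipped with a
    warning.  Grey genes are excluded from modules but kept in the
    universe.
    """
    if universe is None:
        universe = partition.gene_ids
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    N = len(uni)
    if N == 0:
        raise ValueError("empty analysis universe")
    set_names = list(set_names) if set_names is not None else list(annotation.set_names)

    module_members = {
        mod: set(partition.members(mod)) & uni for mod in partition.module_ids
    }
    rows = []
    for name in set_names:
        in_set = annotation.members(name) & uni
        if not in_set:
            logger.warning("set %s has no gene in the universe; skipped", name)
            continue
        for mod in partition.module_ids:
            in_mod = module_members[mod]
            a = len(in_mod & in_set)
            b = len(in_mod) - a
            c = len(in_set) - a
            d = N - a - b - c
            p, odds = fisher_test_one_sided(a, b, c, d)
            rows.append(
                {
                    "module": mod,
                    "module_color": partition.color_of_module(mod),
                    "set": name,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    if not rows:
        raise ValueError("no testable (module, set) pair")
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        df["neglog10_p"] = -np.log10(df["p"].to_numpy())
    return EnrichmentResult(table=df, universe_size=N)


def heatmap_matrix(result: EnrichmentResult) -> pd.DataFrame:
    """Modules x sets matrix of -log10(p), rows labeled by module color."""
    mat = result.table.pivot(index="module_color", columns="set", values="neglog10_p")
    # preserve the module order of the result table
    order = result.table["module_color"].drop_duplicates().tolist()
    cols = result.table["set"].drop_duplicates().tolist()
    return mat.loc[order, cols]


def enriched_modules(
    result: EnrichmentResult,
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = False,
) -> dict[str, list[int]]:
    """Per set, the modules significant at ``alpha``, ascending by p."""
    stat = "q" if use_adjusted else "p"
    out: dict[str, list[int]] = {}
    for name, sub in result.table.groupby("set", sort=False):
        hits = sub[sub[stat] < alpha].sort_values(["p", "module"])
        out[str(name)] = [int(m) for m in hits["module"]]
    return out


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Optional PNG/SVG heatmap (sets x modules, darker = more enriched)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.T  # sets as rows
    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * data.shape[1] + 2), max(3, 0.5 * data.shape[0] + 1.5))
    )
    im = ax.imshow(data.to_numpy(), cmap="Greys", aspect="auto")
    ax.set_xticks(range(data.shape[1]), labels=data.columns, rotation=45, ha="right")
    ax.set_yticks(range(data.shape[0]), labels=data.index)
    fig.colorbar(im, ax=ax, label="-log10(p)")
    ax.set_xlabel("module")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
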
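"""Hub-gene connectivity, network export, and candidate prioritization.

Within each module a binary subnetwork is formed by keeping edges whose
weight (TOM by default, adjacency optionally) meets a threshold; the
degree of connectivity of a gene is the percentage of possible
intramodular partners it is connected to,

    degree_pct(g) = 100 * #{supra-threshold neighbours of g in its module}
                        / (module size - 1).

Candidate genes for a phenotype are the 22q13-region genes that sit in a
module enriched for that phenotype with module membership kME above a
cutoff (default 0.7), ranked by degree_pct and annotated with the gnomAD
pLI haploinsufficiency score (pLI > 0.9 flags the top tier).  A gene may
appear under several phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, enriched_modules
from .genesets import GeneAnnotationTable
from .modules import GREY_LABEL, ModulePartition

logger = logging.getLogger(__name__)

DEFAULT_KME_THRESHOLD = 0.7
DEFAULT_PLI_TOP_TIER = 0.9
ADAPTIVE_P90 = "p90"
REGION_SET = "region_22q13"

CANDIDATE_COLUMNS = (
    "gene",
    "phenotype",
    "module_color",
    "degree_pct",
    "kME",
    "pLI",
    "top_tier",
)


def _module_threshold(
    sub: np.ndarray, edge_weight_threshold: float | str
) -> float:
    if isinstance(edge_weight_threshold, str):
        if edge_weight_threshold != ADAPTIVE_P90:
            raise ValueError(f"unknown threshold rule {edge_weight_threshold!r}")
        iu = np.triu_indices_from(sub, k=1)
        return float(np.quantile(sub[iu], 0.9)) if iu[0].size else 0.0
    if edge_weight_threshold < 0:
        raise ValueError("edge weight threshold must be >= 0")
    return float(edge_weight_threshold)


def intramodular_degree(
    W: np.ndarray,
    gene_ids: Sequence[str],
    partition: ModulePartition,
    edge_weight_threshold: float | str = ADAPTIVE_P90,
) -> pd.Series:
    """Percentage of possible within-module partners connected per gene.

    ``edge_weight_threshold`` is an absolute weight, or the string "p90"
    for the within-module 90th percentile of weights (adaptive default).
    Grey genes and singleton modules get 0 (warned).
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    out = pd.Series(0.0, index=pd.Index(list(partition.gene_ids), name="gene"))
    for mod in partition.module_ids:
        members = partition.members(mod)
        if len(members) < 2:
            logger.warning("module %s has a single gene; degree set to 0", mod)
            continue
        rows = [idx[g] for g in members]
        sub = W[np.ix_(rows, rows)].copy()
        np.fill_diagonal(sub, 0.0)
        thr = _module_threshold(sub, edge_weight_threshold)
        deg = (sub >= thr).sum(axis=1) - (0 >= thr)  # discount zeroed diagonal if thr == 0
        denom = len(members) - 1
        out.loc[members] = 100.0 * np.asarray(deg, dtype=float) / denom
    return out


@dataclass
class EdgeExport:
    """Paths of the per-module edge and node-attribute files written."""

    edge_files: dict[str, Path]
    sif_files: dict[str, Path]
    node_attribute_file: Path | None


def export_edges(
    W: np.ndarray,
    gene_ids: Sequence[str],
    partition: ModulePartition,
    out_dir: str | Path,
    edge_weight_threshold: float | str = ADAPTIVE_P90,
    annotation: GeneAnnotationTable | None = None,
) -> EdgeExport:
    """Write per-module edge lists (TSV + SIF) for external visualization.

    Edges are undirected, listed once with gene_a < gene_b
    lexicographically; a node-attribute table carries the gene-set labels
    and the 22q13-region flag for node coloring.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx = {g: i for i, g in enumerate(gene_ids)}
    edge_files: dict[str, Path] = {}
    sif_files: dict[str, Path] = {}
    for mod in partition.module_ids:
        color = partition.color_of_module(mod)
        members = sorted(partition.members(mod))
        rows = [idx[g] for g in members]
        sub = W[np.ix_(rows, rows)].copy()
        np.fill_diagonal(sub, 0.0)
        thr = _module_threshold(sub, edge_weight_threshold)
        records = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                w = float(sub[i, j])
                if w >= thr:
                    records.append((members[i], members[j], w, color))
        edge_path = out_dir / f"edges_{color}.tsv"
        sif_path = out_dir / f"network_{color}.sif"
        pd.DataFrame(records, columns=["gene_a", "gene_b", "weight", "module"]).to_csv(
            edge_path, sep="\t", index=False
        )
        with sif_path.open("w") as handle:
            for a, b, _, _ in records:
                handle.write(f"{a}\tco_expr\t{b}\n")
        if not records:
            logger.warning("module %s: no edge survives the weight threshold", color)
        edge_files[color] = edge_path
        sif_files[color] = sif_path

    node_path = None
    if annotation is not None:
        node_path = out_dir / "node_attributes.tsv"
        members_map = {s: annotation.members(s) for s in annotation.set_names}
        rows_out = []
        for g in partition.gene_ids:
            labels = [s for s in annotation.set_names if g in members_map[s]]
            rows_out.append(
                {
                    "gene": g,
                    "module": partition.color_of(g),
                    "sets": ",".join(labels),
                    "region_22q13": int(REGION_SET in labels),
                }
            )
        pd.DataFrame(rows_out).to_csv(node_path, sep="\t", index=False)
    return EdgeExport(edge_files=edge_files, sif_files=sif_files, node_attribute_file=node_path)


def load_pli(path: str | Path) -> pd.Series:
    """Load a gene -> pLI table (TSV with 'gene' and 'pLI' columns).

    Values must lie in [0, 1]; 'NA' entries are allowed and propagate as
    missing downstream.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "pli" not in cols:
        raise ValueError("pLI table needs 'gene' and 'pLI' columns")
    genes = df[cols["gene"]].astype(str).str.upper()
    pli = pd.to_numeric(df[cols["pli"]], errors="coerce")
    valid = pli.dropna()
    if ((valid < 0) | (valid > 1)).any():
        bad = genes[pli.index[(pli < 0) | (pli > 1)]].tolist()
        raise ValueError(f"pLI outside [0, 1] for {bad[:5]}")
    out = pd.Series(pli.to_numpy(), index=genes.to_numpy(), name="pLI")
    return out[~out.index.duplicated()]


def select_candidates(
    annotation: GeneAnnotationTable,
    partition: ModulePartition,
    kme: pd.DataFrame,
    degrees: pd.Series,
    enrichment: EnrichmentResult,
    pli: pd.Series | None = None,
    kme_threshold: float = DEFAULT_KME_THRESHOLD,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    region_set: str = REGION_SET,
    phenotype_sets: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assemble the candidate table of prioritized region genes.

    For each phenotype: take its enriched modules, keep region genes in
    them whose kME to their own module exceeds ``kme_threshold``
    (strict), rank by degree_pct descending, and attach pLI with the
    top-tier flag (pLI > 0.9).  Phenotypes with no enriched module yield
    an empty section and an explanatory note.
    """
    if region_set not in annotation.set_names:
        raise ValueError(f"annotation has no {region_set!r} set")
    if phenotype_sets is None:
        phenotype_sets = [s for s in annotation.set_names if s != region_set]
    region_genes = annotation.members(region_set)
    enriched = enriched_modules(enrichment, alpha=alpha, use_adjusted=use_adjusted)
    rows = []
    notes: dict[str, str] = {}
    for pheno in phenotype_sets:
        mods = enriched.get(pheno, [])
        if not mods:
            notes[pheno] = (
                f"no module enriched for {pheno} at alpha={alpha}; "
                "no candidate genes selected"
            )
            logger.info("%s", notes[pheno])
            continue
        section = []
        for g in sorted(region_genes):
            if g not in partition.labels.index:
                continue
            mod = int(partition.labels[g])
            if mod == GREY_LABEL or mod not in mods:
                continue
            k = float(kme.loc[g, mod])
            if not k > kme_threshold:
                continue
            pli_val = float(pli[g]) if pli is not None and g in pli.index and pd.notna(pli[g]) else np.nan
            section.append(
                {
                    "gene": g,
                    "phenotype": pheno,
                    "module_color": partition.color_of_module(mod),
                    "degree_pct": float(degrees.get(g, 0.0)),
                    "kME": k,
                    "pLI": pli_val,
                    "top_tier": bool(pli_val > DEFAULT_PLI_TOP_TIER) if pd.notna(pli_val) else False,
                }
            )
        section.sort(key=lambda r: (-r["degree_pct"], r["gene"]))
        rows.extend(section)
        if not section:
            notes[pheno] = (
                f"module(s) enriched for {pheno} contain no {region_set} gene "
                f"with kME > {kme_threshold}"
            )
    table = pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))
    return table, notes
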
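"""End-to-end orchestration of the co-expression pipeline.

Stages: gene-list curation -> expression preprocessing -> network
construction (soft threshold, adjacency, TOM) -> module detection
(clustering, cut, eigengenes, merging) -> enrichment -> hub
prioritization.  Every stage logs its parameters and attrition counts to
a structured, timestamp-free run log; all artifacts are written as TSV /
JSON and listed, with SHA-256 checksums, in a manifest.  Re-running with
the same config and inputs reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import hubs
from . import modules as mod
from . import network as net
from . import preprocess as prep
from .config import PipelineConfig
from .genesets import (
    GeneAnnotationTable,
    build_annotation,
    load_alias_map,
    load_combined_sets,
    load_gene_set,
)

logger = logging.getLogger(__name__)


class RunLog:
    """Structured, deterministic (timestamp-free) run log."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, stage: str, event: str, **counts) -> None:
        entry = {"stage": stage, "event": event, **counts}
        self.events.append(entry)
        logger.info("[%s] %s %s", stage, event, counts if counts else "")

    def write(self, path: Path) -> None:
        with path.open("w") as handle:
            for entry in self.events:
                handle.write(json.dumps(entry, default=str) + "\n")


@dataclass
class RunArtifacts:
    """Everything a pipeline run produced, on disk and in memory."""

    out_dir: Path
    manifest: dict[str, str]  # relative path -> sha256
    config: PipelineConfig
    annotation: GeneAnnotationTable | None = None
    expression: prep.ExpressionMatrix | None = None
    soft_threshold: net.SoftThresholdReport | None = None
    tom: net.TOMMatrix | None = None
    partition: mod.ModulePartition | None = None
    eigengenes: mod.EigengeneMatrix | None = None
    kme: pd.DataFrame | None = None
    enrichment: enr.EnrichmentResult | None = None
    degrees: pd.Series | None = None
    candidates: pd.DataFrame | None = None
    candidate_notes: dict[str, str] = field(default_factory=dict)
    outlier_samples: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_annotation(cfg: PipelineConfig, log: RunLog) -> GeneAnnotationTable:
    paths = cfg.paths
    alias = load_alias_map(paths.alias_file) if paths.alias_file else None
    if paths.combined_gene_sets:
        sets = load_combined_sets(paths.combined_gene_sets, alias_map=alias)
    elif paths.gene_sets:
        sets = [load_gene_set(p, name, alias_map=alias) for name, p in paths.gene_sets.items()]
    else:
        raise ValueError("no gene-set inputs configured")
    for s in sets:
        log.add("curation", "gene_set_loaded", set=s.name, n_genes=len(s))
    table = build_annotation(sets)
    log.add("curation", "annotation_built", n_genes=len(table.genes), n_sets=len(table.set_names))
    return table


def _preprocess(
    cfg: PipelineConfig,
    M: prep.ExpressionMatrix,
    annotation: GeneAnnotationTable,
    log: RunLog,
    out: Path,
) -> tuple[prep.ExpressionMatrix, list[str]]:
    log.add("preprocess", "loaded", n_genes=M.n_genes, n_samples=M.n_samples)
    if cfg.preprocess.restrict_to_annotated:
        M, missing = prep.subset_to_annotation(M, annotation)
        log.add(
            "preprocess",
            "restricted_to_annotation",
            n_genes=M.n_genes,
            n_annotated_missing=len(missing),
        )
    M2 = prep.drop_zero_genes(M)
    log.add("preprocess", "zero_sum_removed", n_removed=M.n_genes - M2.n_genes, n_genes=M2.n_genes)
    M3 = prep.log_transform(M2)
    log.add("preprocess", "log2_rpkm_plus1", n_genes=M3.n_genes)
    M4 = prep.filter_low_expression(M3, cfg.preprocess.low_expression_rpkm)
    log.add(
        "preprocess",
        "low_expression_filtered",
        threshold_rpkm=cfg.preprocess.low_expression_rpkm,
        n_removed=M3.n_genes - M4.n_genes,
        n_genes=M4.n_genes,
    )
    for name in annotation.set_names:
        members = annotation.members(name)
        log.add(
            "preprocess",
            "set_attrition",
            set=name,
            n_listed=len(members),
            n_analyzed=len(members & set(M4.gene_ids)),
        )
    qc = prep.qc_report(M4)
    dropped = sorted(set(M.gene_ids) - set(M4.gene_ids))
    qc["kept"] = 1
    qc.to_csv(out / "qc_report.tsv", sep="\t")
    pd.Series(dropped, name="gene").to_csv(out / "dropped_genes.tsv", sep="\t", index=False)
    outliers = prep.sample_outlier_report(M4, cfg.preprocess.outlier_quantile)
    log.add("preprocess", "sample_outliers_flagged", n_flagged=len(outliers), samples=outliers)
    return M4, outliers


def run_pipeline(
    config: PipelineConfig,
    expression: prep.ExpressionMatrix | None = None,
    annotation: GeneAnnotationTable | None = None,
) -> RunArtifacts:
    """Execute the full pipeline and write all artifacts.

    ``expression`` and ``annotation`` may be passed in-memory (synthetic
    runs, tests); otherwise they are loaded from the configured paths.
    """
    cfg = config
    out = Path(cfg.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    incomplete_marker = out / "INCOMPLETE"
    incomplete_marker.write_text("run in progress or aborted\n")
    for dotted in cfg.paper_unstated_defaults():
        log.add("config", "paper_unstated_default", key=dotted)
    log.add("config", "seed", seed=cfg.seed)

    art = RunArtifacts(out_dir=out, manifest={}, config=cfg)
    stage = "curation"
    try:
        if annotation is None:
            annotation = _load_annotation(cfg, log)
        art.annotation = annotation
        annotation.to_tsv(out / "annotation.tsv")

        stage = "preprocess"
        if expression is None:
            if not cfg.paths.expression:
                raise ValueError("no expression matrix configured")
            expression = prep.load_expression(
                cfg.paths.expression, cfg.paths.row_meta, cfg.paths.col_meta
            )
        M, outliers = _preprocess(cfg, expression, annotation, log, out)
        art.expression = M
        art.outlier_samples = outliers

        stage = "network"
        S = net.similarity(M, mode=cfg.network.mode)
        report = net.pick_soft_threshold(
            S,
            candidates=cfg.network.candidate_betas,
            target_r2=cfg.network.target_r2,
            fallback_beta=cfg.network.fallback_beta,
            n_bins=cfg.network.n_bins,
        )
        log.add(
            "network",
            "soft_threshold_chosen",
            beta=report.chosen_beta,
            fallback_used=report.fallback_used,
            target_r2=cfg.network.target_r2,
            mode=cfg.network.mode,
        )
        report.to_tsv(out / "soft_threshold.tsv")
        A = net.adjacency(S, report.chosen_beta)
        tom = net.topological_overlap(A)
        art.soft_threshold = report
        art.tom = tom

        stage = "modules"
        dendro = mod.hierarchical_cluster(tom.dissimilarity, tom.gene_ids, cfg.modules.linkage)
        part = mod.cut_modules(
            dendro,
            method=cfg.modules.cut_method,
            cut_height=cfg.modules.cut_height,
            min_module_size=cfg.modules.min_module_size,
            gap_fraction=cfg.modules.gap_fraction,
        )
        log.add(
            "modules",
            "dendrogram_cut",
            method=cfg.modules.cut_method,
            min_module_size=cfg.modules.min_module_size,
            n_modules=part.n_modules,
            n_grey=int((part.labels == mod.GREY_LABEL).sum()),
        )
        eig = mod.module_eigengenes(M, part)
        part, eig = mod.merge_close_modules(M, part, eig, cfg.modules.merge_cut_height)
        part = mod.assign_colors(part)
        log.add(
            "modules",
            "merged",
            merge_cut_height=cfg.modules.merge_cut_height,
            n_modules=part.n_modules,
            sizes={part.color_of_module(m): s for m, s in part.module_sizes.items()},
        )
        kme = mod.module_membership(M, eig)
        art.partition = part
        art.eigengenes = eig
        art.kme = kme

        assignments = pd.DataFrame(
            {
                "module_color": [part.color_of(g) for g in part.gene_ids],
                "module": part.labels,
                "kME_own": [
                    float(kme.loc[g, int(part.labels[g])]) if int(part.labels[g]) != mod.GREY_LABEL else np.nan
                    for g in part.gene_ids
                ],
            },
            index=pd.Index(part.gene_ids, name="gene"),
        )
        assignments.to_csv(out / "module_assignments.tsv", sep="\t")
        me_out = eig.ME.copy()
        me_out.index = [part.color_of_module(m) for m in me_out.index]
        me_out.index.name = "module"
        me_out.to_csv(out / "eigengenes.tsv", sep="\t")
        gl_dir = out / "module_gene_lists"
        gl_dir.mkdir(exist_ok=True)
        for m in part.module_ids:
            (gl_dir / f"{part.color_of_module(m)}.txt").write_text(
                "\n".join(sorted(part.members(m))) + "\n"
            )

        stage = "enrichment"
        universe = (
            M.gene_ids
            if cfg.enrichment.universe == "analyzed"
            else [g for g in annotation.genes]
        )
        result = enr.fisher_enrichment(part, annotation, universe=universe)
        result.to_tsv(out / "enrichment.tsv")
        hm = enr.heatmap_matrix(result)
        hm.to_csv(out / "heatmap_matrix.tsv", sep="\t")
        sel = enr.enriched_modules(result, cfg.enrichment.alpha, cfg.enrichment.use_adjusted)
        log.add(
            "enrichment",
            "modules_selected",
            alpha=cfg.enrichment.alpha,
            use_adjusted=cfg.enrichment.use_adjusted,
            universe=cfg.enrichment.universe,
            universe_size=result.universe_size,
            enriched={s: [part.color_of_module(m) for m in ms] for s, ms in sel.items()},
        )
        art.enrichment = result

        stage = "prioritization"
        W = tom.T if cfg.prioritization.weight_source == "tom" else net.adjacency(S, report.chosen_beta).A
        degrees = hubs.intramodular_degree(
            W, tom.gene_ids, part, cfg.prioritization.edge_weight_threshold
        )
        degrees.rename("degree_pct").to_csv(out / "intramodular_degree.tsv", sep="\t")
        hubs.export_edges(
            W,
            tom.gene_ids,
            part,
            out / "networks",
            cfg.prioritization.edge_weight_threshold,
            annotation=annotation,
        )
        pli = None
        if cfg.paths.pli:
            if Path(cfg.paths.pli).exists():
                pli = hubs.load_pli(cfg.paths.pli)
            else:
                log.add("prioritization", "pli_file_missing", path=cfg.paths.pli)
                logger.warning("pLI file %s missing; pLI column will be NA", cfg.paths.pli)
        candidates, notes = hubs.select_candidates(
            annotation,
            part,
            kme,
            degrees,
            result,
            pli=pli,
            kme_threshold=cfg.prioritization.kme_threshold,
            alpha=cfg.enrichment.alpha,
            use_adjusted=cfg.enrichment.use_adjusted,
            region_set=cfg.prioritization.region_set,
        )
        candidates.to_csv(out / "candidate_table.tsv", sep="\t", index=False)
        (out / "candidate_notes.json").write_text(json.dumps(notes, indent=2, sort_keys=True) + "\n")
        log.add(
            "prioritization",
            "candidates_selected",
            kme_threshold=cfg.prioritization.kme_threshold,
            n_candidates=len(candidates),
            notes=notes,
        )
        art.degrees = degrees
        art.candidates = candidates
        art.candidate_notes = notes
    except Exception as exc:
        log.add(stage, "error", message=str(exc))
        log.write(out / "run_log.jsonl")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "params.json").write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    log.write(out / "run_log.jsonl")
    incomplete_marker.unlink(missing_ok=True)

    manifest: dict[str, str] = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    art.manifest = manifest
    return art
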
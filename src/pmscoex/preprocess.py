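"""Expression-matrix ingestion and preprocessing.

The pipeline consumes a genes x samples matrix in RPKM units, removes
genes with zero total expression, applies the log2(RPKM + 1) transform,
filters genes whose mean RPKM falls below 0.3, optionally restricts to
the annotated gene universe, and flags (never removes) sample outliers
by hierarchical clustering.

Unit state is tracked explicitly: a matrix is either on the RPKM scale
or on the log2(RPKM + 1) scale, and the transform may be applied exactly
once.  The low-expression filter always uses means on the RPKM scale,
computed before the transform and carried along.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .genesets import GeneAnnotationTable

logger = logging.getLogger(__name__)

#: Mean-RPKM cutoff below which a gene counts as not expressed.
LOW_EXPRESSION_RPKM = 0.3


class UnitState(enum.Enum):
    RPKM = "RPKM"
    LOG2_RPKM_PLUS1 = "LOG2_RPKM_PLUS1"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with explicit unit state.

    ``rpkm_means`` holds the per-gene mean on the RPKM scale; it is filled
    at construction when the matrix is in RPKM units and carried across
    the log transform so the low-expression filter can run on either
    scale.
    """

    values: pd.DataFrame
    unit_state: UnitState = UnitState.RPKM
    rpkm_means: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if v.isna().any().any():
            bad = v.index[v.isna().any(axis=1)][:5].tolist()
            raise ValueError(f"missing values are not supported (e.g. genes {bad})")
        if (v.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.unit_state is UnitState.RPKM:
            self.rpkm_means = v.mean(axis=1)
        elif self.rpkm_means is not None:
            self.rpkm_means = self.rpkm_means.loc[v.index]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def _subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        sub = replace(self, values=self.values.loc[list(genes)])
        return sub


def _read_table(path: Path, **kwargs) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, **kwargs)


def load_expression(
    matrix_path: str | Path,
    row_meta_path: str | Path | None = None,
    col_meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an RPKM matrix from plain TSV/CSV or the BrainSpan dialect.

    Plain dialect: genes in rows, first column gene symbols, header row of
    sample ids.  BrainSpan dialect (both metadata paths given): a
    header-less numeric matrix whose first column is a row number, a rows
    file with a ``gene_symbol`` column, and a columns file whose
    remaining columns (e.g. age, structure) become per-sample metadata.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean (logged).
    """
    matrix_path = Path(matrix_path)
    sample_meta = None
    if row_meta_path is not None or col_meta_path is not None:
        if row_meta_path is None or col_meta_path is None:
            raise ValueError("BrainSpan dialect needs both row and column metadata")
        raw = _read_table(matrix_path, header=None, index_col=0)
        rows = _read_table(Path(row_meta_path))
        cols = _read_table(Path(col_meta_path))
        if "gene_symbol" not in rows.columns:
            raise ValueError("row metadata must contain a 'gene_symbol' column")
        if len(rows) != raw.shape[0]:
            raise ValueError(
                f"row metadata has {len(rows)} rows but matrix has {raw.shape[0]}"
            )
        if len(cols) != raw.shape[1]:
            raise ValueError(
                f"column metadata has {len(cols)} rows but matrix has {raw.shape[1]} columns"
            )
        gene_ids = rows["gene_symbol"].astype(str).str.upper().tolist()
        if "column_num" in cols.columns:
            sample_ids = [f"S{int(i)}" for i in cols["column_num"]]
        else:
            sample_ids = [f"S{i + 1}" for i in range(len(cols))]
        values = pd.DataFrame(raw.to_numpy(dtype=float), index=gene_ids, columns=sample_ids)
        sample_meta = cols.copy()
        sample_meta.index = pd.Index(sample_ids, name="sample")
    else:
        values = _read_table(matrix_path, index_col=0)
        values.index = values.index.astype(str).str.upper()
        values = values.astype(float)

    if values.index.has_duplicates:
        n_before = len(values)
        means = values.mean(axis=1).to_numpy()
        by_mean = values.iloc[np.argsort(-means, kind="stable")]
        dedup = by_mean[~by_mean.index.duplicated(keep="first")]
        values = dedup.loc[values.index.drop_duplicates()]
        logger.info(
            "collapsed %d duplicate gene row(s), keeping the highest-mean row",
            n_before - len(values),
        )
    return ExpressionMatrix(values=values, unit_state=UnitState.RPKM, sample_meta=sample_meta)


def drop_zero_genes(M: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose expression sums to 0 RPKM across all samples."""
    if M.unit_state is not UnitState.RPKM:
        raise ValueError("drop_zero_genes expects a matrix in RPKM units")
    sums = M.values.sum(axis=1)
    keep = sums > 0
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("empty matrix: every gene sums to 0 RPKM")
    if n_removed:
        logger.info("removed %d gene(s) with zero total RPKM", n_removed)
    return M._subset(M.values.index[keep])


def log_transform(M: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(RPKM + 1) cell-wise; allowed exactly once."""
    if M.unit_state is not UnitState.RPKM:
        raise ValueError("matrix already log2(RPKM+1)-transformed")
    values = np.log2(M.values + 1.0)
    return ExpressionMatrix(
        values=values,
        unit_state=UnitState.LOG2_RPKM_PLUS1,
        rpkm_means=M.rpkm_means,
        sample_meta=M.sample_meta,
    )


def filter_low_expression(
    M: ExpressionMatrix, threshold: float = LOW_EXPRESSION_RPKM
) -> ExpressionMatrix:
    """Drop genes with mean RPKM below ``threshold`` (strict <, so 0.3 stays)."""
    if M.rpkm_means is None:
        raise ValueError("RPKM-scale means unavailable; load data in RPKM units first")
    keep = M.rpkm_means >= threshold
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("empty matrix: every gene falls below the expression threshold")
    if n_removed:
        logger.info(
            "filtered %d gene(s) with mean RPKM < %g (%d retained)",
            n_removed,
            threshold,
            int(keep.sum()),
        )
    return M._subset(M.values.index[keep])


def subset_to_annotation(
    M: ExpressionMatrix, table: GeneAnnotationTable
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict the matrix to annotated genes.

    Returns the subset matrix and the annotated genes missing from the
    matrix (reported, not an error — the attrition is logged per set).
    """
    annotated = set(table.genes)
    keep = [g for g in M.gene_ids if g in annotated]
    missing = sorted(annotated - set(M.gene_ids))
    if not keep:
        raise ValueError("no annotated gene is present in the expression matrix")
    if missing:
        logger.info("%d annotated gene(s) absent from the expression matrix", len(missing))
    for name in table.set_names:
        members = table.members(name)
        n_present = len(members & set(keep))
        logger.info("set %s: %d/%d genes present in matrix", name, n_present, len(members))
    return M._subset(keep), missing


def qc_report(M: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene descriptive statistics (on the current scale) plus mean RPKM."""
    df = pd.DataFrame(
        {
            "mean": M.values.mean(axis=1),
            "median": M.values.median(axis=1),
            "sd": M.values.std(axis=1, ddof=1),
        }
    )
    if M.rpkm_means is not None:
        df["mean_rpkm"] = M.rpkm_means
    df.index.name = "gene"
    return df


def sample_outlier_report(
    M: ExpressionMatrix, cut_height_quantile: float = 0.95
) -> list[str]:
    """Flag isolated samples by Euclidean average-linkage clustering.

    Samples are clustered on their expression profiles; the dendrogram is
    cut at the given quantile of merge heights, and samples left as
    singletons above that cut are flagged.  Report-only: nothing is
    removed.
    """
    if M.unit_state is not UnitState.LOG2_RPKM_PLUS1:
        raise ValueError("outlier check runs on the log2(RPKM+1) matrix")
    if M.n_samples < 3:
        logger.warning("fewer than 3 samples; outlier report empty")
        return []
    X = M.values.to_numpy().T  # samples x genes
    d = pdist(X, metric="euclidean")
    if np.allclose(d, 0):
        return []
    Z = sch.linkage(d, method="average")
    cut = float(np.quantile(Z[:, 2], cut_height_quantile))
    labels = sch.fcluster(Z, t=cut, criterion="distance")
    counts = pd.Series(labels).value_counts()
    singletons = set(counts.index[counts == 1])
    flagged = [s for s, lab in zip(M.sample_ids, labels) if lab in singletons]
    if flagged:
        logger.warning("flagged %d sample outlier(s): %s", len(flagged), flagged)
    return flagged
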
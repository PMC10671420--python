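"""Weighted co-expression network construction.

The network is built from pairwise Pearson correlations of the
log-transformed expression profiles.  The similarity S_ij = |cor(x_i,
x_j)| (unsigned network; a signed variant (1 + cor)/2 is available) is
raised element-wise to a soft-threshold power beta, A_ij = S_ij^beta,
with beta chosen as the smallest integer for which the connectivity
distribution of the resulting network approximates a scale-free (power
law) topology.  The adjacency is then transformed into the topological
overlap matrix (TOM),

    T_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{j != i} a_ij,

whose dissimilarity D = 1 - T is the clustering input downstream.

All matrices are dense; a guard refuses more genes than
``MAX_DENSE_GENES`` rather than exhausting memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix, UnitState

logger = logging.getLogger(__name__)

MAX_DENSE_GENES = 20_000

UNSIGNED_ABS = "unsigned_abs"
SIGNED_SHIFT = "signed_shift"

DEFAULT_BETA_CANDIDATES = tuple(range(1, 21))
DEFAULT_TARGET_R2 = 0.8
DEFAULT_FALLBACK_BETA = 9


@dataclass
class SimilarityMatrix:
    S: np.ndarray
    mode: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n = self.S.shape[0]
        if self.S.shape != (n, n) or n != len(self.gene_ids):
            raise ValueError("similarity matrix shape does not match gene ids")


@dataclass
class AdjacencyMatrix:
    A: np.ndarray
    beta: int
    gene_ids: list[str]

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum of off-diagonal adjacency in row i."""
        return self.A.sum(axis=1) - np.diag(self.A)


@dataclass
class TOMMatrix:
    T: np.ndarray
    gene_ids: list[str]

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.T


@dataclass
class ScaleFreeFit:
    r2_signed: float
    slope: float
    degenerate: bool = False


@dataclass
class SoftThresholdReport:
    """Per-candidate scale-free fit statistics and the chosen power."""

    table: pd.DataFrame  # columns: beta, r2_signed, slope, mean_k, median_k
    chosen_beta: int
    target_r2: float
    fallback_used: bool = False

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["chosen"] = out["beta"] == self.chosen_beta
        out.to_csv(path, sep="\t", index=False)


def similarity(M: ExpressionMatrix, mode: str = UNSIGNED_ABS) -> SimilarityMatrix:
    """Pairwise Pearson similarity of gene expression profiles."""
    if M.unit_state is not UnitState.LOG2_RPKM_PLUS1:
        raise ValueError("similarity runs on the log2(RPKM+1) matrix")
    if mode not in (UNSIGNED_ABS, SIGNED_SHIFT):
        raise ValueError(f"unknown similarity mode {mode!r}")
    if M.n_genes > MAX_DENSE_GENES:
        raise ValueError(
            f"{M.n_genes} genes exceeds the dense-matrix guard ({MAX_DENSE_GENES})"
        )
    X = M.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(M.gene_ids, sd) if s == 0]
        raise ValueError(f"zero-variance gene(s): {bad[:5]} — filter before networking")
    C = np.corrcoef(X)
    if mode == UNSIGNED_ABS:
        S = np.abs(C)
    else:
        S = (1.0 + C) / 2.0
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S=S, mode=mode, gene_ids=list(M.gene_ids))


def adjacency(S: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Element-wise soft-thresholding A_ij = S_ij^beta."""
    if not float(beta).is_integer() or beta < 1:
        raise ValueError(f"beta must be a positive integer, got {beta!r}")
    A = np.power(S.S, int(beta))
    return AdjacencyMatrix(A=A, beta=int(beta), gene_ids=list(S.gene_ids))


def scale_free_fit(k: np.ndarray | Sequence[float], n_bins: int = 10) -> ScaleFreeFit:
    """Goodness of scale-free topology for a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    relative frequency of non-empty bins is regressed on the log10 bin
    center.  The returned R^2 is multiplied by -sign(slope), so a
    decreasing power-law tail yields a positive value.  A constant
    connectivity vector is degenerate (single occupied bin): R^2 = 0.
    """
    k = np.asarray(k, dtype=float)
    if k.size == 0:
        raise ValueError("empty connectivity vector")
    lo, hi = float(k.min()), float(k.max())
    if hi <= lo:
        return ScaleFreeFit(r2_signed=0.0, slope=0.0, degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    occupied = (counts > 0) & (centers > 0)
    if occupied.sum() < 2:
        return ScaleFreeFit(r2_signed=0.0, slope=0.0, degenerate=True)
    freq = counts[occupied] / k.size
    x = np.log10(centers[occupied])
    y = np.log10(freq)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    return ScaleFreeFit(r2_signed=-np.sign(slope) * r2, slope=slope, degenerate=False)


def pick_soft_threshold(
    S: SimilarityMatrix,
    candidates: Sequence[int] = DEFAULT_BETA_CANDIDATES,
    target_r2: float = DEFAULT_TARGET_R2,
    fallback_beta: int = DEFAULT_FALLBACK_BETA,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scan candidate powers and pick the smallest meeting the fit target.

    For each candidate beta the adjacency, connectivity and signed
    scale-free R^2 are computed; the chosen beta is the smallest with
    R^2 >= target.  When no candidate qualifies the configured fallback
    is used and flagged prominently.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate powers")
    if any(b2 <= b1 for b1, b2 in zip(candidates, candidates[1:])):
        raise ValueError("candidate powers must be strictly ascending")
    rows = []
    chosen = None
    for beta in candidates:
        A = adjacency(S, beta)
        k = A.connectivity
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "beta": beta,
                "r2_signed": fit.r2_signed,
                "slope": fit.slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "degenerate": fit.degenerate,
            }
        )
        if chosen is None and not fit.degenerate and fit.r2_signed >= target_r2:
            chosen = beta
    fallback_used = chosen is None
    if fallback_used:
        chosen = int(fallback_beta)
        logger.warning(
            "no candidate power reached scale-free R^2 >= %.2f; "
            "falling back to beta = %d",
            target_r2,
            chosen,
        )
    return SoftThresholdReport(
        table=pd.DataFrame(rows),
        chosen_beta=int(chosen),
        target_r2=float(target_r2),
        fallback_used=fallback_used,
    )


def topological_overlap(A: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap of a weighted adjacency.

    Shared-neighbour sums and connectivities exclude the diagonal; the
    TOM diagonal is set to 1 by convention.
    """
    W = A.A.copy()
    np.fill_diagonal(W, 0.0)
    k = W.sum(axis=1)
    L = W @ W  # l_ij = sum_u a_iu a_uj with u != i,j (diagonal of W is 0)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - W
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + W) / denom
    T = np.where(denom > 0, T, 0.0)
    T = (T + T.T) / 2.0
    np.clip(T, 0.0, 1.0, out=T)
    np.fill_diagonal(T, 1.0)
    return TOMMatrix(T=T, gene_ids=list(A.gene_ids))
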
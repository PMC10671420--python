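"""Module detection on the TOM dissimilarity.

Genes are clustered hierarchically (average linkage by default) on
D = 1 - TOM.  The dendrogram is cut either statically (connected
components below a fixed height, small components unassigned) or with a
recursive gap-based branch cut: a branch becomes a module when it holds
at least ``min_module_size`` genes and the height gap between the merge
that absorbs it and its own top merge exceeds a configurable fraction of
the total tree height.  Unassigned genes are labeled 0 and colored grey.

Each module is summarized by its eigengene — the first principal
component of the standardized (per-gene z-scored) module submatrix,
sign-aligned so it correlates positively with the module's mean
expression profile.  Modules whose eigengenes cluster below a merge
height (1 - cor) are fused iteratively.  kME, the module-membership
matrix, is the Pearson correlation of each gene with each eigengene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.cluster.hierarchy import ClusterNode
from scipy.spatial.distance import squareform

from ._colors import GREY, color_for_rank
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY_LABEL = 0

STATIC = "static"
DYNAMIC_BRANCH = "dynamic_branch"

DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_GAP_FRACTION = 0.005
#: fraction of the merge-height span above which a split of two internal
#: branches always marks the parent as spanning several clusters
STRONG_SPLIT_FRACTION = 0.5
DEFAULT_MERGE_CUT_HEIGHT = 0.25


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage form."""

    Z: np.ndarray  # (n-1, 4) linkage matrix
    gene_ids: list[str]
    linkage: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.gene_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.Z[:, 2].max()) if len(self.Z) else 0.0


@dataclass
class ModulePartition:
    """Gene -> module label (0 = unassigned/grey) plus color names."""

    labels: pd.Series  # index: gene ids, values: int labels
    colors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def module_ids(self) -> list[int]:
        """Non-grey module labels, sorted."""
        return sorted(set(self.labels) - {GREY_LABEL})

    @property
    def module_sizes(self) -> dict[int, int]:
        counts = self.labels.value_counts()
        return {int(m): int(counts[m]) for m in self.module_ids}

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def color_of(self, gene: str) -> str:
        return self.color_of_module(int(self.labels[gene]))

    def color_of_module(self, module: int) -> str:
        if module == GREY_LABEL:
            return GREY
        return self.colors.get(module, str(module))


def hierarchical_cluster(
    D: np.ndarray, gene_ids: list[str], linkage: str = "average"
) -> Dendrogram:
    """Cluster genes on a symmetric zero-diagonal dissimilarity matrix."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(gene_ids):
        raise ValueError("dissimilarity shape does not match gene ids")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix is not symmetric")
    Ds = (D + D.T) / 2.0
    np.fill_diagonal(Ds, 0.0)
    Z = sch.linkage(squareform(Ds, checks=False), method=linkage)
    return Dendrogram(Z=Z, gene_ids=list(gene_ids), linkage=linkage)


def _cut_static(dendro: Dendrogram, cut_height: float, min_module_size: int) -> np.ndarray:
    flat = sch.fcluster(dendro.Z, t=cut_height, criterion="distance")
    return _relabel_small_to_grey(flat, min_module_size)


def _relabel_small_to_grey(flat: np.ndarray, min_module_size: int) -> np.ndarray:
    labels = np.zeros_like(flat)
    next_id = 1
    for lab in sorted(set(flat)):
        idx = flat == lab
        if idx.sum() >= min_module_size:
            labels[idx] = next_id
            next_id += 1
    return labels


def _cut_dynamic(
    dendro: Dendrogram, min_module_size: int, gap_fraction: float
) -> np.ndarray:
    """Recursive gap-based branch cut (see module docstring).

    A branch *qualifies* as separable when it holds at least
    ``min_module_size`` leaves and the gap between the height of the
    merge that absorbs it and its own top height is at least
    ``gap_fraction`` of the dendrogram's merge-height span (max - min
    height; the span makes the rule invariant to the compression of TOM
    dissimilarities toward 1 at high soft-threshold powers).  Walking
    down from the root, the first (maximal) separable branch met is
    accepted as a module; elsewhere the walk descends.  The root itself
    is accepted as a single module only when no separable branch exists
    anywhere below it.  Genes in branches too small to be modules stay
    grey.
    """
    n = dendro.n_leaves
    labels = np.zeros(n, dtype=int)
    root = sch.to_tree(dendro.Z)
    heights = dendro.heights
    span = float(heights.max() - heights.min()) if len(heights) else 0.0
    if span == 0:
        return labels
    threshold = gap_fraction * span

    # bottom-up pass: per subtree, its mean internal merge height ("core
    # height", a robust cohesion summary that stray late-joining leaves
    # cannot inflate) and whether it contains a divisive split — a merge
    # of two module-sized branches both cohering clearly below it.
    core_height: dict[int, float] = {}
    core_stats: dict[int, tuple[float, int]] = {}  # (sum of heights, n merges)
    has_divisive: dict[int, bool] = {}
    stack: list[tuple[ClusterNode, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if node.is_leaf():
            core_stats[node.id] = (0.0, 0)
            core_height[node.id] = 0.0
            has_divisive[node.id] = False
        elif processed:
            left, right = node.left, node.right
            s = core_stats[left.id][0] + core_stats[right.id][0] + node.dist
            m = core_stats[left.id][1] + core_stats[right.id][1] + 1
            core_stats[node.id] = (s, m)
            core_height[node.id] = s / m
            core_gap = node.dist - max(core_height[left.id], core_height[right.id])
            both_module_sized = (
                left.get_count() >= min_module_size
                and right.get_count() >= min_module_size
            )
            # divisive either way: two module-sized cohesive branches, or
            # two branches of any size separated by most of the height
            # span (so raising min_module_size cannot fuse well-separated
            # clusters into one sprawling "module")
            divisive = (both_module_sized and core_gap >= threshold) or (
                not left.is_leaf()
                and not right.is_leaf()
                and core_gap >= STRONG_SPLIT_FRACTION * span
            )
            has_divisive[node.id] = (
                divisive or has_divisive[left.id] or has_divisive[right.id]
            )
        else:
            stack.append((node, True))
            stack.append((node.left, False))
            stack.append((node.right, False))

    # top-down pass: accept maximal separable single-module branches
    next_id = 1
    work: list[tuple[ClusterNode, float]] = [(root, np.inf)]
    while work:
        node, parent_height = work.pop()
        if node.get_count() < min_module_size:
            continue  # stays grey
        gap = parent_height - node.dist
        if gap >= threshold and not has_divisive[node.id]:
            labels[node.pre_order(lambda leaf: leaf.id)] = next_id
            next_id += 1
            continue
        if not node.is_leaf():
            work.append((node.right, node.dist))
            work.append((node.left, node.dist))
    return labels


def cut_modules(
    dendro: Dendrogram,
    method: str = DYNAMIC_BRANCH,
    cut_height: float | None = None,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
) -> ModulePartition:
    """Cut the dendrogram into modules of at least ``min_module_size`` genes."""
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if method == STATIC:
        if cut_height is None:
            cut_height = 0.99 * dendro.max_height
        if not (0.0 <= cut_height <= dendro.max_height):
            raise ValueError(
                f"cut_height {cut_height} outside [0, {dendro.max_height}]"
            )
        flat = _cut_static(dendro, cut_height, min_module_size)
    elif method == DYNAMIC_BRANCH:
        flat = _cut_dynamic(dendro, min_module_size, gap_fraction)
    else:
        raise ValueError(f"unknown cut method {method!r}")
    labels = pd.Series(flat, index=pd.Index(dendro.gene_ids, name="gene"))
    part = ModulePartition(labels=labels)
    logger.info(
        "cut (%s): %d module(s), %d grey gene(s)",
        method,
        part.n_modules,
        int((labels == GREY_LABEL).sum()),
    )
    return part


@dataclass
class EigengeneMatrix:
    """Module eigengenes (modules x samples) with explained variance."""

    ME: pd.DataFrame  # index: module label (int), columns: sample ids
    explained_variance: pd.Series  # per module, fraction in [0, 1]

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.ME.index]


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene inside a module")
    return (X - mu) / sd


def module_eigengenes(M: ExpressionMatrix, partition: ModulePartition) -> EigengeneMatrix:
    """First principal component per module as its eigengene.

    Genes are z-scored across samples, the first right-singular vector of
    the module submatrix is the eigengene (unit norm over samples), and
    its sign is aligned so it correlates non-negatively with the module's
    mean standardized profile.
    """
    rows = {}
    ev = {}
    for mod in partition.module_ids:
        genes = partition.members(mod)
        if len(genes) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        X = _standardize_rows(M.values.loc[genes].to_numpy(dtype=float))
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        e = Vt[0]
        mean_profile = X.mean(axis=0)
        if float(e @ mean_profile) < 0:
            e = -e
        rows[mod] = e
        ev[mod] = float(s[0] ** 2 / (s**2).sum())
    ME = pd.DataFrame(rows, index=M.sample_ids).T
    ME.index.name = "module"
    return EigengeneMatrix(ME=ME, explained_variance=pd.Series(ev, name="explained_variance"))


def module_membership(M: ExpressionMatrix, eig: EigengeneMatrix) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every module eigengene."""
    X = _standardize_rows(M.values.to_numpy(dtype=float))
    E = eig.ME.to_numpy(dtype=float)
    E = (E - E.mean(axis=1, keepdims=True))
    E = E / np.linalg.norm(E, axis=1, keepdims=True)
    n = X.shape[1]
    # rows of X have norm sqrt(n); rows of E are centered unit vectors
    kme = (X @ E.T) / np.sqrt(n)
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=M.values.index, columns=eig.ME.index)


def merge_close_modules(
    M: ExpressionMatrix,
    partition: ModulePartition,
    eig: EigengeneMatrix,
    merge_cut_height: float = DEFAULT_MERGE_CUT_HEIGHT,
) -> tuple[ModulePartition, EigengeneMatrix]:
    """Fuse modules whose eigengenes are highly correlated.

    Modules are clustered (average linkage) on 1 - cor(ME); clusters
    below ``merge_cut_height`` are fused, eigengenes recomputed, and the
    procedure iterates to a fixed point.  The module count never
    increases.
    """
    part = partition
    current = eig
    for _ in range(max(1, partition.n_modules)):
        mods = part.module_ids
        if len(mods) < 2:
            break
        E = current.ME.loc[mods].to_numpy(dtype=float)
        corr = np.corrcoef(E)
        D = 1.0 - corr
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        Z = sch.linkage(squareform(D, checks=False), method="average")
        flat = sch.fcluster(Z, t=merge_cut_height, criterion="distance")
        if len(set(flat)) == len(mods):
            break
        mapping = {}
        for new_lab in sorted(set(flat)):
            group = [mods[i] for i in range(len(mods)) if flat[i] == new_lab]
            target = min(group)
            for m in group:
                mapping[m] = target
        new_labels = part.labels.map(lambda m: mapping.get(int(m), GREY_LABEL))
        part = ModulePartition(labels=new_labels)
        current = module_eigengenes(M, part)
        logger.info("merged eigengene clusters: %d -> %d modules", len(mods), part.n_modules)
    return part, current


def assign_colors(partition: ModulePartition) -> ModulePartition:
    """Attach the standard color sequence, largest module first.

    Ties in size break deterministically by the smallest member gene
    symbol.
    """
    sizes = partition.module_sizes

    def tie_key(mod: int) -> tuple[int, str]:
        return (-sizes[mod], min(partition.members(mod)))

    ordered = sorted(partition.module_ids, key=tie_key)
    colors = {mod: color_for_rank(rank) for rank, mod in enumerate(ordered)}
    return replace(partition, colors=colors)
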
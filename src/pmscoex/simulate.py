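"""Synthetic expression data with planted co-expression modules.

The generator emulates, at desk scale, the statistical structure the
pipeline assumes in brain developmental expression data: groups of genes
sharing a latent per-sample driver.  On the log scale, gene g of module
m is

    x_g = lambda_g * e_m + sqrt(1 - lambda_g^2) * eps_g,

with latent factor e_m and noise eps_g standard normal over samples and
loading lambda_g drawn uniformly from the module's range, so that
cor(x_g, e_m) = lambda_g in expectation.  Background genes are pure
standard normal.  Log-scale values map to RPKM by v = 2^(x + c) - 1
(clipped at 0, c = 3 by default), so the pipeline's own log2(RPKM + 1)
transform approximately recovers x.  A block of "near-zero" genes with
mean RPKM ~ 0.05 exercises the 0.3-RPKM filter, and phenotype/region
labels are planted on chosen modules so that enrichment, and candidate
selection downstream, have a known ground truth.  One phenotype
(hypotonia by default) is planted on background genes only, reproducing
the no-enriched-module outcome path.

Everything is deterministic given the seed: a single numpy PCG64 stream
(``numpy.random.default_rng(seed)``) is consumed in a fixed documented
order — per-module factors, then per-module loadings and noise, then
background genes, then near-zero genes, then set plants in listed order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .genesets import GeneAnnotationTable, GeneSet, build_annotation
from .modules import ModulePartition
from .preprocess import ExpressionMatrix, UnitState

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20231026
DEFAULT_LOG_OFFSET = 3.0
NEAR_ZERO_MEAN_RPKM = 0.05


@dataclass(frozen=True)
class ModulePlan:
    """One planted module: gene count and loading range (lo, hi] in (0, 1]."""

    size: int
    loading_range: tuple[float, float] = (0.6, 0.9)

    def __post_init__(self) -> None:
        lo, hi = self.loading_range
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loadings must lie in (0, 1]")


@dataclass(frozen=True)
class SetPlant:
    """Plant a gene-set label: fraction of one module plus background genes.

    ``module`` is a 0-based module index or None for a background-only
    set (no enrichment planted anywhere).
    """

    set_name: str
    module: int | None
    fraction: float = 0.5
    n_background: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


@dataclass(frozen=True)
class HubPlant:
    """An extra gene with a fixed high loading, carrying the given labels."""

    module: int
    loading: float = 0.95
    sets: tuple[str, ...] = ("region_22q13",)


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset (defaults = benchmark)."""

    n_samples: int = 120
    modules: tuple[ModulePlan, ...] = tuple(ModulePlan(60) for _ in range(5))
    n_background: int = 100
    n_near_zero: int = 20
    set_plants: tuple[SetPlant, ...] = (
        SetPlant("ASD", 0),
        SetPlant("ID", 1),
        SetPlant("seizures", 2),
        SetPlant("language_impairment", 3),
        SetPlant("region_22q13", 0, fraction=0.3, n_background=5),
        SetPlant("region_22q13", 4, fraction=0.3, n_background=0),
        SetPlant("hypotonia", None, n_background=15),
    )
    hub_plants: tuple[HubPlant, ...] = (HubPlant(module=0),)
    log_offset: float = DEFAULT_LOG_OFFSET
    factor_correlation: float = 0.0  # inter-module factor correlation knob
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        n_mod = len(self.modules)
        for plant in self.set_plants:
            if plant.module is not None and not (0 <= plant.module < n_mod):
                raise ValueError(f"set plant references missing module {plant.module}")
        for hub in self.hub_plants:
            if not (0 <= hub.module < n_mod):
                raise ValueError(f"hub plant references missing module {hub.module}")
            if not (0.0 < hub.loading <= 1.0):
                raise ValueError("hub loading must lie in (0, 1]")
        if not (0.0 <= self.factor_correlation <= 1.0):
            raise ValueError("factor correlation must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list) + "\n")


def default_benchmark() -> SyntheticSpec:
    """The default planted benchmark used throughout the test suite."""
    return SyntheticSpec()


@dataclass
class PlantedTruth:
    """Ground truth emitted next to a synthetic matrix."""

    module_of: pd.Series  # gene -> 0-based module index, -1 = background/near-zero
    loadings: pd.Series  # gene -> loading (NaN for background)
    factors: pd.DataFrame  # modules x samples latent factors
    planted_sets: dict[str, list[int]]  # set name -> module indices with planted enrichment

    def module_genes(self, module: int) -> list[str]:
        return list(self.module_of.index[self.module_of == module])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of": {g: int(m) for g, m in self.module_of.items()},
            "loadings": {
                g: (None if pd.isna(v) else float(v)) for g, v in self.loadings.items()
            },
            "planted_sets": self.planted_sets,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def simulate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate an RPKM matrix with planted modules and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_mod = len(spec.modules)
    n = spec.n_samples

    factors = rng.standard_normal((n_mod, n))
    if spec.factor_correlation != 0.0 and n_mod > 1:
        shared = rng.standard_normal(n)
        rho = spec.factor_correlation
        factors = np.sqrt(rho) * shared + np.sqrt(1 - rho) * factors

    gene_ids: list[str] = []
    module_of: list[int] = []
    loadings: list[float] = []
    log_rows: list[np.ndarray] = []

    hubs_by_module: dict[int, list[HubPlant]] = {}
    for hub in spec.hub_plants:
        hubs_by_module.setdefault(hub.module, []).append(hub)

    for m, plan in enumerate(spec.modules):
        lo, hi = plan.loading_range
        lam = rng.uniform(lo, hi, size=plan.size)
        eps = rng.standard_normal((plan.size, n))
        X = lam[:, None] * factors[m] + np.sqrt(1 - lam**2)[:, None] * eps
        for i in range(plan.size):
            gene_ids.append(f"M{m + 1}G{i + 1:03d}")
            module_of.append(m)
            loadings.append(float(lam[i]))
            log_rows.append(X[i])
        for h, hub in enumerate(hubs_by_module.get(m, [])):
            eps_h = rng.standard_normal(n)
            x = hub.loading * factors[m] + np.sqrt(1 - hub.loading**2) * eps_h
            gene_ids.append(f"M{m + 1}HUB{h + 1}")
            module_of.append(m)
            loadings.append(float(hub.loading))
            log_rows.append(x)

    for i in range(spec.n_background):
        gene_ids.append(f"BG{i + 1:03d}")
        module_of.append(-1)
        loadings.append(np.nan)
        log_rows.append(rng.standard_normal(n))

    X_log = np.vstack(log_rows) if log_rows else np.empty((0, n))
    rpkm = np.clip(np.exp2(X_log + spec.log_offset) - 1.0, 0.0, None)

    near_zero_rows = rng.exponential(NEAR_ZERO_MEAN_RPKM, size=(spec.n_near_zero, n))
    for i in range(spec.n_near_zero):
        gene_ids.append(f"NZ{i + 1:03d}")
        module_of.append(-1)
        loadings.append(np.nan)
    values = np.vstack([rpkm, near_zero_rows]) if spec.n_near_zero else rpkm

    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    M = ExpressionMatrix(values=df, unit_state=UnitState.RPKM)
    truth = PlantedTruth(
        module_of=pd.Series(module_of, index=df.index, name="module"),
        loadings=pd.Series(loadings, index=df.index, name="loading"),
        factors=pd.DataFrame(factors, index=range(n_mod), columns=sample_ids),
        planted_sets={
            name: sorted(
                {p.module for p in spec.set_plants if p.set_name == name and p.module is not None}
            )
            for name in {p.set_name for p in spec.set_plants}
        },
    )
    logger.info(
        "simulated %d genes x %d samples (%d modules, %d background, %d near-zero)",
        len(gene_ids),
        n,
        n_mod,
        spec.n_background,
        spec.n_near_zero,
    )
    return M, truth


def plant_gene_sets(truth: PlantedTruth, spec: SyntheticSpec) -> GeneAnnotationTable:
    """Label genes so that planted (module, set) pairs are enriched.

    Labels are drawn from a fresh seeded stream (seed + 1, so annotation
    does not perturb expression): per plant, a random subset of the
    module of the stated fraction, plus the stated number of random
    background genes.  Hub genes always carry their declared labels.
    Near-zero genes each get one random phenotype label so that list
    attrition through the expression filter is visible per set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    members: dict[str, set[str]] = {}
    order: list[str] = []
    background = [g for g in truth.module_of.index if truth.module_of[g] == -1 and not g.startswith("NZ")]
    for plant in spec.set_plants:
        if plant.set_name not in members:
            members[plant.set_name] = set()
            order.append(plant.set_name)
        if plant.module is not None:
            module_genes = [
                g for g in truth.module_genes(plant.module) if "HUB" not in g
            ]
            k = int(round(plant.fraction * len(module_genes)))
            if plant.fraction > 0 and k == 0:
                logger.warning(
                    "plant %s on module %d: fraction %.3f labels zero genes",
                    plant.set_name,
                    plant.module,
                    plant.fraction,
                )
            chosen = rng.choice(module_genes, size=k, replace=False) if k else []
            members[plant.set_name].update(map(str, chosen))
        if plant.n_background:
            k = min(plant.n_background, len(background))
            chosen = rng.choice(background, size=k, replace=False)
            members[plant.set_name].update(map(str, chosen))
    for hub in spec.hub_plants:
        for s in hub.sets:
            if s not in members:
                members[s] = set()
                order.append(s)
        hub_genes = [
            g
            for g in truth.module_of.index
            if truth.module_of[g] == hub.module and "HUB" in g
        ]
        for s in hub.sets:
            members[s].update(hub_genes)
    phenos = [s for s in order if s != "region_22q13"] or order
    near_zero = [g for g in truth.module_of.index if g.startswith("NZ")]
    for g in near_zero:
        members[str(rng.choice(phenos))].add(g)
    sets = [GeneSet(name=s, genes=frozenset(members[s])) for s in order if members[s]]
    return build_annotation(sets)


def simulate_pli(truth: PlantedTruth, spec: SyntheticSpec) -> pd.DataFrame:
    """Synthetic gene -> pLI table (two-column TSV-ready frame).

    Loss-of-function intolerance scores are drawn uniformly on [0, 1]
    from a stream seeded ``spec.seed + 2``; planted hub genes get pLI
    0.99 so the haploinsufficiency top tier (pLI > 0.9) is non-empty,
    and one background gene is left NA to exercise the missing-score
    path.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = list(truth.module_of.index)
    values = rng.uniform(0.0, 1.0, size=len(genes))
    df = pd.DataFrame({"gene": genes, "pLI": values})
    hub_mask = df["gene"].str.contains("HUB")
    df.loc[hub_mask, "pLI"] = 0.99
    bg = df.index[df["gene"].str.startswith("BG")]
    if len(bg):
        df.loc[bg[0], "pLI"] = np.nan
    return df


@dataclass
class RecoveryScore:
    ari: float
    jaccard: pd.Series  # per true module: best-match Jaccard

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RecoveryScore(ari={self.ari:.3f}, mean_jaccard={self.jaccard.mean():.3f})"


def score_recovery(truth: PlantedTruth, partition: ModulePartition) -> RecoveryScore:
    """Adjusted Rand index and per-module Jaccard of a recovered partition.

    The ARI is computed over genes with a true module (background
    excluded); grey counts as its own recovered class.
    """
    common = [g for g in truth.module_of.index if truth.module_of[g] >= 0 and g in partition.labels.index]
    true_labels = truth.module_of[common].to_numpy()
    found_labels = partition.labels[common].to_numpy()
    ari = float(adjusted_rand_score(true_labels, found_labels))
    jac = {}
    for m in sorted(set(true_labels)):
        true_set = {g for g in common if truth.module_of[g] == m}
        best = 0.0
        for mod in partition.module_ids:
            rec = set(partition.members(mod))
            inter = len(true_set & rec)
            union = len(true_set | rec)
            if union:
                best = max(best, inter / union)
        jac[int(m)] = best
    return RecoveryScore(ari=ari, jaccard=pd.Series(jac, name="jaccard"))
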
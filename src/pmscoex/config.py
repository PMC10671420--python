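"""Pipeline configuration: schema, defaults, and validation.

The configuration is a nested mapping (YAML or JSON on disk) mirroring
the pipeline stages.  Unknown keys are rejected, out-of-range values are
reported all at once, and every default that substitutes for a parameter
the source protocol leaves unstated is tagged ``paper-unstated`` in the
run log so a reader can see which knobs were choices of this
implementation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import modules as _modules
from . import network as _network

#: Defaults standing in for parameters the source protocol does not state.
PAPER_UNSTATED = (
    "network.target_r2",
    "network.candidate_betas",
    "modules.cut_method",
    "modules.min_module_size",
    "modules.gap_fraction",
    "enrichment.alpha",
    "enrichment.use_adjusted",
    "prioritization.edge_weight_threshold",
    "prioritization.weight_source",
)


@dataclass
class PathsConfig:
    expression: str | None = None
    row_meta: str | None = None
    col_meta: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    combined_gene_sets: str | None = None
    alias_file: str | None = None
    pli: str | None = None
    out_dir: str = "results/pipeline"


@dataclass
class PreprocessConfig:
    restrict_to_annotated: bool = True
    low_expression_rpkm: float = 0.3
    outlier_quantile: float = 0.95


@dataclass
class NetworkConfig:
    mode: str = _network.UNSIGNED_ABS
    candidate_betas: list[int] = field(default_factory=lambda: list(range(1, 21)))
    target_r2: float = _network.DEFAULT_TARGET_R2
    fallback_beta: int = _network.DEFAULT_FALLBACK_BETA
    n_bins: int = 10


@dataclass
class ModulesConfig:
    linkage: str = "average"
    cut_method: str = _modules.DYNAMIC_BRANCH
    cut_height: float | None = None
    min_module_size: int = _modules.DEFAULT_MIN_MODULE_SIZE
    gap_fraction: float = _modules.DEFAULT_GAP_FRACTION
    merge_cut_height: float = _modules.DEFAULT_MERGE_CUT_HEIGHT


@dataclass
class EnrichmentConfig:
    alpha: float = 0.05
    use_adjusted: bool = False
    universe: str = "analyzed"  # or "annotated"


@dataclass
class PrioritizationConfig:
    kme_threshold: float = 0.7
    weight_source: str = "tom"  # or "adjacency"
    edge_weight_threshold: float | str = "p90"
    region_set: str = "region_22q13"


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    modules: ModulesConfig = field(default_factory=ModulesConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    seed: int = 0

    def paper_unstated_defaults(self) -> list[str]:
        """Config keys still at a default that the protocol never stated."""
        reference = PipelineConfig()
        out = []
        for dotted in PAPER_UNSTATED:
            section, key = dotted.split(".")
            if getattr(getattr(self, section), key) == getattr(getattr(reference, section), key):
                out.append(dotted)
        return out

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTIONS = {
    "paths": PathsConfig,
    "preprocess": PreprocessConfig,
    "network": NetworkConfig,
    "modules": ModulesConfig,
    "enrichment": EnrichmentConfig,
    "prioritization": PrioritizationConfig,
}


def _check_ranges(cfg: PipelineConfig) -> list[str]:
    errors = []
    if not (0.0 < cfg.network.target_r2 < 1.0):
        errors.append(f"network.target_r2 must lie in (0, 1), got {cfg.network.target_r2}")
    betas = cfg.network.candidate_betas
    if not betas or any(b2 <= b1 for b1, b2 in zip(betas, betas[1:])):
        errors.append("network.candidate_betas must be a non-empty ascending list")
    if betas and any(int(b) < 1 for b in betas):
        errors.append("network.candidate_betas must be >= 1")
    if cfg.network.mode not in (_network.UNSIGNED_ABS, _network.SIGNED_SHIFT):
        errors.append(f"network.mode must be unsigned_abs or signed_shift, got {cfg.network.mode!r}")
    if cfg.modules.cut_method not in (_modules.STATIC, _modules.DYNAMIC_BRANCH):
        errors.append(f"modules.cut_method must be static or dynamic_branch, got {cfg.modules.cut_method!r}")
    if cfg.modules.min_module_size < 2:
        errors.append("modules.min_module_size must be >= 2")
    if not (0.0 < cfg.modules.gap_fraction < 1.0):
        errors.append("modules.gap_fraction must lie in (0, 1)")
    if not (0.0 <= cfg.modules.merge_cut_height <= 1.0):
        errors.append("modules.merge_cut_height must lie in [0, 1]")
    if not (0.0 < cfg.enrichment.alpha <= 1.0) and cfg.enrichment.alpha != 0.0:
        errors.append("enrichment.alpha must lie in [0, 1]")
    if cfg.enrichment.universe not in ("analyzed", "annotated"):
        errors.append("enrichment.universe must be 'analyzed' or 'annotated'")
    if not (0.0 <= cfg.prioritization.kme_threshold <= 1.0):
        errors.append("prioritization.kme_threshold must lie in [0, 1]")
    if cfg.prioritization.weight_source not in ("tom", "adjacency"):
        errors.append("prioritization.weight_source must be 'tom' or 'adjacency'")
    thr = cfg.prioritization.edge_weight_threshold
    if isinstance(thr, str):
        if thr != "p90":
            errors.append("prioritization.edge_weight_threshold must be 'p90' or a number >= 0")
    elif thr < 0:
        errors.append("prioritization.edge_weight_threshold must be >= 0")
    if not (0.0 < cfg.preprocess.outlier_quantile < 1.0):
        errors.append("preprocess.outlier_quantile must lie in (0, 1)")
    if cfg.preprocess.low_expression_rpkm < 0:
        errors.append("preprocess.low_expression_rpkm must be >= 0")
    return errors


def config_from_dict(data: dict[str, Any] | None) -> PipelineConfig:
    """Build a validated config from a nested mapping, filling defaults.

    All violations (unknown keys, out-of-range values) are reported in a
    single error.
    """
    data = dict(data or {})
    errors: list[str] = []
    kwargs: dict[str, Any] = {}
    for name, value in list(data.items()):
        if name == "seed":
            kwargs["seed"] = int(value)
        elif name in _SECTIONS:
            cls = _SECTIONS[name]
            known = {f.name for f in dataclasses.fields(cls)}
            value = dict(value or {})
            unknown = set(value) - known
            if unknown:
                errors.append(f"unknown key(s) in {name}: {sorted(unknown)}")
                for k in unknown:
                    value.pop(k)
            kwargs[name] = cls(**value)
        else:
            errors.append(f"unknown top-level key {name!r}")
    cfg = PipelineConfig(**kwargs)
    errors.extend(_check_ranges(cfg))
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)
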
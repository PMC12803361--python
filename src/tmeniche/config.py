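"""Pipeline configuration.

Every published threshold used by the analysis is a named parameter with
the study's value as default, grouped by pipeline stage.  Configs load
from a single YAML file with nested sections mirroring these dataclasses.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class QCConfig:
    mito_max: float = 0.25          # discard above this mitochondrial fraction
    mouse_low: float = 0.10         # ambiguous-species band lower edge (exclusive)
    mouse_high: float = 0.95        # >= this -> spiked mouse control cell
    adt_outlier_fold: float = 10.0  # discard > fold x cluster-median total ADT
    enrichment_alpha: float = 0.01  # BH-adjusted p cutoff for ADT enrichment


@dataclass
class ScoringConfig:
    n_bins: int = 24                # expression bins for control-gene matching
    n_ctrl: int = 100               # control genes sampled per signature gene
    target_sum: float = 1e4         # per-cell scale before log1p
    hvg_n_top: int = 5000
    hvg_n_bins: int = 20
    subsample_lower: int = 25
    subsample_upper: int = 250


@dataclass
class SpatialConfig:
    proximity_um: float = 50.0      # close/far-from-B threshold
    microenv_radius_um: float = 200.0
    neighborhood_radius_um: float = 30.0
    top_fraction: float = 0.10      # top-scoring fraction called Tfh
    tfh_markers: tuple = ("CXCL13", "BCL6", "CD4")
    bin_width_um: float = 25.0


@dataclass
class ClonalConfig:
    # clone-size categories: Single (1), Small (2-5), Medium (6-20), Large (>20)
    small_max: int = 5
    medium_max: int = 20
    per_subset_clone_scope: bool = False  # clone size within (patient, timepoint) by default


@dataclass
class DynamicsConfig:
    pseudocount: float = 0.5
    de_alpha: float = 0.05
    de_lfc_min: float = 0.25


@dataclass
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    clonal: ClonalConfig = field(default_factory=ClonalConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | None = None) -> PipelineConfig:
    """Load a YAML config; missing sections/keys fall back to defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for f in fields(PipelineConfig):
        if f.name == "seed":
            cfg.seed = int(raw.get("seed", cfg.seed))
            continue
        section = raw.get(f.name, {})
        obj = getattr(cfg, f.name)
        for key, val in (section or {}).items():
            if not hasattr(obj, key):
                raise KeyError(f"unknown config key {f.name}.{key}")
            setattr(obj, key, tuple(val) if isinstance(val, list) else val)
    return cfg
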
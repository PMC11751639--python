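"""Pipeline configuration: one YAML-round-trippable object covering all stages.

Defaults mirror the study constants (128 slices of 650x512 px cropped to
512x512, bottleneck 64 trained 150 epochs on a 2500/500 split, MAF >= 5%,
genome-wide 5e-8) — scale them down explicitly for desk-size runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .latent import AutoencoderConfig
from .simulate import BlockSpec, CausalSpec, OutcomeSpec, ScanGeometry, SimConfig

__all__ = ["PipelineConfig", "SegmentationConfig", "AssocConfig", "SurvivalConfig"]


@dataclass
class SegmentationConfig:
    method: str = "oracle"  # "oracle" or "unet"
    max_missing_fraction: float = 0.2
    unet_train_pairs: int = 100
    unet_epochs: int = 50
    unet_depth: int = 3
    unet_base: int = 8


@dataclass
class AssocConfig:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-15
    call_rate_min: float = 0.99
    n_embedding_traits: int = 8  # embeddings taken forward to GWAS
    n_pca_traits: int = 4
    mtag_r_threshold: float = 0.9
    genome_wide: float = 5e-8
    replication_family_alpha: float = 0.01
    replication_fraction: float = 0.25  # held-out subjects for the replication GWAS


@dataclass
class SurvivalConfig:
    outcome_codes: list[str] = field(default_factory=lambda: ["H40"])
    penalty_strength: float = 0.1
    l1_ratio: float = 0.5
    n_repetitions: int = 20
    n_folds: int = 5
    top_fraction: float = 0.25


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 200
    n_variants: int = 500
    sim: SimConfig = field(default_factory=SimConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    # -- lossless YAML round trip ------------------------------------------ #

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "geometry" in sim:
            sim["geometry"] = ScanGeometry(**sim["geometry"])
        sim["blocks"] = [BlockSpec(**b) for b in sim.get("blocks", [])]
        sim["causal_map"] = [CausalSpec(**c) for c in sim.get("causal_map", [])]
        sim["outcomes"] = [OutcomeSpec(**o) for o in sim.get("outcomes", [])]
        if sim.get("inversion_effect") is not None:
            sim["inversion_effect"] = CausalSpec(**sim["inversion_effect"])
        if "texture_width_frac" in sim:
            sim["texture_width_frac"] = tuple(sim["texture_width_frac"])
        ae = dict(d.pop("autoencoder", {}))
        if "input_shape" in ae:
            ae["input_shape"] = tuple(ae["input_shape"])
        return cls(
            sim=SimConfig(**sim),
            segmentation=SegmentationConfig(**d.pop("segmentation", {})),
            autoencoder=AutoencoderConfig(**ae),
            assoc=AssocConfig(**d.pop("assoc", {})),
            survival=SurvivalConfig(**d.pop("survival", {})),
            **d,
        )

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "PipelineConfig":
        text = str(path_or_text)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
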
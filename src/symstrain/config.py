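"""YAML configuration: one file with sections phantom/hog/detector/symmetry/filter/cascade/eval."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade import CascadeConfig
from .detector import DetectorConfig
from .filternet import AugmentConfig, FilterConfig
from .hog import HogConfig
from .phantom import PhantomParams
from .symmetry import SymmetryConfig


@dataclass(frozen=True)
class EvalConfig:
    iou_threshold: float = 0.5
    bootstrap_B: int = 10000
    bootstrap_level: float = 0.95
    k_folds: int = 5
    holdout_pairs: int = 32


@dataclass
class Config:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    hog: HogConfig = field(default_factory=HogConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig.desk_scale)
    symmetry: SymmetryConfig = field(default_factory=SymmetryConfig)
    filter: FilterConfig = field(default_factory=FilterConfig.desk_scale)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


_TUPLE_FIELDS = {
    "image_size", "lesion_axes_range", "cell", "block", "strides", "scale",
    "noise_sd", "backbone_channels", "anchor_sizes",
}


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[k] = v
    return out


def load_config(path: str | Path | None = None) -> Config:
    """Build a Config from a YAML file; missing sections/keys keep defaults."""
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "phantom": PhantomParams, "hog": HogConfig, "detector": DetectorConfig,
        "symmetry": SymmetryConfig, "filter": FilterConfig, "cascade": CascadeConfig,
        "eval": EvalConfig,
    }
    kw = {}
    for name, cls in sections.items():
        sub = _tuplify(raw.get(name, {}) or {})
        if name == "filter" and "augment" in sub:
            sub["augment"] = AugmentConfig(**_tuplify(sub["augment"]))
        kw[name] = cls(**sub)
    return Config(**kw)
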
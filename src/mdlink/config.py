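"""YAML configuration loading.

The YAML schema mirrors the typed stage configurations one-to-one; every key
is optional and defaults to the corresponding dataclass default::

    similarity: {FC: 0.5, alpha_d: 1.0, alpha_m: 1.0,
                 sigmoid_norm_d: null, sigmoid_norm_m: null}
    gcn:        {h1: 256, h2: 128, layers: 2, dropout: 0.5,
                 epochs: 1000, learning_rate: 0.001, loss: bce}
    dae:        {encoder_dims: [1311, 1152, 576, 288, 144], epochs: 150,
                 initial_learning_rate: 0.01, kl_weight: 1.0}
    cascade:    {forests_per_layer: 4, n_estimators: 17,
                 split_criterion: entropy, cv_folds: 5, max_layers: 10}
    negatives:  {strategy: kmeans, n_clusters: 23, per_cluster: auto}
    n_folds: 10
    evaluation_mode: faithful
    ablation: LHRF
    threshold: 0.5
    seed: 0

Unknown keys raise immediately, so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .autoencoder import DAEConfig
from .cascade import CascadeConfig
from .gcn import GCNConfig
from .negative_sampling import NegativeSamplingPlan
from .pipeline import PipelineConfig
from .similarity import SimilarityConfig

__all__ = ["load_config", "config_to_dict"]

_SECTIONS = {
    "similarity": SimilarityConfig,
    "gcn": GCNConfig,
    "dae": DAEConfig,
    "cascade": CascadeConfig,
    "negatives": NegativeSamplingPlan,
}
_SCALARS = ("n_folds", "evaluation_mode", "ablation", "threshold", "seed")


def _build_section(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is DAEConfig and "encoder_dims" in data:
        data = {**data, "encoder_dims": tuple(data["encoder_dims"])}
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file and/or an override dict."""
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw = {**raw, **overrides}
    unknown = set(raw) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw and raw[name] is not None:
            kwargs[name] = _build_section(cls, dict(raw[name]))
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Round-trippable plain-dict form of a pipeline configuration."""
    out: dict = {}
    for name, _ in _SECTIONS.items():
        section = getattr(cfg, name if name != "negatives" else "negatives")
        out[name] = dataclasses.asdict(section) if section is not None else None
    if out["dae"] is not None and "encoder_dims" in out["dae"]:
        out["dae"]["encoder_dims"] = list(out["dae"]["encoder_dims"])
    for name in _SCALARS:
        out[name] = getattr(cfg, name)
    return out
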
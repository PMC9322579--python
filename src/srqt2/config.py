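"""YAML round-trip for :class:`~srqt2.pipeline.ExperimentConfig`."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .denoise import DenoiseParams
from .fitting import FitConfig
from .pipeline import ExperimentConfig


def config_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["grid_shape"] = list(config.grid_shape)
    d["grid_spacing"] = list(config.grid_spacing)
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    if "denoise_params" in d and isinstance(d["denoise_params"], dict):
        d["denoise_params"] = DenoiseParams(**d["denoise_params"])
    if "fit" in d and isinstance(d["fit"], dict):
        d["fit"] = FitConfig(**d["fit"])
    for key in ("grid_shape", "grid_spacing"):
        if key in d:
            d[key] = tuple(d[key])
    return ExperimentConfig(**d)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=False))


def load_config(path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
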
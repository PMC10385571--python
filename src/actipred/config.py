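"""YAML (de)serialization of pipeline configuration.

The YAML mirrors the nested dataclasses one-to-one, so a config round-trips
losslessly: ``load_config(save_config(cfg)) == cfg``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .classifier import ClassifierSpec, ClassifierTrainConfig
from .forecasters import ForecasterSpec, TrainConfig
from .pipeline import PipelineConfig
from .preprocessing import PreprocessConfig
from .synthetic import ActivityModel, SyntheticDatasetConfig

_SECTION_TYPES = {
    "dataset": SyntheticDatasetConfig,
    "forecaster": ForecasterSpec,
    "classifier": ClassifierSpec,
    "forecaster_train": TrainConfig,
    "classifier_train": ClassifierTrainConfig,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _build_dataset(d: dict) -> SyntheticDatasetConfig:
    d = dict(d)
    if d.get("preprocess") is not None:
        d["preprocess"] = PreprocessConfig(**d["preprocess"])
    if d.get("models") is not None:
        models = {}
        for name, m in d["models"].items():
            m = dict(m)
            m["harmonics"] = tuple(tuple(h) for h in m["harmonics"])
            m["channel_gains"] = tuple(m["channel_gains"])
            m["channel_phases"] = tuple(m["channel_phases"])
            models[name] = ActivityModel(**m)
        d["models"] = models
    if "activities" in d:
        d["activities"] = tuple(d["activities"])
    return SyntheticDatasetConfig(**d)


def config_from_dict(data: dict) -> PipelineConfig:
    kw = dict(data)
    if "dataset" in kw:
        kw["dataset"] = _build_dataset(kw["dataset"])
    for key, cls in _SECTION_TYPES.items():
        if key == "dataset":
            continue
        if key in kw and isinstance(kw[key], dict):
            d = dict(kw[key])
            if key == "classifier" and "bilstm_units" in d:
                d["bilstm_units"] = tuple(d["bilstm_units"])
            kw[key] = cls(**d)
    return PipelineConfig(**kw)


def load_config(path) -> PipelineConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_to_plain(cfg), sort_keys=True, default_flow_style=False)
    )
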
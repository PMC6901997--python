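"""Single-file experiment configuration (YAML or JSON).

One config artifact determines every number an experiment reports: it
bundles the simulator, preprocessing, architecture, optimizer and transfer
sections plus a global seed, and hashes canonically so runs are traceable.
Sections omitted from the file take their package defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .epochs import ValidationError
from .model import ModelConfig
from .preprocessing import PreprocConfig
from .synthetic import ClassSpec, SubjectShift, SynthConfig
from .training import LayeredLRPolicy, TrainConfig

__all__ = ["TransferConfig", "ExperimentConfig", "load_config", "config_hash"]


@dataclass
class TransferConfig:
    """Transfer-experiment settings: layered LRs, mixing and sample sizes."""

    policy: LayeredLRPolicy = field(default_factory=LayeredLRPolicy)
    mix_ratio: float = 1.0
    sample_sizes: tuple[int, ...] = (10, 20, 50, 100)
    n_subjects: int = 4
    shift: SubjectShift = field(default_factory=SubjectShift)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)


@dataclass
class ExperimentConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    model: dict = field(default_factory=dict)  # completed against data at run time
    train: TrainConfig = field(default_factory=TrainConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    paths: dict = field(default_factory=dict)
    seed: int = 0

    def model_config(self, n_channels: int, n_times: int, n_classes: int) -> ModelConfig:
        """Materialize the architecture against realized data dimensions."""
        kwargs = dict(self.model)
        kwargs.setdefault("n_channels", n_channels)
        kwargs.setdefault("n_times", n_times)
        kwargs.setdefault("n_classes", n_classes)
        return ModelConfig.from_dict(kwargs)


def _build(cls, raw: dict | None):
    if raw is None:
        return cls()
    if not isinstance(raw, dict):
        raise ValidationError(f"section for {cls.__name__} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValidationError(f"unknown keys {sorted(unknown)} in {cls.__name__} section")
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name == "class_specs" and value is not None:
            value = tuple(
                ClassSpec(
                    name=v["name"], channels=tuple(v["channels"]),
                    mu_gain=v.get("mu_gain", 0.4), beta_gain=v.get("beta_gain", 0.5),
                )
                for v in value
            )
        elif f.name == "policy":
            value = _build(LayeredLRPolicy, value)
        elif f.name == "shift":
            value = _build(SubjectShift, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment config from a ``.yaml``/``.yml`` or ``.json`` file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    known = {"synth", "preproc", "model", "train", "transfer", "paths", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown top-level config keys {sorted(unknown)}")
    return ExperimentConfig(
        synth=_build(SynthConfig, raw.get("synth")),
        preproc=_build(PreprocConfig, raw.get("preproc")),
        model=dict(raw.get("model") or {}),
        train=_build(TrainConfig, raw.get("train")),
        transfer=_build(TransferConfig, raw.get("transfer")),
        paths=dict(raw.get("paths") or {}),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash of the full config, for run logs."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    blob = json.dumps(encode(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
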
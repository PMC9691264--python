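"""Run configuration: YAML-backed, validated before any stage runs."""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .network import BEMConfig
from .synthetic import SimConfig
from .training import TrainSettings

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Top-level configuration shared by the CLI stages."""

    sim: SimConfig = field(default_factory=SimConfig)
    bem: BEMConfig = field(default_factory=BEMConfig)
    train: TrainSettings = field(default_factory=TrainSettings)
    depth: int = 4
    base_channels: int = 32
    folds: int = 4
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        return d

    def dump(self, out_dir: str | Path) -> None:
        """Write the resolved config (and seed) next to a run's outputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(
            json.dumps(self.resolved(), indent=2, default=str)
        )


def _build(cls, data: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration; ``seed`` overrides the
    file-level seed everywhere."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    sim = _build(SimConfig, raw.get("sim", {}), "sim")
    bem_raw = dict(raw.get("bem", {}))
    for key in ("dilation_rates", "layers_with_bem"):
        if key in bem_raw and bem_raw[key] is not None:
            bem_raw[key] = tuple(bem_raw[key])
    bem = _build(BEMConfig, bem_raw, "bem")
    train_raw = dict(raw.get("train", {}))
    if "weights" in train_raw:
        train_raw["weights"] = LossWeights(**train_raw["weights"])
    train = _build(TrainSettings, train_raw, "train")
    top = {k: raw[k] for k in ("depth", "base_channels", "folds", "seed")
           if k in raw}
    cfg = RunConfig(sim=sim, bem=bem, train=train, **top)
    if seed is not None:
        cfg.seed = seed
        cfg.sim = cfg.sim.replace(seed=seed)
        cfg.train = dataclasses.replace(cfg.train, seed=seed)
    return cfg
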
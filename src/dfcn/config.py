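"""Run configuration: defaults, YAML loading, CLI overrides, hashing.

One YAML file with sections {data, window, model, training, evaluation};
every value has a default, and flags override file values.  The hash of the
fully resolved config is embedded in output artifacts for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .arch import ArchitectureSpec, build_variant
from .train_eval import TrainingConfig
from .windowing import WindowSpec

__all__ = ["DEFAULT_CONFIG", "load_config", "config_hash", "window_from_config",
           "arch_from_config", "training_from_config", "artifact_meta"]

DEFAULT_CONFIG: dict = {
    "data": {
        "manifest": None,
        "root": None,
        "split": {"train": 70, "val": 30, "test": 20, "seed": 0},
    },
    "window": {"lo": -300, "hi": 600, "channels": 3},
    "model": {"variant": "dfcn4s", "n_classes": 7, "width_multiplier": 1.0},
    "training": {
        "learning_strategy": "step",
        "initial_lr": 1e-3,
        "batch_size": 4,
        "momentum": 0.9,
        "weight_decay": 5e-4,
        "max_iterations": 500_000,
        "checkpoint_interval": 5_000,
        "seed": 0,
        "loss": "cross_entropy",
        "class_weights": None,
        "augment_flips": False,
    },
    "evaluation": {"foreground_classes": None},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a run config: defaults <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def window_from_config(cfg: dict) -> WindowSpec:
    w = cfg["window"]
    return WindowSpec(lo=w["lo"], hi=w["hi"], n_channels=w["channels"])


def arch_from_config(cfg: dict) -> ArchitectureSpec:
    m = cfg["model"]
    return build_variant(m["variant"], n_classes=m["n_classes"],
                         width_multiplier=m["width_multiplier"],
                         window=window_from_config(cfg))


def training_from_config(cfg: dict, seed: int | None = None) -> TrainingConfig:
    t = dict(cfg["training"])
    if t.get("class_weights") is not None:
        t["class_weights"] = tuple(t["class_weights"])
    if seed is not None:
        t["seed"] = seed
    return TrainingConfig(**t)


def artifact_meta(cfg: dict) -> dict:
    """Provenance block embedded in output artifacts."""
    return {"tool": "dfcn", "version": __version__, "config_hash": config_hash(cfg)}
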
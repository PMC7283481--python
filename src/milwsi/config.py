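"""Run configuration: YAML loading, strict validation, defaults.

Defaults are the pipeline's reference operating point: tiles of 512 px at
working magnification x10, inference stride 256, Adam (beta1 0.9, beta2
0.999) with batch 64, the FS warm-start schedule (0.001 -> 0.05, decay 0.9,
22 epochs, patience 10), the MIL loop (warm k = 32 for 2 epochs, top-k
decay 5 -> 1, accumulation buffer n = 512, lr 0.001), and 1000 bootstrap
iterations.  Unknown keys are rejected with a closest-match suggestion;
all violations are aggregated into one report.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from milwsi.tile_model import AugmentationConfig, OptimizerConfig
from milwsi.training import FsConfig, MilConfig

DEFAULTS: dict = {
    "seed": 0,
    "working_magnification": 10.0,
    "synthesize": {
        "n_slides": 40,
        "carcinoma_fraction": 0.5,
        "slide_size": [512, 512],
        "tile_size": 64,
        "necrosis_in_carcinoma": 0.3,
        "necrosis_in_negative": 0.5,
        "texture_noise_sd": 10.0,
    },
    "train_fs": {
        "tile_size": 512,
        "stride": 512,
        "min_overlap": 0.5,
        "tissue_threshold": 0.1,
        "max_epochs": 22,
        "patience": 10,
        "batch_size": 64,
        "channels": None,
        "val_fraction": 0.2,
    },
    "train_ws": {
        "tile_size": 512,
        "warm_k": 32,
        "warm_epochs": 2,
        "k_start": 5,
        "k_end": 1,
        "mil_epochs": 5,
        "buffer_n": 512,
        "initial_lr": 0.001,
        "lr_decay_per_epoch": 0.9,
        "min_overlap": 0.5,
        "tissue_threshold": 0.1,
        "batch_size": 64,
        "channels": None,
        "val_fraction": 0.2,
    },
    "predict": {
        "tile_size": 512,
        "stride": 256,
        "tissue_threshold": 0.1,
        "threshold": 0.5,
        "heatmaps": False,
    },
    "evaluate": {
        "bootstrap_iterations": 1000,
    },
}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


@dataclass
class RunConfig:
    seed: int
    working_magnification: float
    synthesize: dict
    train_fs: dict
    train_ws: dict
    predict: dict
    evaluate: dict
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def fs_config(self) -> FsConfig:
        c = self.train_fs
        return FsConfig(
            optimizer=OptimizerConfig(batch_size=c["batch_size"]),
            augmentation=AugmentationConfig(),
            max_epochs=c["max_epochs"],
            patience=c["patience"],
            channels=tuple(c["channels"]) if c["channels"] else None,
            tissue_threshold=c["tissue_threshold"],
            seed=self.seed,
        )

    def mil_config(self) -> MilConfig:
        c = self.train_ws
        return MilConfig(
            optimizer=OptimizerConfig(batch_size=c["batch_size"]),
            augmentation=AugmentationConfig(),
            warm_k=c["warm_k"],
            warm_epochs=c["warm_epochs"],
            k_start=c["k_start"],
            k_end=c["k_end"],
            mil_epochs=c["mil_epochs"],
            buffer_n=c["buffer_n"],
            initial_lr=c["initial_lr"],
            lr_decay_per_epoch=c["lr_decay_per_epoch"],
            min_overlap=c["min_overlap"],
            tissue_threshold=c["tissue_threshold"],
            tile_size=c["tile_size"],
            channels=tuple(c["channels"]) if c["channels"] else None,
            seed=self.seed,
        )


def _check_keys(user: dict, defaults: dict, prefix: str, errors: list[str]) -> None:
    for key in user:
        if key not in defaults:
            suggestion = difflib.get_close_matches(key, defaults.keys(), n=1)
            hint = f" (did you mean {suggestion[0]!r}?)" if suggestion else ""
            errors.append(f"unknown key {prefix}{key!r}{hint}")
        elif isinstance(defaults[key], dict) and isinstance(user[key], dict):
            _check_keys(user[key], defaults[key], f"{prefix}{key}.", errors)


def _merge(user: dict, defaults: dict) -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = _merge(user[key], dval)
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    return out


def _overlay(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _overlay(out[k], v)
        else:
            out[k] = v
    return out


def _validate(cfg: dict, errors: list[str]) -> None:
    syn = cfg["synthesize"]
    for name in ("carcinoma_fraction", "necrosis_in_carcinoma", "necrosis_in_negative"):
        if not 0.0 <= syn[name] <= 1.0:
            errors.append(f"synthesize.{name} must be in [0, 1]")
    w, h = syn["slide_size"]
    if w < syn["tile_size"] or h < syn["tile_size"]:
        errors.append("synthesize.slide_size must be at least tile_size in both dimensions")
    ws = cfg["train_ws"]
    if ws["k_end"] > ws["k_start"]:
        errors.append("train_ws.k_end must not exceed train_ws.k_start")
    if ws["buffer_n"] % ws["batch_size"] != 0:
        errors.append("train_ws.buffer_n must be a multiple of train_ws.batch_size")
    fs = cfg["train_fs"]
    if fs["patience"] > fs["max_epochs"]:
        errors.append("train_fs.patience must not exceed train_fs.max_epochs")
    if cfg["evaluate"]["bootstrap_iterations"] < 1:
        errors.append("evaluate.bootstrap_iterations must be >= 1")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load, merge with defaults, and strictly validate a run configuration."""
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
    if overrides:
        user = _overlay(user, overrides)

    errors: list[str] = []
    _check_keys(user, DEFAULTS, "", errors)
    merged = _merge(user, DEFAULTS)
    _validate(merged, errors)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(
        seed=int(merged["seed"]),
        working_magnification=float(merged["working_magnification"]),
        synthesize=merged["synthesize"],
        train_fs=merged["train_fs"],
        train_ws=merged["train_ws"],
        predict=merged["predict"],
        evaluate=merged["evaluate"],
        raw=merged,
    )
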
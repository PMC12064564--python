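"""Run configuration and manifest handling for the command-line workflows."""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig", "load_config", "save_config", "write_manifest"]


@dataclass
class RunConfig:
    """Everything a command needs to re-run exactly.

    Flags override config-file values; the manifest written next to each
    artifact echoes the merged configuration and all seeds.
    """

    counts: str | None = None
    covariates: str | None = None
    metadata: str | None = None
    erc: str | None = None
    out: str = "microvi_out"
    seed: int = 0
    # model hyperparameters
    k: int = 5
    lam: float = 0.5
    upsilon: float = 0.5
    # optimizer
    iters: int = 30_000
    learning_rate: float = 0.01
    n_mc: int = 1
    # preprocessing
    filter_fraction: float | None = None
    common_sum: bool = False
    pseudo: float = 1.0
    # selection
    draws: int = 10
    folds: int = 5
    inits: int = 10
    # downstream
    knn: int = 10
    credible: float = 0.95
    posterior_samples: int = 100
    verbosity: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_manifest(out_dir, command: str, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a YAML manifest sufficient to re-run the command exactly."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
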
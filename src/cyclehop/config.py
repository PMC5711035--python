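"""Run configuration and reproducibility manifests.

All tunable parameters of a run live in one flat config object that can be
loaded from a YAML file and overridden by CLI flags. Every CLI run writes a
manifest (config values, seeds, package version) alongside its outputs,
sufficient to reproduce them exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    """Flat parameter set for the encode / simulate / search pipeline."""

    # periodicity
    transient_skip: int = 2
    r_max_threshold: float = 0.3
    drop_decay_term: bool = False
    p: int = 8
    t_start: float | None = None  # default: first time point after the transient

    # dynamics
    lambda_mix: float = 0.3
    temperature: float = 0.035
    update_prob: float = 0.2
    sparsify: bool = True

    # population protocol
    kappa: int = 200
    relax_steps: int = 200
    control_steps: int = 400
    post_steps: int = 0
    tau_window: int | None = None

    # search
    n_targ: int = 4
    mu_objective: int = 7
    ga_population: int = 50
    ga_generations: int = 100
    exhaustive: bool = False

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML key-value file; unknown keys are rejected by name."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_manifest(out_dir: str | Path, config: RunConfig, command: str, **extra) -> Path:
    """Write the reproducibility manifest next to a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "config": config.to_dict(),
        **extra,
    }
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
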
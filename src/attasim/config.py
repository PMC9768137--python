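"""Run configuration, validation and reproducibility manifests.

Configuration is a flat key-value mapping (YAML on disk) whose defaults
reproduce the reference study conditions exactly: 25 ants, 10,000 timesteps,
cost coefficient c = 0.3, a 0.05-step behaviour sweep with 10 replicates,
and evolutionary runs of 50 colonies for 10,000 generations with mutation
rate 0.01, mutation SD 0.1 and initial genotypes uniform on [0, 0.2].
Unknown keys are rejected; command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__


@dataclass
class RunConfig:
    """Flat configuration shared by the simulate / sweep / evolve commands."""

    # colony simulation
    tree_height: int = 20
    pp: float = 0.0
    pd: float = 0.0
    n_ants: int = 25
    t_max: int = 10_000
    cost_coefficient: float = 0.3
    forage_prob: float = 0.95
    detection_radius: int = 5
    replicates: int = 1
    # landscape sweep
    sweep_step: float = 0.05
    sweep_replicates: int = 10
    # evolution
    colonies: int = 50
    generations: int = 10_000
    mutation_rate: float = 0.01
    mutation_sd: float = 0.1
    init_min: float = 0.0
    init_max: float = 0.2
    thin: int = 100
    # bookkeeping
    seed: int = 0
    out_dir: str = "out"
    verbose: bool = False

    def validate(self) -> None:
        """Raise ValueError listing every offending key."""
        errors = []
        for key in ("pp", "pd", "forage_prob", "mutation_rate"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{key}={v} (must be in [0, 1])")
        for key in ("cost_coefficient", "mutation_sd", "sweep_step"):
            if getattr(self, key) < 0:
                errors.append(f"{key}={getattr(self, key)} (must be >= 0)")
        for key, lo in (("tree_height", 1), ("n_ants", 1), ("t_max", 0),
                        ("detection_radius", 0), ("replicates", 1),
                        ("sweep_replicates", 1), ("colonies", 2),
                        ("generations", 0), ("thin", 1)):
            if getattr(self, key) < lo:
                errors.append(f"{key}={getattr(self, key)} (must be >= {lo})")
        if not 0.0 <= self.init_min <= self.init_max <= 1.0:
            errors.append(f"init_min={self.init_min}, init_max={self.init_max} "
                          "(need 0 <= init_min <= init_max <= 1)")
        if not 0.0 < self.sweep_step <= 1.0:
            errors.append(f"sweep_step={self.sweep_step} (must be in (0, 1])")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides.

    ``overrides`` (typically CLI flags) take precedence over file values;
    ``None`` override values are ignored. Unknown keys in either source are
    rejected.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a flat key-value mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(values) - _FIELDS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    config = RunConfig(**values)
    config.validate()
    return config


def write_run_manifest(config: RunConfig, out_dir: str | Path) -> Path:
    """Write ``manifest.json`` recording the full configuration, the base
    seed and the software version — enough to re-run bit-identically.

    Creates ``out_dir`` if missing and returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "attasim",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "seed_derivation": (
            "simulate replicate r uses seed + r; sweep runs use "
            "SeedSequence((seed, node_pp, node_pd, replicate)); "
            "evolve replicate r uses seed + r"
        ),
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
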
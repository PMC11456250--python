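"""Validated run configuration and deterministic seed derivation.

A :class:`RunConfig` collects every knob of the pipeline commands (paths,
rank or rank range, restart count, noise model, priors, excess-zero
probability, simulator parameters, seed).  Configurations load from a YAML
file, with command-line flags overriding file values, and validate before
any computation runs.  All randomness in a command flows from the single
root ``seed`` through named stage sub-seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

SCHEMA_VERSION = 1

_RANGES = {
    "phi": (0.0, 1.0),
    "doublet_rate": (0.0, 1.0),
    "dropout_midpoint": (-50.0, 50.0),
    "step_size": (0.0, 10.0),
}
_POSITIVE = (
    "rank", "n_restarts", "max_iter", "n_mc_samples", "prior_shape", "prior_rate",
    "gate_prior_sd", "n_cells", "n_genes", "n_donors", "n_identity", "n_activity",
    "tensor_rank",
)


@dataclass
class RunConfig:
    """Flat, schema-versioned configuration for one pipeline command."""

    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    # factorization
    noise_model: str = "zip"
    rank: int = 8
    ranks: list[int] = field(default_factory=list)  # rank-scan range
    n_restarts: int = 10
    max_iter: int = 1000
    n_mc_samples: int = 2
    step_size: float = 0.2
    step_decay: float = 0.005
    prior_shape: float = 1.0
    prior_rate: float = 0.3
    gate_prior_mean: float = 0.0
    gate_prior_sd: float = 1.0
    mode_of_interest: int = -1
    # tensor simulation
    tensor_shape: list[int] = field(default_factory=lambda: [10, 20, 300])
    tensor_rank: int = 9
    factor_shape: float = 3.0
    factor_rate: float = 0.3
    phi: float = 0.0
    # scRNA-seq simulation
    n_cells: int = 3000
    n_genes: int = 1000
    n_donors: int = 6
    n_identity: int = 5
    n_activity: int = 3
    mean_de_log2fc: float = 0.75
    dropout: bool = True
    doublet_rate: float = 0.05
    # pseudobulk filters
    min_gene_total: int = 50
    min_group_frac: float = 0.02
    cpm: bool = True
    drop_doublets: bool = True
    # misc knobs surfaced elsewhere
    dropout_midpoint: float = 0.0

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {self.schema_version} != {SCHEMA_VERSION}"
            )
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_model not in ("zip", "gamma_poisson", "truncated_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic sub-seed for a named pipeline stage (< 2**31)."""
        h = np.random.SeedSequence(
            [self.seed, zlib.crc32(stage.encode()), index]
        )
        return int(h.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return asdict(self)


def parse_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (optional) and apply keyword overrides.

    Unknown keys raise a :class:`ValueError` naming the field; omitted keys
    take their documented defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
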
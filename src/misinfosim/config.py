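"""Run configuration and seed management.

All randomness in a run flows from one named base seed, fanned out to
stages by hashing the stage name — reproducible and parallelizable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


def derive_seed(base_seed: int, *parts: str | int) -> int:
    """Deterministic stage seed below 2^31, derived from a base seed and labels."""
    key = ":".join([str(base_seed), *map(str, parts)])
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class RunConfig:
    """Validated knobs of an end-to-end run."""

    seed: int = 0
    alpha: float = 3.0
    n_trials: int = 1000
    max_layers: int | None = None
    n_users: int = 500
    n_communities: int = 5
    resolution: float = 1.0
    embedder: str = "hashing"
    generator: str = "nearest-neighbour"
    paths: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.max_layers is not None and self.max_layers < 0:
            raise ValueError("max_layers must be non-negative or None")
        if self.n_users < 1 or self.n_communities < 1:
            raise ValueError("n_users and n_communities must be positive")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.blake2b(blob.encode(), digest_size=8).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = cls(**yaml.safe_load(fh))
        cfg.validate()
        return cfg

    def write_manifest(self, path: str | Path, **extra) -> None:
        """Record config hash, seed and free-form stage outputs for provenance."""
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "config": asdict(self), **extra}, fh, indent=2)
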
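"""Run configuration: strict parsing, seeds, and provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All parameters that affect pipeline numbers, with explicit seeds.

    Every random stage derives its seed from ``seed`` deterministically, so
    one integer reproduces the whole run.  Unknown keys are rejected.
    """

    seed: int
    # synthetic human cohort
    human: dict = field(default_factory=dict)
    # synthetic gene matrix
    gene: dict = field(default_factory=dict)
    # synthetic mouse cohort
    mouse: dict = field(default_factory=dict)
    # density / similarity stage
    n_grid: int = 512
    bandwidth_method: str = "silverman"
    epsilon: float = 1e-12
    # group comparison
    fdr_alpha: float = 0.01
    # PLS stage
    n_perm_pls: int = 5000
    n_boot: int = 1000
    z_threshold: float = 3.0
    # covariance network stage
    n_perm_edges: int = 10_000
    alphas: tuple[float, ...] = (0.05, 0.01)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("config must set an explicit integer seed")
        self.seed = int(self.seed)
        self.alphas = tuple(float(a) for a in self.alphas)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValidationError("config must set an explicit integer seed")
        return cls(**d)


def load_config(path, seed_override: int | None = None) -> RunConfig:
    """Load a YAML or JSON config file into a validated RunConfig."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    if seed_override is not None:
        data["seed"] = seed_override
    return RunConfig.from_dict(data)
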
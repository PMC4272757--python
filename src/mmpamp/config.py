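"""Analysis configuration shared across the pipeline stages.

Defaults: at most 40 breakable bonds per molecule, variable parts of at
most 10 heavy atoms, 50% Tanimoto similarity filter, alpha 0.05, minimum
5 pairs per tested transformation, and 1,000 bootstrap replicas.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # fragmentation limits
    max_cuts: int = 3
    max_variable_atoms: int = 10
    max_breakable_bonds: int = 40
    # pairing
    min_similarity: float = 0.5
    fp_radius: int = 2
    fp_bits: int = 2048
    # significance testing
    alpha: float = 0.05
    min_pairs: int = 5
    n_replicas: int = 1000
    seed: int = 0
    tie_tol: float = 1e-9
    include_out_of_domain: bool = False
    use_stereo: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_similarity <= 1:
            raise ValueError("min_similarity must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
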
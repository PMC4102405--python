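"""Pipeline configuration with documented defaults.

Every tunable of the pipeline lives here so that a run is fully described
by one serialisable object.  The sparse-correction parameters (sigma 10
for distance, 20 for torsion potentials), the 25 % sequence-identity cap
and the 10 % worst-prediction exclusion are the method's published
operating points; the melting-temperature cutoff separating mesostable
from thermostable training proteins, the smoothing kernel and the
torsion-domain boundary table are package defaults that can be overridden
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .structures import DEFAULT_TORSION_DOMAINS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    tm_cutoff_c: float = 70.0        # meso/thermo split (package default)
    identity_cap_pct: float = 25.0   # max pairwise identity within a set
    sigma_distance: float = 10.0     # sparse-data correction, distance
    sigma_torsion: float = 20.0      # sparse-data correction, torsion
    # decreasing half-kernel (center, +-1, +-2); symmetrised and normalised
    smoothing_kernel: list[float] = field(default_factory=lambda: [1.0, 0.5, 0.25])
    min_separation: int = 2          # minimum |i-j| for distance pairs
    torsion_domain_table: list = field(
        default_factory=lambda: [list(row) for row in DEFAULT_TORSION_DOMAINS])
    exclude_fraction: float = 0.1    # worst-prediction exclusion in stats
    anchor_policy: str = "one_pass"  # single corrective anchor re-fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_distance <= 0 or self.sigma_torsion <= 0:
            raise ValueError("sigma parameters must be positive")
        if not 0 <= self.exclude_fraction < 1:
            raise ValueError("exclude_fraction must be in [0, 1)")
        if not 0 < self.identity_cap_pct <= 100:
            raise ValueError("identity_cap_pct must be in (0, 100]")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if self.anchor_policy != "one_pass":
            raise ValueError(f"unknown anchor policy {self.anchor_policy!r}")

    @property
    def torsion_table(self) -> list[tuple]:
        return [tuple(row) for row in self.torsion_domain_table]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
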
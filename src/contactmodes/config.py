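"""Run configuration shared by the CLI subcommands and the analysis drivers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class RunConfig:
    """Tunable parameters of the pipeline.

    Defaults follow the analysis protocol: residue-residue contacts use a
    4.2 Å any-atom cutoff; contacts formed in more than 90% or fewer than
    10% of frames are treated as static and dropped; the eight dominant PCs
    are retained for discriminant analysis; hydrogen bonds use a 3.5 Å
    donor-acceptor distance cutoff and a 20 degree donor-centered angle
    cutoff; the membrane normal is z.
    """

    contact_cutoff_A: float = 4.2
    u_low: float = 0.1
    u_high: float = 0.9
    n_pcs: int = 8
    hbond_distance_A: float = 3.5
    hbond_angle_deg: float = 20.0
    membrane_normal_axis: str = "z"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_cutoff_A <= 0:
            raise ValueError("contact_cutoff_A must be positive")
        if not (0 <= self.u_low < 1):
            raise ValueError("u_low must be in [0, 1)")
        if not (0 < self.u_high <= 1):
            raise ValueError("u_high must be in (0, 1]")
        if self.u_low >= self.u_high:
            raise ValueError("u_low must be strictly less than u_high")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be a positive integer")
        if self.hbond_distance_A <= 0 or self.hbond_angle_deg <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")
        if self.membrane_normal_axis not in _AXES:
            raise ValueError("membrane_normal_axis must be one of x, y, z")

    @property
    def axis_index(self) -> int:
        return _AXES[self.membrane_normal_axis]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
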
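"""Run configuration: every tunable of the pipeline with its default.

Serializes to JSON or YAML (by file extension) and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .types import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # shell detection
    shell_mode: str = "second_peak"  # second_peak | cutoff | manual
    cutoff_fraction: float = 0.15
    manual_ell: Optional[float] = None
    bin_fraction: float = 0.005
    # symmetry
    target_m: int = 6
    m_set: tuple = (2, 3, 4, 5, 6, 7)
    # rho / correlogram
    rho_bin_size: Optional[float] = None  # None -> 2% of the arena side
    rho_sigma: Optional[float] = None  # None -> 4% of the arena side
    min_overlap: int = 20
    # classification
    n_shuffles: int = 100
    percentile: float = 95.0
    # temporal analysis
    window: float = 100.0  # seconds
    # randomness
    seed: Optional[int] = None

    def __post_init__(self):
        self.m_set = tuple(int(m) for m in self.m_set)
        if self.target_m not in self.m_set:
            raise ValidationError(
                f"m_set {self.m_set} must contain target_m={self.target_m}"
            )
        if self.shell_mode not in ("second_peak", "cutoff", "manual"):
            raise ValidationError(f"unknown shell_mode {self.shell_mode!r}")
        if self.shell_mode == "manual" and not (
            self.manual_ell is not None and self.manual_ell > 0
        ):
            raise ValidationError("manual shell_mode requires manual_ell > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["m_set"] = list(d["m_set"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d or {})
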
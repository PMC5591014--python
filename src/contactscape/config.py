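"""Pipeline configuration: one flat YAML mapping, eagerly validated.

Every analysis constant lives here with its default; unknown keys are
rejected by name, and stochastic runs require an explicit seed (there is no
silent default seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Dict, List, Optional

import yaml


@dataclass
class PipelineConfig:
    seed: Optional[int] = None
    primary_site: str = "GATC"
    secondary_site: str = "GTAC"
    window_size: int = 30
    window_step: int = 1
    exclusion_radius: int = 2
    z_threshold: float = 2.0
    q_threshold: float = 0.05
    normalization_span_bp: int = 15_000_000
    proximity_windows: List[int] = field(default_factory=lambda: [10_000, 20_000])
    permutations: int = 5_000
    profile_half_width: int = 2_000
    profile_bin: int = 10
    smooth_bins: int = 5
    # synthetic preset geometry
    genome_length: int = 500_000
    n_replicates: int = 2
    gene_n_per_class: int = 200
    # optional input paths (used instead of simulation when set)
    fasta: Optional[str] = None
    reads: Dict[str, List[str]] = field(default_factory=dict)  # condition -> replicate paths
    genes: Optional[str] = None
    features: Dict[str, str] = field(default_factory=dict)     # name -> BED path
    signal_track: Optional[str] = None

    def __post_init__(self) -> None:
        positive = ["window_size", "window_step", "normalization_span_bp",
                    "permutations", "profile_half_width", "profile_bin",
                    "smooth_bins", "genome_length", "n_replicates", "gene_n_per_class"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ["exclusion_radius"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ["z_threshold"]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.q_threshold < 1:
            raise ValueError(f"q_threshold must lie in (0,1), got {self.q_threshold}")
        if any(w < 0 for w in self.proximity_windows):
            raise ValueError("proximity windows must be >= 0")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("this operation is stochastic: an explicit seed is required")
        return int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict:
        return asdict(self)
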
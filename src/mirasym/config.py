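"""Pipeline configuration: a flat key-value schema shared by all subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # inputs
    hairpin_fasta: Optional[str] = None
    mature_coords: Optional[str] = None
    tag_counts: list = field(default_factory=list)  # list of paths
    tag_dialect: str = "tsv"
    # quantification
    min_reads: int = 100
    min_reads_per_strand: bool = False
    arm_window: int = 5
    bin_high: float = 10.0
    bin_moderate: float = 2.0
    # composition
    n_sets: int = 100
    window_start: int = 1
    window_end: int = 18
    two_sided: bool = False
    flank_halfwidth: int = 10
    flank_ci: float = 0.95
    # structure
    pairing_threshold: float = 0.5
    engine: str = "builtin"
    score_gc: float = 3.0
    score_au: float = 2.0
    score_gu: float = 1.0
    run_penalty: float = 0.5
    asym_penalty: float = 1.5
    # covariation
    fisher_method: str = "auto"
    fisher_n_mc: int = 10000
    enumeration_cap: int = 10**6
    collapse_nt1_u: bool = False
    # strata: all | by_arm | by_bin (comma-separable)
    strata: str = "all,by_arm,by_bin"
    # misc
    seed: int = 0
    outdir: str = "mirasym_out"

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.arm_window < 0 or self.n_sets < 1:
            raise ValueError("thresholds must be positive")
        if not self.bin_high > self.bin_moderate > 1.0:
            raise ValueError("bin thresholds must be strictly decreasing and > 1")
        if not 0.0 < self.pairing_threshold < 1.0:
            raise ValueError("pairing_threshold must be in (0, 1)")
        if not 1 <= self.window_start <= self.window_end:
            raise ValueError("bad resample window")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load YAML config (flat key-value), with keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(Path(path)) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
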
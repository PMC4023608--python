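"""Pipeline constants.

Every analysis constant lives in one auditable place: the normalization
target (tag counts are rescaled to a library of 10^7 specifically mapped
tags), the normalized-tag peak threshold (a window is peak-positive only if
its normalized count exceeds 20, strict), the knockout-background ratio
(peaks are kept only if their signal is at least 4-fold the normalized
background, inclusive), the empirical FDR operating point (0.1%), the
promoter window (+/-1000 bp of a TSS), the ncRNA association window
(20 kb), the knockdown fold-change cutoff (1.5, strict), and the physical
read/fragment geometry (25 bp reads, 200 bp fragments binned in 200 bp
windows).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    norm_target: float = 1e7
    peak_threshold: float = 20.0
    bg_ratio: float = 4.0
    fdr_target: float = 0.001
    promoter_window: int = 1000
    ncrna_window: int = 20_000
    fc_cutoff: float = 1.5
    fragment_len: int = 200
    window_size: int = 200
    read_len: int = 25
    bg_pseudocount: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "norm_target",
            "peak_threshold",
            "bg_ratio",
            "promoter_window",
            "ncrna_window",
            "fragment_len",
            "window_size",
            "read_len",
            "bg_pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
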
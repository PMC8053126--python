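"""Pipeline configuration.

Every analysis constant used across the pipeline lives here: differential
expression thresholds, the TSS assignment window, profile and motif windows,
coverage bin/smoothing widths, the relative motif-score threshold, the motif
E-value cutoff, and the accessibility-stratification cut sizes. Defaults are
the values used throughout the analysis this package implements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml


@dataclass
class PipelineConfig:
    # gene categorization (units: log2 fold change; BH-adjusted p)
    up_padj: float = 0.05
    up_log2fc: float = 1.5
    nr_padj: float = 0.5
    nr_log2fc_hi: float = 0.5
    # peak-to-gene assignment: full width of the window centered on the TSS (bp)
    tss_window: int = 60_000
    # sequence windows around peak centers (bp, half-widths)
    motif_flank: int = 250
    profile_halfwidth: int = 2_000
    gc_halfwidth: int = 5_000
    rank_halfwidth: int = 250
    # coverage binning (bp)
    gc_bin: int = 50
    track_bin: int = 20
    smooth_len: int = 60
    # motif scanning / enrichment
    rel_score_threshold: float = 0.8
    evalue_threshold: float = 1e-30
    # accessibility stratification cut sizes (full-scale study values;
    # synthetic runs pass cut sizes appropriate to the simulated cistrome)
    k_low_access: int = 17_125
    k_high_gc: int = 3_296
    k_high_motif: int = 6_593
    random_seed: int = 0

    def __post_init__(self) -> None:
        for f in ("tss_window", "motif_flank", "profile_halfwidth", "gc_halfwidth",
                  "rank_halfwidth", "gc_bin", "track_bin"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be a positive integer")
        if self.smooth_len < 0:
            raise ValueError("smooth_len must be >= 0")
        if not (0.0 <= self.rel_score_threshold <= 1.0):
            raise ValueError("rel_score_threshold must be in [0, 1]")
        for f in ("up_padj", "nr_padj"):
            if not (0.0 < getattr(self, f) <= 1.0):
                raise ValueError(f"{f} must be in (0, 1]")
        for f in ("k_low_access", "k_high_gc", "k_high_motif"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
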
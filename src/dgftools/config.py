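"""Analysis configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from typing import Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Pipeline thresholds and window definitions.

    Defaults follow the published footprinting workflow: a motif instance
    counts as DNase-supported when >= 90% of it is covered by a single
    footprint, and is kept only when its information-content-weighted
    conservation is >= 0.22. Enrichment tests use 10000 Monte Carlo
    repetitions; the co-regulator screen applies the four selection
    thresholds (adjusted p < 0.05, ratio > 1.05, >= 20 genes, ratio
    difference > 0.5).
    """

    overlap_threshold: float = 0.9
    conservation_threshold: float = 0.22
    conservation_default: float = 0.0
    overlap_mode: str = "single"          # single best footprint vs "union"
    mc_repetitions: int = 10000
    mc_alternative: str = "auto"          # auto | greater | less | two-sided
    fdr_alpha: float = 0.05
    tss_bin_width: int = 100
    tss_window: int = 5000
    promoter_upstream: int = 2500
    promoter_downstream: int = 500
    coreg_window: int = 5000
    ratio_threshold: float = 1.05
    min_gene_count: int = 20
    gene_count_scope: str = "combined"    # combined (both directions) vs "per-set"
    ratio_diff_threshold: float = 0.5
    distance_formula: str = "linear"      # 10*(a-b) vs "power": 10**(a-b)
    midpoint_flank: int = 12
    min_cross_cell_overlap: int = 6
    min_chip_overlap: int = 1
    core_cutoff: float = 0.75
    matrix_cutoff: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.overlap_threshold <= 1.0, "overlap_threshold in [0,1]"),
            (0.0 <= self.conservation_threshold <= 1.0, "conservation_threshold in [0,1]"),
            (0.0 <= self.conservation_default <= 1.0, "conservation_default in [0,1]"),
            (self.overlap_mode in ("single", "union"), "overlap_mode single|union"),
            (self.mc_repetitions >= 100, "mc_repetitions >= 100"),
            (self.mc_alternative in ("auto", "greater", "less", "two-sided"),
             "mc_alternative auto|greater|less|two-sided"),
            (0.0 < self.fdr_alpha < 1.0, "fdr_alpha in (0,1)"),
            (self.tss_bin_width > 0 and self.tss_window % self.tss_bin_width == 0,
             "tss_bin_width must divide tss_window"),
            (self.promoter_upstream >= 0 and self.promoter_downstream >= 0, "promoter spans >= 0"),
            (self.coreg_window > 0, "coreg_window > 0"),
            (self.ratio_threshold > 0, "ratio_threshold > 0"),
            (self.min_gene_count >= 0, "min_gene_count >= 0"),
            (self.gene_count_scope in ("combined", "per-set"), "gene_count_scope combined|per-set"),
            (self.ratio_diff_threshold >= 0, "ratio_diff_threshold >= 0"),
            (self.distance_formula in ("linear", "power"), "distance_formula linear|power"),
            (self.midpoint_flank >= 0, "midpoint_flank >= 0"),
            (1 <= self.min_cross_cell_overlap, "min_cross_cell_overlap >= 1"),
            (1 <= self.min_chip_overlap, "min_chip_overlap >= 1"),
            (0.0 <= self.core_cutoff <= 1.0 and 0.0 <= self.matrix_cutoff <= 1.0,
             "motif cutoffs in [0,1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
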
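"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """Thresholds, paths and seed for a full pipeline run.

    Defaults are the standard filter settings: >= 2 junction reads per
    sample, recurrence in >= 10 samples, match-score tiers 150/180, DE gene
    filters p < 0.05 and |log2FC| >= 2 (high tier), pathway FDR < 0.01.
    """

    outdir: str = "circnet_out"
    seed: int = 0
    # inputs; populated by the simulate stage when absent
    genome: Optional[str] = None
    gene_models: Optional[str] = None
    sample_sheet: Optional[str] = None
    mirna_fasta: Optional[str] = None
    targets_db1: Optional[str] = None
    targets_db2: Optional[str] = None
    de_table: Optional[str] = None
    gmt: Optional[str] = None
    # thresholds
    min_reads: int = 2
    recurrence_min_samples: int = 10
    recurrence_min_reads: int = 2
    score_low: float = 150.0
    score_high: float = 180.0
    energy_threshold: float = -20.0
    de_p_cutoff: float = 0.05
    de_lfc_cutoff: float = 2.0
    fdr_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.recurrence_min_samples < 1:
            raise ValueError("read/recurrence thresholds out of range")
        if not 0.0 <= self.de_p_cutoff <= 1.0 or not 0.0 <= self.fdr_cutoff <= 1.0:
            raise ValueError("p-value cutoffs must be in [0, 1]")
        if self.score_high < self.score_low:
            raise ValueError("score_high below score_low")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
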
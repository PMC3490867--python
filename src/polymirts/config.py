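"""Pipeline configuration: the thresholds applied by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their default values.

    Thresholds documented as strict use ``>`` comparisons; the SNP quality
    and depth minima are inclusive (``>=``).
    """

    #: minimum phred-scaled variant call quality (inclusive)
    min_snp_quality: float = 50.0
    #: minimum total read depth at the variant site (inclusive)
    min_depth: int = 15
    #: a 3'-UTR counts as covered when covered_fraction > this (strict)
    coverage_fraction_threshold: float = 0.5
    #: read length used for the mappability track
    read_length: int = 35
    #: mismatches tolerated when counting multi-mapping positions
    mismatches: int = 2
    #: SNP mappability is averaged over a window of this width (2 x L)
    mappability_window: int | None = None
    #: SNPs are retained when their window-averaged mappability equals this
    mappability_retain_value: float = 1.0
    #: |score(variant) - score(reference)| > delta marks a perturbed site
    perturbation_delta: float = 2.0
    #: miRNA counted as expressed when reads > this (strict)
    coexpr_min_mirna_reads: int = 10
    #: mRNA counted as expressed when FPKM > this (strict)
    coexpr_min_fpkm: float = 1.0
    #: allele-specific expression significance level (binomial exact test)
    ase_alpha: float = 0.001
    #: cross-tissue allelic-proportion significance level (Fisher exact test)
    allelic_fisher_alpha: float = 0.05
    #: width of the folding window used by the accessibility predictor
    folding_window: int = 150
    #: context scores are expressed in units of this scale factor
    score_scale: float = 10.0
    #: seed for every random draw in the pipeline
    rng_seed: int = 0
    #: count reverse-complement matches in the mappability track
    both_strands: bool = False
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mismatches < 0:
            raise ValueError("mismatches must be non-negative")
        for name in ("min_snp_quality", "min_depth", "coverage_fraction_threshold",
                     "perturbation_delta", "coexpr_min_mirna_reads",
                     "coexpr_min_fpkm", "ase_alpha", "allelic_fisher_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mappability_window is None:
            self.mappability_window = 2 * self.read_length

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key/value (YAML mapping) config file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat key/value mapping")
        known = {f.name for f in fields(cls)} - {"extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(extra=extra, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "extra"}
        out.update(self.extra)
        return out
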
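"""Analysis configuration with validated defaults and YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

from .errors import ConfigError


@dataclass
class ExpressionFilter:
    min_tpm: float = 1.0
    min_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_tpm < 0:
            raise ConfigError("min_tpm must be non-negative")
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ConfigError("min_fraction must lie in [0, 1]")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the pipeline.

    Defaults follow the published analysis: 500 top-variable genes,
    1,000 bootstrap iterations, ssGSEA exponent 0.25, expression filter
    of 1 TPM in at least 20% of samples, 70% locus-feature prevalence
    filter, BH-FDR, and a median per-patient aggregator.
    """

    top_k_variable_genes: int = 500
    bootstrap_iterations: int = 1000
    ssgsea_exponent: float = 0.25
    expression_filter: ExpressionFilter = field(default_factory=ExpressionFilter)
    herv_expressed_fraction: float = 0.70
    fdr_method: str = "benjamini-hochberg"
    per_patient_aggregator: str = "median"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.expression_filter, dict):
            self.expression_filter = ExpressionFilter(**self.expression_filter)
        if self.top_k_variable_genes < 1:
            raise ConfigError("top_k_variable_genes must be >= 1")
        if self.bootstrap_iterations < 1:
            raise ConfigError("bootstrap_iterations must be >= 1")
        if self.ssgsea_exponent < 0:
            raise ConfigError("ssgsea_exponent must be >= 0")
        if not (0.0 <= self.herv_expressed_fraction <= 1.0):
            raise ConfigError("herv_expressed_fraction must lie in [0, 1]")
        if self.fdr_method != "benjamini-hochberg":
            raise ConfigError("only benjamini-hochberg FDR is supported")
        if self.per_patient_aggregator not in ("median", "maximum"):
            raise ConfigError("per_patient_aggregator must be 'median' or 'maximum'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"unknown configuration key: {exc}") from exc

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
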
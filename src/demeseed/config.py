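"""Run configuration: YAML-backed, strictly validated."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .core import ConfigError, DEFAULT_SUBSTRATE_EXCLUDES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run. Unknown keys are rejected."""

    genotypes: str = ""
    genotype_format: str | None = None  # vcf | tsv | None (infer)
    samples: str = ""
    individuals: str = ""
    output_dir: str = "demeseed_out"
    location_code: str = "L"

    # site filters
    min_call_rate: float = 0.7
    max_het_fraction: float = 0.5

    # clustering / classification
    minor_variant_max_diff: int = 2
    min_overlap: float = 0.5
    f1_min_het_fraction: float = 0.9
    min_block_sites: int = 3

    # co-occurrence
    thresholds_m: list[float] = field(
        default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0]
    )
    min_n_list: list[int] = field(default_factory=lambda: [2, 6])
    substrate_excludes: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_SUBSTRATE_EXCLUDES)
    )
    mixing_radius_m: float = 1.0
    mle_replicates: int = 100
    mle_draws: int = 10_000

    # founder model
    p_multi: float | None = None  # None: wired from the MLE theta-hat
    priors: list[str] = field(
        default_factory=lambda: ["fixed:0.5", "fixed:0.1", "uniform", "beta:2,2"]
    )
    founder_trials: int = 10_000

    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_call_rate <= 1.0):
            raise ConfigError("min_call_rate must lie in (0, 1]")
        if not (0.0 < self.max_het_fraction <= 1.0):
            raise ConfigError("max_het_fraction must lie in (0, 1]")
        if not (0.0 < self.min_overlap <= 1.0):
            raise ConfigError("min_overlap must lie in (0, 1]")
        if not (0.0 < self.f1_min_het_fraction <= 1.0):
            raise ConfigError("f1_min_het_fraction must lie in (0, 1]")
        if self.minor_variant_max_diff < 1 or self.min_block_sites < 1:
            raise ConfigError("count parameters must be >= 1")
        if self.p_multi is not None and not (0.0 < self.p_multi < 1.0):
            raise ConfigError("p_multi must lie in (0, 1)")
        if any(n < 1 for n in self.min_n_list):
            raise ConfigError("min_n values must be >= 1")
        if self.founder_trials < 1 or self.mle_replicates < 1:
            raise ConfigError("trial counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
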
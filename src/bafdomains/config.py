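"""Pipeline configuration: every numeric rule parameter in one place.

Defaults reproduce the published analysis conventions: 200-bp within-sample
peak merging, 3-of-4 consensus with a 2-kb merge gap for BAF ATPase peaks
(5 kb for H3K27me3 polycomb domains), a twofold fusion-vs-control signal
filter, the ±1-kb TSS promoter window with an H3K4me3 fallback threshold of
8 normalized units, per-10-million-fragment track normalization, 20-kb
display windows at 100-bp (heat map) and 10-bp (composite) resolution with a
99th-percentile cap, width quartiles, and fourfold / adjusted-P<0.05
differential-expression cutoffs with 5x / 20x signature folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    within_sample_merge_gap: int = 200
    consensus_min_support: int = 3
    consensus_merge_gap_baf: int = 2000
    consensus_merge_gap_polycomb: int = 5000
    fusion_min_fold: float = 2.0
    tss_window: int = 1000
    promoter_signal_threshold: float = 8.0
    normalization_depth: int = 10_000_000
    window_span: int = 20_000
    heatmap_bin: int = 100
    composite_bin: int = 10
    cap_percentile: float = 99.0
    n_quantiles: int = 4
    de_fold: float = 4.0
    de_alpha: float = 0.05
    signature_fold_tcga_joint: float = 5.0
    signature_fold_tcga_pairwise: float = 20.0
    log2_pseudocount: float = 1.0
    signature_pseudocount: float = 0.1
    state_high_threshold: float = 1.0
    hcluster_k: int = 8
    gene_width_statistic: str = "max"  # max | mean | nearest

    def __post_init__(self) -> None:
        positive = [
            "within_sample_merge_gap", "consensus_merge_gap_baf",
            "consensus_merge_gap_polycomb", "tss_window", "normalization_depth",
            "window_span", "heatmap_bin", "composite_bin",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("fusion_min_fold", "de_fold",
                     "signature_fold_tcga_joint", "signature_fold_tcga_pairwise"):
            if getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be > 1")
        if not (0 < self.de_alpha < 1):
            raise ConfigError("de_alpha must be in (0, 1)")
        if self.n_quantiles < 2:
            raise ConfigError("n_quantiles must be >= 2")
        if not (0 < self.cap_percentile <= 100):
            raise ConfigError("cap_percentile must be in (0, 100]")
        if self.log2_pseudocount <= 0:
            raise ConfigError("log2_pseudocount must be > 0")
        if self.gene_width_statistic not in ("max", "mean", "nearest"):
            raise ConfigError("gene_width_statistic must be max, mean or nearest")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing keys take defaults, unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {', '.join(unknown)}")
    coerced = {}
    for key, value in raw.items():
        ftype = known[key].type
        try:
            if ftype == "int":
                if isinstance(value, float) and not value.is_integer():
                    raise ConfigError(f"{path}: key '{key}' must be an integer")
                coerced[key] = int(value)
            elif ftype == "float":
                coerced[key] = float(value)
            else:
                coerced[key] = str(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: key '{key}': {exc}") from exc
    return PipelineConfig(**coerced)
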
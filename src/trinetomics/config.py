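"""Analysis configuration: every statistical threshold used by the pipeline.

Defaults are the values the analysis is defined with: per-round significance
p < 0.05 for triangular retention, Benjamini–Hochberg q < 0.1 and
|rho| >= 0.3 for network edges, soft threshold beta = 13 with a scale-free
fit target, dynamic-cut deep split 4 with minimum module size 3, reporter
|Z| >= 1.96, and 5-repeat 10-fold down-sampling cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # correlation screens
    p_threshold: float = 0.05          # per-leg triangular retention
    q_threshold: float = 0.1           # BH FDR for network edges
    rho_threshold: float = 0.3         # |Spearman rho| cutoff for network edges
    # metabolite co-abundance clustering
    beta: int = 13                     # signed soft-threshold power
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    scale_free_r2_target: float = 0.8
    deep_split: int = 4
    min_module_size: int = 3
    # preprocessing
    prevalence_min_fraction: float = 0.10   # strict > filter
    # functional enrichment
    reporter_z_threshold: float = 1.96
    reporter_draws: int = 1000
    # PERMANOVA
    n_permutations: int = 999
    # community analysis
    min_community_size: int = 5
    # cross-validated prediction
    cv_folds: int = 10
    cv_repeats: int = 5
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0 <= self.rho_threshold <= 1:
            raise ValueError(f"rho_threshold must lie in [0, 1], got {self.rho_threshold}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not self.beta_grid or any(b <= 0 for b in self.beta_grid):
            raise ValueError("beta_grid must be a non-empty list of positive powers")
        if not 0 <= self.scale_free_r2_target <= 1:
            raise ValueError("scale_free_r2_target must lie in [0, 1]")
        if not 0 <= self.deep_split <= 4:
            raise ValueError(f"deep_split must lie in 0..4, got {self.deep_split}")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 < self.prevalence_min_fraction < 1:
            raise ValueError("prevalence_min_fraction must lie in (0, 1)")
        if self.reporter_z_threshold <= 0:
            raise ValueError("reporter_z_threshold must be positive")
        if self.n_permutations < 1 or self.reporter_draws < 1:
            raise ValueError("permutation/draw counts must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path=None) -> AnalysisConfig:
    """Load a YAML config; omitted keys take the defaults, unknown keys are rejected."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(**raw)
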
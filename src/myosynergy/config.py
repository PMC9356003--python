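"""Pipeline configuration: analysis constants and cohort settings.

Defaults mirror the analysis protocol: 30 NMF restarts, VAF tolerance 1e-5
over 50 consecutive iterations, VAF > 0.95 synergy-count selection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .synthetic import CohortConfig


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    nmf_restarts: int = 30
    nmf_tol: float = 1e-5
    nmf_tol_window: int = 50
    nmf_max_iter: int = 500
    vaf_threshold: float = 0.95
    nmf_decimate: int = 2
    response_intercept: bool = False
    jackknife_pseudo_values: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.vaf_threshold <= 1:
            raise ValueError("vaf_threshold must lie in (0, 1]")
        if self.nmf_restarts < 1 or self.nmf_decimate < 1:
            raise ValueError("nmf_restarts and nmf_decimate must be >= 1")
        if self.nmf_tol <= 0:
            raise ValueError("nmf_tol must be positive")

    @property
    def nmf_kwargs(self) -> dict:
        return dict(restarts=self.nmf_restarts, tol=self.nmf_tol,
                    tol_window=self.nmf_tol_window, max_iter=self.nmf_max_iter)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["cohort"] = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in d["cohort"].items()}
    return d


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    cohort_data = dict(data.pop("cohort", {}))
    valid = {f.name for f in fields(CohortConfig)}
    unknown = set(cohort_data) - valid
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    for key, value in cohort_data.items():
        if isinstance(value, list):
            cohort_data[key] = tuple(value)
    valid_top = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(cohort=CohortConfig(**cohort_data), **data)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
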
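"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluate import RegressorConfig
from .ga import GAConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Settings shared across pipeline stages.

    ``ws`` is the sliding-window width (odd); ``groups`` selects and
    orders the feature groups; GA and regressor settings nest their own
    dataclasses.  A YAML file with top-level keys matching the field
    names populates this; command-line flags override afterwards.
    """

    seed: int = 0
    ws: int = 3
    pad: str = "zero"
    min_models: int = 5
    min_length: int = 25
    groups: list[str] | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.ws < 1 or self.ws % 2 == 0:
            raise ValueError("ws must be odd and >= 1")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    ga = GAConfig(**data.pop("ga", {}))
    rc = RegressorConfig(**data.pop("regressor", {}))
    data.update({k: v for k, v in overrides.items() if v is not None})
    seed = data.get("seed")
    if seed is not None:
        ga.seed = rc.seed = int(seed)
    return PipelineConfig(ga=ga, regressor=rc, **data)
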
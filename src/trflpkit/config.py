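"""Run configuration: one YAML file reaching every stage's parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Tuple, Union

import yaml

from .simulate import ScenarioConfig
from .trflp import HHAI_CUT_OFFSET, HHAI_SITE

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full pipeline run. Unknown keys are rejected."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    outdir: str = "runs/run"
    enzyme_site: str = HHAI_SITE
    cut_offset: int = HHAI_CUT_OFFSET
    channel: str = "forward"
    bin_width: float = 1.0
    size_min: float = 34.0
    size_max: float = 966.0
    rel_threshold: float = 0.0
    peak_scale: float = 1000.0
    n_perm: int = 999
    n_boot: int = 1000
    n_null: int = 200
    alpha: float = 0.05
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1 or self.n_boot < 1 or self.n_null < 1:
            raise ValueError("replication counts must be >= 1")


def _build(cls, data: Mapping[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: Union[str, Path]) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    scenario_raw = raw.pop("scenario", {}) or {}
    if "layers" in scenario_raw:
        scenario_raw["layers"] = tuple(scenario_raw["layers"])
    if "trf_range" in scenario_raw:
        scenario_raw["trf_range"] = tuple(scenario_raw["trf_range"])
    scenario = _build(ScenarioConfig, scenario_raw)
    return _build(RunConfig, {**raw, "scenario": scenario})


def dump_config(config: RunConfig, path: Union[str, Path]) -> None:
    data = asdict(config)
    data["scenario"]["layers"] = list(data["scenario"]["layers"])
    data["scenario"]["trf_range"] = list(data["scenario"]["trf_range"])
    data["scenario"]["layer_groups"] = dict(data["scenario"]["layer_groups"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
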
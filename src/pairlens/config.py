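"""Pipeline configuration: one seeded object covering every stage, with
YAML round-tripping and a canonical hash for the run manifest."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import yaml

from .align import ScoringScheme
from .clusters import ClusterConfig, SplitConfig
from .restriction import RestrictionConfig
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    With ``input_pairs`` / ``input_candidates`` unset, the simulator
    produces the repertoire; otherwise records are read from those files
    and downstream behaviour is identical.  A fixed ``seed`` makes the
    whole run bit-reproducible.
    """

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    restriction: RestrictionConfig = field(default_factory=RestrictionConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    splitting: SplitConfig = field(default_factory=SplitConfig)
    n_v_per_locus: int = 8
    n_j_per_locus: int = 4
    germline_combine: str = "combined"  # v_only | j_only | combined
    input_pairs: Optional[str] = None
    input_candidates: Optional[str] = None
    input_dialect: str = "airr"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy with the top-level seed pushed into every stage config."""
        return dataclasses.replace(
            self,
            seed=seed,
            simulation=dataclasses.replace(self.simulation, seed=seed),
            restriction=dataclasses.replace(self.restriction, seed=seed),
        )

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def _build(section: Dict, cls):
    return cls(**section) if section else cls()


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML.

    Top-level keys mirror the dataclass fields; stage sections
    (``simulation``, ``scoring``, ``restriction``, ``clustering``,
    ``splitting``) are optional mappings of that stage's parameters.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {
        "simulation": SimulationConfig,
        "scoring": ScoringScheme,
        "restriction": RestrictionConfig,
        "clustering": ClusterConfig,
        "splitting": SplitConfig,
    }
    kwargs: Dict = {}
    for key, value in raw.items():
        if key in sections:
            if key == "simulation" and "cdr3_len_range" in (value or {}):
                value["cdr3_len_range"] = tuple(value["cdr3_len_range"])
            if key == "clustering" and "thresholds" in (value or {}):
                value["thresholds"] = tuple(value["thresholds"])
            if key == "splitting" and "fractions" in (value or {}):
                value["fractions"] = tuple(value["fractions"])
            kwargs[key] = _build(value, sections[key])
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    return cfg.with_seed(cfg.seed)


def dump_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
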
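"""Run configuration: one YAML document describing a full pipeline run.

Sections mirror the package's stages: ``model`` (potential parameters),
``ga`` (search), ``hbond`` (detection criterion), plus scalar analysis
settings.  Unknown keys are rejected loudly, and a config round-trips
through YAML losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .ga import GAConfig
from .potential import EnergyModel
from .shells import FIRST_SHELL_CUTOFF, HBondCriterion

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    model: EnergyModel = field(default_factory=EnergyModel)
    ga: GAConfig = field(default_factory=GAConfig)
    hbond: HBondCriterion = field(default_factory=HBondCriterion)
    first_shell_cutoff: float = FIRST_SHELL_CUTOFF
    temperature: float = 298.15
    rng_seed: int = 0
    n_candidates_thermo: int = 3  # pool entries ranked at 0 K vs T

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "ga": self.ga.to_dict(),
            "hbond": dataclasses.asdict(self.hbond),
            "first_shell_cutoff": self.first_shell_cutoff,
            "temperature": self.temperature,
            "rng_seed": self.rng_seed,
            "n_candidates_thermo": self.n_candidates_thermo,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data or {})
        known = {
            "model",
            "ga",
            "hbond",
            "first_shell_cutoff",
            "temperature",
            "rng_seed",
            "n_candidates_thermo",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            model = EnergyModel.from_dict(data.get("model", {}))
            ga = GAConfig.from_dict(data.get("ga", {}))
            hb = data.get("hbond", {})
            extra = set(hb) - {"max_OO_distance", "min_OHO_angle", "max_HO_distance"}
            if extra:
                raise ConfigError(f"unknown hbond keys: {sorted(extra)}")
            hbond = HBondCriterion(**hb)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cls(
            model=model,
            ga=ga,
            hbond=hbond,
            first_shell_cutoff=float(data.get("first_shell_cutoff", FIRST_SHELL_CUTOFF)),
            temperature=float(data.get("temperature", 298.15)),
            rng_seed=int(data.get("rng_seed", 0)),
            n_candidates_thermo=int(data.get("n_candidates_thermo", 3)),
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(raw)


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize to YAML (sorted keys: stable byte-for-byte output)."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
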
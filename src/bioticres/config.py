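"""Study configuration: durations, bootstrap settings, fecundities, designs.

A single YAML (or JSON — YAML is a superset) file configures a run; every
field has a default mirroring the copepod-mosquito study design: five
prey densities {2, 4, 7, 10, 15} with 5 replicates, five availability
ratios summing to 20 with 3 replicates, 1-period (6-h) trials, 2000
bootstrap resamples at 95% confidence, significance threshold 0.05, and
literature fecundity proxies for the three copepod predators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import DEFAULT_GROUP_PARAMS, FRDesign, SwitchDesign

__all__ = ["StudyConfig", "DEFAULT_FECUNDITY", "ConfigError"]

# clutch weight per female body weight per day, from the literature
DEFAULT_FECUNDITY = {
    "M. albidus": 0.350,
    "M. fuscus": 0.200,
    "M. viridis": 0.370,
}


class ConfigError(ValueError):
    """Invalid or inconsistent study configuration."""


@dataclass
class StudyConfig:
    duration: float = 1.0
    n_boot: int = 2000
    confidence: float = 0.95
    alpha_level: float = 0.05
    seed: int = 0
    fecundity: dict = field(default_factory=lambda: dict(DEFAULT_FECUNDITY))
    invader_prey: str = "A. albopictus"
    densities: tuple = (2, 4, 7, 10, 15)
    fr_replicates: int = 5
    ratios: tuple = ((2, 18), (5, 15), (10, 10), (15, 5), (18, 2))
    switch_replicates: int = 3
    control_replicates: int = 1
    round_decimals: int = 3
    sim_group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if not 0 < self.confidence < 1:
            raise ConfigError("confidence must be in (0, 1)")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        if not 0 < self.alpha_level < 1:
            raise ConfigError("alpha_level must be in (0, 1)")
        if any(v <= 0 for v in self.fecundity.values()):
            raise ConfigError("fecundity proxies must be positive")

    @property
    def fr_design(self) -> FRDesign:
        return FRDesign(
            densities=tuple(self.densities),
            replicates=self.fr_replicates,
            control_replicates=self.control_replicates,
        )

    @property
    def switch_design(self) -> SwitchDesign:
        return SwitchDesign(
            ratios=tuple(tuple(r) for r in self.ratios),
            replicates=self.switch_replicates,
            control_replicates=self.control_replicates,
        )

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "sim_group_params" in raw:
            raw["sim_group_params"] = {
                _parse_group_key(k): tuple(v) for k, v in raw["sim_group_params"].items()
            }
        if "ratios" in raw:
            raw["ratios"] = tuple(tuple(r) for r in raw["ratios"])
        if "densities" in raw:
            raw["densities"] = tuple(raw["densities"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim_group_params"] = {
            "|".join(k): list(v) for k, v in self.sim_group_params.items()
        }
        d["densities"] = list(self.densities)
        d["ratios"] = [list(r) for r in self.ratios]
        return d


def _parse_group_key(key):
    if isinstance(key, str):
        parts = key.split("|")
        if len(parts) != 2:
            raise ConfigError(
                f"sim_group_params keys must be 'predator|prey' strings, got {key!r}"
            )
        return tuple(parts)
    return tuple(key)
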
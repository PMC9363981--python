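"""Scenario configuration: the manipulation grid and all fixed parameters.

A :class:`ScenarioConfig` pins down one simulation permutation — population
size, round count, the three manipulated factors (training regime,
broadcaster condition, baseline cue-sensitivity level) and every fixed
parameter block — plus the master seed. Identical (config, seed) pairs
reproduce bit-identical runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

from .belief import CredibilityParams
from .cues import BASE_MCS_LEVELS, CueParams
from .inoculation import TRAINING_REGIMES, InoculationParams

__all__ = [
    "ConfigError",
    "BROADCASTER_CONDITIONS",
    "ScenarioConfig",
    "active_broadcaster_values",
]

#: The three broadcaster conditions. Honest communicates the ground truth
#: (0.5), biased communicates 0.75; a lone broadcaster is active twice every
#: three rounds, competing broadcasters alternate with a peer-only round.
BROADCASTER_CONDITIONS = ("honest", "biased", "competing")

HONEST_VALUE = 0.5
BIASED_VALUE = 0.75


class ConfigError(ValueError):
    """Invalid scenario configuration; the message names the offending field."""


@dataclass(frozen=True)
class ScenarioConfig:
    n_citizens: int = 1000
    rounds: int = 25
    training_regime: str = "none"
    broadcaster_condition: str = "honest"
    base_mcs_level: str = "medium"
    credibility: CredibilityParams = field(default_factory=CredibilityParams)
    cues: CueParams = field(default_factory=CueParams)
    inoculation: InoculationParams | None = None
    seed: int = 0
    replicates: int = 1
    grid_size: float = 100.0

    def __post_init__(self) -> None:
        if self.n_citizens < 1:
            raise ConfigError(f"n_citizens must be >= 1, got {self.n_citizens}")
        if self.rounds < 0:
            raise ConfigError(f"rounds must be >= 0, got {self.rounds}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if self.training_regime.lower() not in TRAINING_REGIMES:
            raise ConfigError(
                f"training_regime must be one of {sorted(TRAINING_REGIMES)}, "
                f"got {self.training_regime!r}"
            )
        if self.broadcaster_condition.lower() not in BROADCASTER_CONDITIONS:
            raise ConfigError(
                f"broadcaster_condition must be one of {BROADCASTER_CONDITIONS}, "
                f"got {self.broadcaster_condition!r}"
            )
        if self.base_mcs_level.lower() not in BASE_MCS_LEVELS:
            raise ConfigError(
                f"base_mcs_level must be one of {sorted(BASE_MCS_LEVELS)}, "
                f"got {self.base_mcs_level!r}"
            )
        if self.inoculation is None:
            object.__setattr__(
                self,
                "inoculation",
                InoculationParams.for_regime(self.training_regime),
            )

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with fields replaced (training regime resets its schedule)."""
        if "training_regime" in kwargs and "inoculation" not in kwargs:
            kwargs["inoculation"] = None
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        if "credibility" in data and isinstance(data["credibility"], dict):
            data["credibility"] = CredibilityParams(**data["credibility"])
        if "cues" in data and isinstance(data["cues"], dict):
            data["cues"] = CueParams(**data["cues"])
        if "inoculation" in data and isinstance(data["inoculation"], dict):
            ino = dict(data["inoculation"])
            if "schedule" in ino:
                ino["schedule"] = tuple(tuple(pair) for pair in ino["schedule"])
            data["inoculation"] = InoculationParams(**ino)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:  # bad nested field names
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def active_broadcaster_values(condition: str, round_index: int) -> list[tuple[str, float]]:
    """Which broadcasters speak in a given (1-based) round.

    A lone honest or biased broadcaster is active on every round except
    multiples of three ("twice every three time points"). Under competition
    the honest broadcaster takes rounds = 1 (mod 3), the biased one rounds
    = 2 (mod 3), and multiples of three are peer-to-peer only — never more
    than one broadcaster per round.
    """
    condition = condition.lower()
    phase = round_index % 3
    if condition == "honest":
        return [] if phase == 0 else [("honest", HONEST_VALUE)]
    if condition == "biased":
        return [] if phase == 0 else [("biased", BIASED_VALUE)]
    if condition == "competing":
        if phase == 1:
            return [("honest", HONEST_VALUE)]
        if phase == 2:
            return [("biased", BIASED_VALUE)]
        return []
    raise ConfigError(f"unknown broadcaster_condition {condition!r}")
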
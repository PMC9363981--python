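"""Misinformation cues: generation, probabilistic detection, rejection classification.

Every communication carries a scalar cue value in [0, 1] standing in for the
tell-tale signs of manipulative content (emotive language, fake experts,
conspiratorial framing ...). Cue intensity is drawn from a truncated normal
whose mean grows with how far the communicated value deviates from the
sender's perception of audience belief — persuading away from the perceived
consensus takes more manipulative rhetoric. Citizens detect cues
probabilistically against their current cue sensitivity (baseline plus any
inoculation-training effect).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .sampling import truncated_normal

__all__ = [
    "BASE_MCS_LEVELS",
    "CueParams",
    "SensitivityState",
    "RejectionKind",
    "generate_cue",
    "detect_misinformation",
    "classify_rejection",
    "sample_base_mcs",
]

#: Population means of baseline misinformation-cue sensitivity per condition.
BASE_MCS_LEVELS = {"low": 0.05, "medium": 0.2, "high": 0.35}

#: SD of the truncated-normal draw of baseline sensitivity.
BASE_MCS_SD = 0.05


@dataclass(frozen=True)
class CueParams:
    """Fixed cue parameters.

    broadcast_cue_sd
        SD of the truncated normal generating cue values (senders of both
        kinds).
    detect_sd
        SD of the detection-threshold draw around current sensitivity.
    alpha_citizen
        Citizens' proclivity to deploy cues relative to broadcasters
        (broadcasters use alpha = 1 implicitly).
    truth_value
        Ground truth of the simulated world.
    fp_band
        Half-width of the band around the truth inside which a cue-based
        rejection counts as a false positive.
    """

    broadcast_cue_sd: float = 0.2
    detect_sd: float = 0.25
    alpha_citizen: float = 0.2
    truth_value: float = 0.5
    fp_band: float = 0.05


@dataclass
class SensitivityState:
    """Baseline and current misinformation-cue sensitivity of one citizen.

    ``current_mcs`` equals ``base_mcs`` until training adds a fixed effect,
    after which it decays linearly back toward baseline;
    ``age_since_training`` counts rounds since the last (re)training, 0
    meaning never trained.
    """

    base_mcs: float
    current_mcs: float
    ever_trained: bool = False
    age_since_training: int = 0

    @classmethod
    def at_baseline(cls, base_mcs: float) -> "SensitivityState":
        return cls(base_mcs=base_mcs, current_mcs=base_mcs)


class RejectionKind(Enum):
    CORRECT_REJECTION = "correct_rejection"
    FALSE_POSITIVE = "false_positive"


def generate_cue(
    intended_value: float,
    perceived_audience_mean: float,
    alpha: float,
    sd: float,
    rng: np.random.Generator,
) -> float:
    """Draw the cue value attached to a communication.

    One truncated-normal draw on [0, 1] with mean
    ``|intended − audience| × alpha`` (alpha = 1 for broadcasters,
    alpha_citizen for citizens) and the configured SD.
    """
    mean = abs(intended_value - perceived_audience_mean) * alpha
    return truncated_normal(rng, mean, sd)


def detect_misinformation(
    cue: float,
    current_mcs: float,
    sd: float,
    rng: np.random.Generator,
) -> bool:
    """One probabilistic detection check; True means the message is rejected.

    A threshold is drawn from a truncated normal on [0, 1] centred on the
    citizen's current sensitivity; the message is flagged when the inverse
    cue value (1 − cue) falls at or below it. High cues and high
    sensitivity both raise the rejection probability — including for
    truthful content (the false-positive channel).
    """
    sample = truncated_normal(rng, current_mcs, sd)
    return (1.0 - cue) <= sample


def classify_rejection(value: float, params: CueParams = CueParams()) -> RejectionKind:
    """Classify a cue-based rejection by proximity to the ground truth.

    Values within ±fp_band of the truth (boundary inclusive) were wrongly
    rejected; anything further out is a correct rejection of misinformation.
    """
    # small epsilon keeps the inclusive boundary robust to float representation
    if abs(value - params.truth_value) <= params.fp_band + 1e-12:
        return RejectionKind.FALSE_POSITIVE
    return RejectionKind.CORRECT_REJECTION


def sample_base_mcs(level: str, rng: np.random.Generator) -> float:
    """Draw one citizen's baseline cue sensitivity for a named condition."""
    try:
        mean = BASE_MCS_LEVELS[level.lower()]
    except KeyError:
        raise ValueError(
            f"unknown base_mcs level {level!r}; expected one of {sorted(BASE_MCS_LEVELS)}"
        ) from None
    return truncated_normal(rng, mean, BASE_MCS_SD)
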
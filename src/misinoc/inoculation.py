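"""Inoculation training: external campaigns, peer-to-peer spread, decay.

Training ("prebunking") raises a citizen's misinformation-cue sensitivity by
a fixed effect size calibrated to the d ≈ 0.3 lower bound reported for
game-based inoculation interventions. The boost holds for a short duration
and then decays linearly back to baseline, but trained citizens may pass the
training on to their direct peers, so a critical mass of sharers can sustain
a trained equilibrium against decay — the psychological analogue of herd
immunity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cues import SensitivityState

__all__ = [
    "TRAINING_REGIMES",
    "InoculationParams",
    "apply_training",
    "decay_step",
    "peer_share_decision",
    "run_external_campaign",
]

#: Named external-campaign schedules as (round, fraction of citizens) pairs.
#: "upfront" trains 60% once at the start; "staggered" spreads the same 60%
#: over three 20% sessions at rounds 1, 5 and 10.
TRAINING_REGIMES: dict[str, tuple[tuple[int, float], ...]] = {
    "none": (),
    "upfront": ((1, 0.60),),
    "staggered": ((1, 0.20), (5, 0.20), (10, 0.20)),
}


@dataclass(frozen=True)
class InoculationParams:
    """Training parameters.

    effect
        Additive boost to cue sensitivity per training (Inoc_Effect).
    duration
        Rounds after training during which no decay occurs.
    decay_rate
        Linear decay per round toward baseline once the duration has passed.
    peer_share_prob
        Base per-round probability that a trained citizen shares the
        training with all direct peers, scaled by current sensitivity
        relative to the effect size.
    schedule
        External campaign as (round, fraction) pairs.
    peer_sharing
        Master switch for lateral transmission of training.
    """

    effect: float = 0.3
    duration: int = 2
    decay_rate: float = 0.15
    peer_share_prob: float = 0.05
    schedule: tuple[tuple[int, float], ...] = ()
    peer_sharing: bool = True

    def __post_init__(self) -> None:
        for name, v in (("effect", self.effect), ("decay_rate", self.decay_rate),
                        ("peer_share_prob", self.peer_share_prob)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for rnd, frac in self.schedule:
            if rnd < 1:
                raise ValueError(f"schedule round {rnd} must be >= 1")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"schedule fraction {frac} must lie in [0, 1]")

    @classmethod
    def for_regime(cls, regime: str, **overrides) -> "InoculationParams":
        try:
            schedule = TRAINING_REGIMES[regime.lower()]
        except KeyError:
            raise ValueError(
                f"unknown training regime {regime!r}; expected one of {sorted(TRAINING_REGIMES)}"
            ) from None
        return cls(schedule=schedule, **overrides)


def apply_training(s: SensitivityState, p: InoculationParams) -> None:
    """(Re)train a citizen: add the effect to baseline, reset the clock.

    Re-training refreshes rather than stacks: sensitivity is set to
    min(base + effect, 1) regardless of any residual boost.
    """
    s.current_mcs = min(s.base_mcs + p.effect, 1.0)
    s.age_since_training = 1
    s.ever_trained = True


def decay_step(s: SensitivityState, p: InoculationParams) -> None:
    """Age a trained citizen by one round and decay past the hold duration."""
    if not s.ever_trained:
        return
    s.age_since_training += 1
    if s.age_since_training > p.duration:
        s.current_mcs = max(s.current_mcs - p.decay_rate, s.base_mcs)


def peer_share_decision(
    s: SensitivityState, p: InoculationParams, rng: np.random.Generator
) -> bool:
    """Decide whether a trained citizen shares training with peers this round.

    Probability = peer_share_prob × current_mcs / effect (capped at 1):
    the more cue-sensitive a citizen currently is, the keener they are to
    pass on the training.
    """
    if not s.ever_trained:
        return False
    if p.effect == 0:
        raise ValueError("peer_share_decision requires a non-zero inoculation effect")
    prob = min(p.peer_share_prob * s.current_mcs / p.effect, 1.0)
    return rng.random() < prob


def run_external_campaign(
    population: list,
    round_index: int,
    p: InoculationParams,
    rng: np.random.Generator,
) -> set[int]:
    """Deliver a scheduled external training session, if any, for this round.

    Exactly round(fraction × N) citizens are sampled uniformly without
    replacement (with replacement across rounds: already-trained citizens
    may be refreshed) and trained. Returns the ids trained this session.
    """
    fraction = 0.0
    for rnd, frac in p.schedule:
        if rnd == round_index:
            fraction += frac
    if fraction == 0.0:
        return set()
    if fraction > 1.0:
        raise ValueError(f"campaign fraction {fraction} exceeds 1 at round {round_index}")
    k = round(fraction * len(population))
    chosen = rng.choice(len(population), size=k, replace=False)
    trained: set[int] = set()
    for idx in chosen:
        citizen = population[int(idx)]
        apply_training(citizen.sensitivity, p)
        trained.add(citizen.id)
    return trained
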
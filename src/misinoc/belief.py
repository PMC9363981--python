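"""Citizen cognition: frequency-weighted beliefs, source credibility, Bayesian confidence.

A citizen's belief about a scalar state of the world (on [0, 1]) is not a
parametric distribution but a *frequency-weighted* empirical one: the last
five information items received are each replicated ``temporal_weight ×
credibility_weight`` times in an implicit multiset, and the citizen's belief
``mu_own`` and dispersion ``sigma_own`` are the mean and SD of that multiset.
Recency weighting is quadratic in position (newest of five counts 25x the
oldest); credibility weighting scales with how close the item fell to the
citizen's belief at the time it was evaluated.

Overlaid on the belief distribution is a *source-credibility* curve: a
Gaussian kernel centred on ``mu_own`` with scale ``sigma_own`` whose height,
relative to its peak, is the perceived credibility of an incoming value.
Confidence that one's belief is correct, P(H|E), updates by Bayes' rule where
the relative credibility acts as an amalgam of perceived trust and expertise
gating both direction and strength of the update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .sampling import truncated_normal

__all__ = [
    "HISTORY_LENGTH",
    "NO_INFO_VALUES",
    "NO_INFO_CREDIBILITY",
    "RawInfoItem",
    "BeliefState",
    "CredibilityParams",
    "SourceCredibilityTable",
    "temporal_weight",
    "credibility_weight",
    "item_frequency",
    "build_weighted_distribution",
    "relative_credibility",
    "passes_credibility",
    "update_confidence",
    "initialize_belief",
    "push_information",
    "push_no_information",
]

#: Rolling raw-information history length (positions 1..5, 1 = oldest).
HISTORY_LENGTH = 5

#: Pair of extreme placeholder values entered when a search finds nothing,
#: widening the belief distribution to reflect lost corroboration.
NO_INFO_VALUES = (0.01, 0.999)

#: Credibility assigned to a failed search, used both as the weighting
#: height of the placeholder pair and as the Bayes amalgam input.
NO_INFO_CREDIBILITY = 0.01

#: Floor on sigma when evaluating credibility, so a fully collapsed belief
#: distribution still accepts values at its peak (see CredibilityParams).
SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class RawInfoItem:
    """One entry of the rolling information history.

    ``value`` is the communicated belief value; ``cred_weight`` the
    credibility weight attached when it was received (5 at initialization,
    the output of :func:`credibility_weight` thereafter); ``position`` the
    temporal slot, 1 = oldest .. 5 = newest.
    """

    value: float
    cred_weight: float
    position: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"item value {self.value} outside [0, 1]")
        if self.cred_weight <= 0:
            raise ValueError("cred_weight must be positive")
        if not 1 <= self.position <= HISTORY_LENGTH:
            raise ValueError(f"position {self.position} outside 1..{HISTORY_LENGTH}")


@dataclass(frozen=True)
class CredibilityParams:
    """Fixed parameters of the source-credibility evaluation.

    cred_cutoff
        Minimum relative credibility for a message to pass (SC cut-off).
    cred_influence
        Universal credibility influence converting relative height into a
        frequency weight (CredInf).
    halo
        Multiplier on sigma in the credibility (not belief) overlay; 1 is
        the identity, >1 widens the band of acceptable values.
    broadcaster_bonus
        Content-independent credibility added when the source is a
        broadcaster (or a re-shared broadcast).
    sigma_floor
        Evaluation-only lower bound on sigma, keeping the Gaussian kernel
        defined when the history has collapsed to a single value.
    """

    cred_cutoff: float = 0.5
    cred_influence: float = 0.3
    halo: float = 1.0
    broadcaster_bonus: float = 0.3
    sigma_floor: float = SIGMA_FLOOR

    def __post_init__(self) -> None:
        if not 0.0 < self.cred_cutoff < 1.0:
            raise ValueError("cred_cutoff must lie in (0, 1)")
        if self.halo < 1.0:
            raise ValueError("halo must be >= 1")


@dataclass(frozen=True)
class SourceCredibilityTable:
    """Conditional probabilities P(E | hypothesis, trust, expertise).

    ``p_h`` holds P(E|H, ·) for the four (trust, expertise) combinations in
    the order (T,Exp), (T,¬Exp), (¬T,Exp), (¬T,¬Exp); the ¬H row is the
    complement. Trust flips the direction of the update, expertise scales
    its strength.
    """

    p_h: tuple[float, float, float, float] = (0.8, 0.65, 0.35, 0.2)

    def likelihoods(self, cred: float) -> tuple[float, float]:
        """Return (P(E|H), P(E|¬H)) with P(Trust) = P(Expertise) = cred."""
        c = min(max(cred, 0.0), 1.0)
        w = (c * c, c * (1 - c), (1 - c) * c, (1 - c) * (1 - c))
        p_e_h = sum(p * wi for p, wi in zip(self.p_h, w))
        p_e_not_h = sum((1 - p) * wi for p, wi in zip(self.p_h, w))
        return p_e_h, p_e_not_h


DEFAULT_TABLE = SourceCredibilityTable()


@dataclass
class BeliefState:
    """A citizen's belief distribution and confidence.

    ``mu_own``/``sigma_own`` are always the mean/SD of the frequency-expanded
    history; ``confidence`` is P(H|E), the prior for the next update.
    """

    history: list[RawInfoItem] = field(default_factory=list)
    mu_own: float = 0.5
    sigma_own: float = 0.0
    confidence: float = 0.05

    def rebuild(self) -> None:
        self.mu_own, self.sigma_own = build_weighted_distribution(self.history)


def temporal_weight(position: int) -> int:
    """Quadratic recency weight of a history slot: position ** 2."""
    if not 1 <= position <= HISTORY_LENGTH:
        raise ValueError(f"position {position} outside 1..{HISTORY_LENGTH}")
    return position * position


def credibility_weight(rel_height: float, cred_influence: float) -> float:
    """Convert a relative credibility height into a frequency weight.

    weight = rel_height × 100 × (cred_influence × 2); with the default
    influence 0.3, a height of 0.8 gives 48 and 0.2 gives 12.
    """
    if rel_height < 0:
        raise ValueError("rel_height must be non-negative")
    if cred_influence < 0:
        raise ValueError("cred_influence must be non-negative")
    return rel_height * 100.0 * (cred_influence * 2.0)


def item_frequency(item: RawInfoItem) -> int:
    """Integer replication count of an item in the expanded multiset."""
    return temporal_weight(item.position) * max(1, round(item.cred_weight))


def build_weighted_distribution(history: list[RawInfoItem]) -> tuple[float, float]:
    """Frequency-weighted mean and SD of the raw history.

    Each item is counted ``temporal_weight(position) × round(cred_weight)``
    times; the result equals the mean/SD of a multiset that literally
    replicates each value that many times (population SD).
    """
    if not history:
        raise ValueError("cannot build a belief distribution from an empty history")
    freqs = np.array([item_frequency(it) for it in history], dtype=float)
    values = np.array([it.value for it in history], dtype=float)
    total = freqs.sum()
    mu = float(freqs @ values / total)
    var = float(freqs @ (values - mu) ** 2 / total)
    return mu, math.sqrt(max(var, 0.0))


def relative_credibility(
    x: float,
    state: BeliefState,
    bonus: float = 0.0,
    params: CredibilityParams = CredibilityParams(),
) -> float:
    """Height of the credibility overlay at x, relative to its peak, plus bonus.

    The overlay is a normal density with mean ``mu_own`` and scale
    ``sigma_own × halo``; dividing by its peak leaves the Gaussian kernel
    exp(−(x−µ)²/(2σ²)). With a broadcaster bonus the result can exceed 1;
    no clamping is applied.
    """
    sigma = max(state.sigma_own, params.sigma_floor) * params.halo
    z = (x - state.mu_own) / sigma
    return math.exp(-0.5 * z * z) + bonus


def passes_credibility(
    x: float,
    state: BeliefState,
    bonus: float = 0.0,
    params: CredibilityParams = CredibilityParams(),
) -> bool:
    """True iff the relative credibility of x strictly exceeds the cut-off."""
    return relative_credibility(x, state, bonus, params) > params.cred_cutoff


def update_confidence(
    prior: float,
    cred: float,
    table: SourceCredibilityTable = DEFAULT_TABLE,
) -> float:
    """Bayesian confidence update gated by source credibility.

    ``cred`` (clamped to [0, 1]) stands in for both P(Trust) and
    P(Expertise); cred = 0.5 leaves the prior unchanged, cred > 0.5 raises
    confidence, cred < 0.5 lowers it.
    """
    p_e_h, p_e_not_h = table.likelihoods(cred)
    num = prior * p_e_h
    return num / (num + (1.0 - prior) * p_e_not_h)


def initialize_belief(
    rng: np.random.Generator,
    prior_mean: float = 0.5,
    prior_sd: float = 0.25,
    n: int = HISTORY_LENGTH,
    init_cred_weight: float = 5.0,
    confidence: float = 0.05,
) -> BeliefState:
    """Draw a citizen's initial belief state.

    ``n`` i.i.d. values from a normal(prior_mean, prior_sd) truncated to
    [0, 1] fill the history oldest-to-newest with a constant credibility
    weight; the weighted distribution is built and confidence set to its
    common initial value.
    """
    values = truncated_normal(rng, prior_mean, prior_sd, size=n)
    history = [
        RawInfoItem(value=float(v), cred_weight=init_cred_weight, position=i + 1)
        for i, v in enumerate(values)
    ]
    state = BeliefState(history=history, confidence=confidence)
    state.rebuild()
    return state


def _refresh_weights(state: BeliefState, params: CredibilityParams) -> None:
    """Recompute every history item's credibility weight before an update.

    Unlike at initialization, credibility weights are dynamic: at each
    belief update the relative height of every retained item under the
    *pre-update* credibility overlay is converted into a fresh weight. Items
    coherent with the current belief keep high weights, stale deviants lose
    theirs — the mechanism behind belief entrenchment — while a single
    deviant arrival is diluted by a coherent history rather than
    overwhelming it.
    """
    new_history = []
    for it in state.history:
        height = relative_credibility(it.value, state, 0.0, params)
        weight = max(credibility_weight(height, params.cred_influence), 1e-12)
        new_history.append(replace(it, cred_weight=weight))
    state.history = new_history


def _shift_and_append(history: list[RawInfoItem], new_items: list[RawInfoItem]) -> list[RawInfoItem]:
    """Evict the oldest len(new_items) items, re-index, append the new ones."""
    k = len(new_items)
    kept = history[k:]
    shifted = [replace(it, position=i + 1) for i, it in enumerate(kept)]
    return shifted + new_items


def push_information(
    state: BeliefState,
    value: float,
    cred_rel_height: float,
    params: CredibilityParams = CredibilityParams(),
) -> None:
    """Integrate an accepted information item into the rolling history.

    The oldest item is evicted, positions re-indexed, and the new item
    appended at position 5 with credibility weight
    ``credibility_weight(cred_rel_height, cred_influence)``; retained items
    have their weights refreshed against the pre-update overlay and the
    weighted distribution is rebuilt in place.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"information value {value} outside [0, 1]")
    _refresh_weights(state, params)
    weight = max(credibility_weight(cred_rel_height, params.cred_influence), 1e-12)
    new = RawInfoItem(value=value, cred_weight=weight, position=HISTORY_LENGTH)
    state.history = _shift_and_append(state.history, [new])
    state.rebuild()


def push_no_information(
    state: BeliefState,
    params: CredibilityParams = CredibilityParams(),
) -> None:
    """Record a failed search by widening the belief distribution.

    The extreme pair (0.01, 0.999) enters the history in the two newest
    slots (evicting the two oldest), each weighted at the failed-search
    credibility 0.01 — a minimal weight that nonetheless spreads the
    distribution and so lowers the credibility of everything off-centre.
    """
    _refresh_weights(state, params)
    weight = max(credibility_weight(NO_INFO_CREDIBILITY, params.cred_influence), 1e-12)
    pair = [
        RawInfoItem(value=NO_INFO_VALUES[0], cred_weight=weight, position=HISTORY_LENGTH - 1),
        RawInfoItem(value=NO_INFO_VALUES[1], cred_weight=weight, position=HISTORY_LENGTH),
    ]
    state.history = _shift_and_append(state.history, pair)
    state.rebuild()
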
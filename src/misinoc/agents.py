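"""Citizens, broadcasters and their interactions: posting, search, sharing, pruning.

Citizens live on a 100 x 100 plane (positions are recorded for fidelity to
the set-up but search is network-wide in these simulations) and hold a
belief state, a cue-sensitivity state and an undirected set of peer links.
Broadcasters are top-down sources reaching every citizen at once, honest
(value 0.5, the ground truth) or biased (0.75), carrying a fixed
content-independent credibility bonus.

Information moves through public *posts*: a value, its attached
misinformation cue, and — when a broadcast is re-shared — the broadcaster's
credibility bonus. Evaluation of any message is two-stage: a deterministic
source-credibility check against the citizen's belief distribution, then a
probabilistic misinformation-cue check against the citizen's current
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .belief import (
    BeliefState,
    CredibilityParams,
    passes_credibility,
    relative_credibility,
)
from .cues import CueParams, SensitivityState, detect_misinformation, generate_cue

__all__ = [
    "ACTIVITY_CUTOFF",
    "SHARE_DRAW_MAX",
    "Post",
    "Citizen",
    "Broadcaster",
    "EvalOutcome",
    "broadcast",
    "evaluate_message",
    "search",
    "share_decision",
    "prune",
]

#: Confidence at or above which a citizen is settled: no search, no pruning.
ACTIVITY_CUTOFF = 0.999

#: Upper bound of the uniform draw in the probabilistic sharing rule.
SHARE_DRAW_MAX = 0.4


@dataclass(frozen=True)
class Post:
    """A publicly declared information item.

    ``source_bonus`` is 0 for a citizen's own opinion and the broadcaster
    bonus when a broadcast is re-shared verbatim; ``seq`` is a global
    declaration counter that orders posts newest-first across rounds.
    """

    value: float
    cue: float
    source_bonus: float
    round_created: int
    author_id: int
    seq: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"post value {self.value} outside [0, 1]")
        if not 0.0 <= self.cue <= 1.0:
            raise ValueError(f"post cue {self.cue} outside [0, 1]")


@dataclass
class Citizen:
    """One network user: belief, cue sensitivity, peers, current declaration."""

    id: int
    position: tuple[float, float]
    belief: BeliefState
    sensitivity: SensitivityState
    peers: set[int] = field(default_factory=set)
    current_post: Post | None = None

    @property
    def active(self) -> bool:
        """Still engaged: not yet fully confident in the current belief."""
        return self.belief.confidence < ACTIVITY_CUTOFF


@dataclass(frozen=True)
class Broadcaster:
    """A top-down information source with a fixed communication strategy."""

    id: int
    strategy_value: float
    bonus: float = 0.3
    label: str = "broadcaster"

    def __post_init__(self) -> None:
        if not 0.0 <= self.strategy_value <= 1.0:
            raise ValueError("strategy_value must lie in [0, 1]")


class EvalOutcome(Enum):
    ACCEPTED = "accepted"
    REJECTED_CREDIBILITY = "rejected_credibility"
    REJECTED_MISINFORMATION = "rejected_misinformation"


def broadcast(
    b: Broadcaster,
    audience_mean: float,
    round_index: int,
    seq: int,
    cue_params: CueParams,
    rng: np.random.Generator,
) -> Post:
    """Compose one broadcast: strategy value plus a generated cue.

    The cue mean is the absolute gap between the communicated value and the
    broadcaster's perception of mean citizen belief (alpha = 1): persuading
    away from the perceived consensus correlates with heavier cue use.
    """
    cue = generate_cue(b.strategy_value, audience_mean, 1.0, cue_params.broadcast_cue_sd, rng)
    return Post(
        value=b.strategy_value,
        cue=cue,
        source_bonus=b.bonus,
        round_created=round_index,
        author_id=b.id,
        seq=seq,
    )


def evaluate_message(
    c: Citizen,
    value: float,
    cue: float,
    bonus: float,
    cred_params: CredibilityParams,
    cue_params: CueParams,
    rng: np.random.Generator,
) -> tuple[EvalOutcome, float]:
    """Two-stage evaluation of one message; returns (outcome, rel_credibility).

    Stage 1 dismisses sources below the credibility cut-off (deterministic
    given the citizen's belief distribution). Stage 2 runs the probabilistic
    cue-detection check. The relative credibility (bonus included) is
    returned for use in belief weighting, confidence updating and sharing.
    """
    rel = relative_credibility(value, c.belief, bonus, cred_params)
    if rel <= cred_params.cred_cutoff:
        return EvalOutcome.REJECTED_CREDIBILITY, rel
    if detect_misinformation(cue, c.sensitivity.current_mcs, cue_params.detect_sd, rng):
        return EvalOutcome.REJECTED_MISINFORMATION, rel
    return EvalOutcome.ACCEPTED, rel


def search(
    c: Citizen,
    declarers: list[Citizen],
    cred_params: CredibilityParams,
    cue_params: CueParams,
    rng: np.random.Generator,
    cue_rejections: list[float] | None = None,
) -> tuple[Post, float] | None:
    """Scan declared posts newest-first and accept the first that passes.

    ``declarers`` must be ordered most-recent declaration first and exclude
    the searcher. The credibility stage is evaluated for every candidate
    (vectorised) with no bonus — peer evaluation carries no independent
    credibility, even for re-shared broadcasts, whose bonus rides along in
    the post but only counts when the broadcaster itself is the source.
    The stochastic cue check runs only on candidates that pass, in recency
    order, stopping at the first acceptance. On acceptance an undirected
    link searcher <-> author is forged and ``(post, rel_credibility)``
    returned; ``None`` means the search failed. Values rejected at the cue
    stage along the way are appended to ``cue_rejections`` when a list is
    supplied.
    """
    if not declarers:
        return None
    values = np.array([d.current_post.value for d in declarers])
    sigma = max(c.belief.sigma_own, cred_params.sigma_floor) * cred_params.halo
    z = (values - c.belief.mu_own) / sigma
    rel = np.exp(-0.5 * z * z)
    for i in np.flatnonzero(rel > cred_params.cred_cutoff):
        d = declarers[int(i)]
        post = d.current_post
        if not detect_misinformation(
            post.cue, c.sensitivity.current_mcs, cue_params.detect_sd, rng
        ):
            c.peers.add(d.id)
            d.peers.add(c.id)
            return post, float(rel[int(i)])
        if cue_rejections is not None:
            cue_rejections.append(post.value)
    return None


def share_decision(
    c: Citizen,
    received: tuple[Post, float] | None,
    peer_declared_mean: float | None,
    round_index: int,
    seq: int,
    cred_params: CredibilityParams,
    cue_params: CueParams,
    rng: np.random.Generator,
) -> Post | None:
    """Decide what, if anything, the citizen posts after a belief update.

    First choice: re-share the received item verbatim (cue and any
    broadcaster bonus preserved) when its perceived credibility beats a
    Uniform(0, 0.4) draw. Otherwise: post one's own opinion (value mu_own,
    freshly generated cue against the mean declared value among direct
    peers, no bonus) when confidence beats an independent Uniform(0, 0.4)
    draw. Returning ``None`` leaves any existing post standing.
    """
    if received is not None:
        post, rel = received
        if rel > rng.uniform(0.0, SHARE_DRAW_MAX):
            return Post(
                value=post.value,
                cue=post.cue,
                source_bonus=post.source_bonus,
                round_created=round_index,
                author_id=c.id,
                seq=seq,
            )
    if c.belief.confidence > rng.uniform(0.0, SHARE_DRAW_MAX):
        audience = c.belief.mu_own if peer_declared_mean is None else peer_declared_mean
        cue = generate_cue(
            c.belief.mu_own, audience, cue_params.alpha_citizen,
            cue_params.broadcast_cue_sd, rng,
        )
        return Post(
            value=c.belief.mu_own,
            cue=cue,
            source_bonus=0.0,
            round_created=round_index,
            author_id=c.id,
            seq=seq,
        )
    return None


def prune(
    c: Citizen,
    population: dict[int, Citizen],
    cred_params: CredibilityParams,
) -> set[tuple[int, int]]:
    """Sever links to declaring peers whose posts fail the credibility check.

    Only peers with a current post are assessed (no bonus applies); each
    severed undirected edge is removed from both endpoints and returned as
    a sorted id pair. Settled citizens (confidence >= 0.999) do not prune.
    """
    if not c.active:
        return set()
    severed: set[tuple[int, int]] = set()
    for pid in list(c.peers):
        peer = population[pid]
        if peer.current_post is None:
            continue
        if not passes_credibility(peer.current_post.value, c.belief, 0.0, cred_params):
            c.peers.discard(pid)
            peer.peers.discard(c.id)
            severed.add((min(c.id, pid), max(c.id, pid)))
    return severed
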
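"""Simulation engine: round orchestration, seeding, the manipulation grid.

Each of the 25 rounds runs four phases in fixed order: (1) inoculation
(peer sharing of training, then decay, then any scheduled external
campaign); (2) broadcasting — every citizen evaluates the broadcast,
accepters update beliefs and may share; (3) search — citizens who did not
accept a broadcast may scan publicly declared peer posts, newest first;
(4) pruning of non-credible declaring peers. The run ends at the configured
round count or as soon as every citizen is settled (confidence >= 0.999).

Replicate seeds are spawned from the master seed with a counter-based
scheme, so no replicate shares a random stream and any single run can be
reproduced in isolation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import (
    Broadcaster,
    Citizen,
    EvalOutcome,
    broadcast,
    evaluate_message,
    prune,
    search,
    share_decision,
)
from .belief import NO_INFO_CREDIBILITY, initialize_belief, push_information, push_no_information, update_confidence
from .config import BROADCASTER_CONDITIONS, ScenarioConfig, active_broadcaster_values
from .cues import RejectionKind, SensitivityState, classify_rejection, sample_base_mcs
from .inoculation import TRAINING_REGIMES, apply_training, decay_step, peer_share_decision, run_external_campaign
from .metrics import RoundMetrics, collect_round_metrics, metrics_frame

__all__ = ["RunResult", "Simulation", "run_simulation", "run_grid", "replicate_seed"]

logger = logging.getLogger(__name__)

#: Broadcaster ids sit above any citizen id.
_BROADCASTER_ID_BASE = 10**9


@dataclass
class RunResult:
    """Outcome of one simulation: per-round metrics and the final state."""

    config: ScenarioConfig
    seed: int
    metrics: list[RoundMetrics]
    citizens: list[Citizen]
    final_round: int
    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        return metrics_frame(self.metrics)


class Simulation:
    """Mutable simulation state for one (config, seed) pair."""

    def __init__(
        self,
        config: ScenarioConfig,
        seed: int | None = None,
        snapshot_rounds: tuple[int, ...] = (),
    ):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.snapshot_rounds = frozenset(snapshot_rounds)
        self.snapshots: dict[int, pd.DataFrame] = {}
        self.rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        self._seq = itertools.count()
        self.round_index = 0
        self.metrics: list[RoundMetrics] = []
        self._declaration_log: list[tuple[int, Citizen]] = []

        rng = self.rng
        self.citizens = [
            Citizen(
                id=i,
                position=(
                    float(rng.uniform(0, config.grid_size)),
                    float(rng.uniform(0, config.grid_size)),
                ),
                belief=initialize_belief(rng),
                sensitivity=SensitivityState.at_baseline(
                    sample_base_mcs(config.base_mcs_level, rng)
                ),
            )
            for i in range(config.n_citizens)
        ]
        self.population = {c.id: c for c in self.citizens}
        self.broadcasters = {
            label: Broadcaster(
                id=_BROADCASTER_ID_BASE + k,
                strategy_value=value,
                bonus=config.credibility.broadcaster_bonus,
                label=label,
            )
            for k, (label, value) in enumerate(
                sorted({
                    lv
                    for r in range(1, max(config.rounds, 1) + 1)
                    for lv in active_broadcaster_values(config.broadcaster_condition, r)
                })
            )
        }

    # -- helpers ----------------------------------------------------------

    def _permuted(self) -> list[Citizen]:
        order = self.rng.permutation(len(self.citizens))
        return [self.citizens[int(i)] for i in order]

    def _publish(self, citizen: Citizen, post) -> None:
        citizen.current_post = post
        self._declaration_log.append((post.seq, citizen))

    def _declarers_newest_first(self, exclude_id: int) -> list[Citizen]:
        """Citizens with a live post, ordered by declaration recency.

        The log may hold superseded entries; an entry is current only when
        its seq matches the citizen's live post.
        """
        out = []
        for seq, citizen in reversed(self._declaration_log):
            post = citizen.current_post
            if post is not None and post.seq == seq and citizen.id != exclude_id:
                out.append(citizen)
        return out

    def _integrate(self, citizen: Citizen, value: float, rel: float) -> None:
        """Accepted information: weight into the history, update confidence."""
        push_information(citizen.belief, value, rel, self.config.credibility)
        citizen.belief.confidence = update_confidence(citizen.belief.confidence, rel)

    def _record_rejection(self, value: float, counts: dict) -> None:
        kind = classify_rejection(value, self.config.cues)
        counts[kind] += 1

    def _maybe_share(self, citizen: Citizen, received) -> None:
        peer_vals = [
            self.population[p].current_post.value
            for p in citizen.peers
            if self.population[p].current_post is not None
        ]
        peer_mean = float(np.mean(peer_vals)) if peer_vals else None
        post = share_decision(
            citizen,
            received,
            peer_mean,
            self.round_index,
            next(self._seq),
            self.config.credibility,
            self.config.cues,
            self.rng,
        )
        if post is not None:
            self._publish(citizen, post)

    # -- phases -----------------------------------------------------------

    def _phase_inoculation(self) -> None:
        logger.debug("round %d phase 1: inoculation", self.round_index)
        params = self.config.inoculation
        trained_this_round: set[int] = set()
        if params.peer_sharing:
            # only citizens trained in previous rounds may share
            eligible = [c for c in self._permuted() if c.sensitivity.ever_trained]
            for c in eligible:
                if peer_share_decision(c.sensitivity, params, self.rng):
                    for pid in sorted(c.peers):
                        apply_training(self.population[pid].sensitivity, params)
                        trained_this_round.add(pid)
        for c in self.citizens:
            if c.sensitivity.ever_trained and c.id not in trained_this_round:
                decay_step(c.sensitivity, params)
        trained_this_round |= run_external_campaign(
            self.citizens, self.round_index, params, self.rng
        )

    def _phase_broadcast(self, rejections: dict) -> tuple[set[int], int]:
        """Returns (ids that accepted a broadcast, accepted count)."""
        logger.debug("round %d phase 2: broadcast", self.round_index)
        active = active_broadcaster_values(
            self.config.broadcaster_condition, self.round_index
        )
        accepted_ids: set[int] = set()
        n_accepted = 0
        for label, _value in active:
            b = self.broadcasters[label]
            audience_mean = float(np.mean([c.belief.mu_own for c in self.citizens]))
            post = broadcast(
                b, audience_mean, self.round_index, next(self._seq),
                self.config.cues, self.rng,
            )
            for c in self._permuted():
                outcome, rel = evaluate_message(
                    c, post.value, post.cue, b.bonus,
                    self.config.credibility, self.config.cues, self.rng,
                )
                if outcome is EvalOutcome.ACCEPTED:
                    self._integrate(c, post.value, rel)
                    accepted_ids.add(c.id)
                    n_accepted += 1
                    self._maybe_share(c, (post, rel))
                elif outcome is EvalOutcome.REJECTED_MISINFORMATION:
                    self._record_rejection(post.value, rejections)
        return accepted_ids, n_accepted

    def _phase_search(self, broadcast_accepters: set[int], rejections: dict) -> int:
        logger.debug("round %d phase 3: search", self.round_index)
        n_accepted = 0
        for c in self._permuted():
            if c.id in broadcast_accepters or not c.active:
                continue
            if self.rng.random() >= 1.0 - c.belief.confidence:
                continue  # confident citizens rarely bother searching
            cue_rejected: list[float] = []
            found = search(
                c,
                self._declarers_newest_first(c.id),
                self.config.credibility,
                self.config.cues,
                self.rng,
                cue_rejections=cue_rejected,
            )
            for value in cue_rejected:
                self._record_rejection(value, rejections)
            if found is not None:
                post, rel = found
                self._integrate(c, post.value, rel)
                n_accepted += 1
                self._maybe_share(c, (post, rel))
            else:
                push_no_information(c.belief, self.config.credibility)
                c.belief.confidence = update_confidence(
                    c.belief.confidence, NO_INFO_CREDIBILITY
                )
                self._maybe_share(c, None)
        return n_accepted

    def _phase_prune(self) -> None:
        logger.debug("round %d phase 4: prune", self.round_index)
        for c in self._permuted():
            prune(c, self.population, self.config.credibility)

    # -- driver -----------------------------------------------------------

    def run_round(self) -> RoundMetrics:
        """Advance the simulation by one round and record its metrics."""
        self.round_index += 1
        rejections = {RejectionKind.CORRECT_REJECTION: 0, RejectionKind.FALSE_POSITIVE: 0}
        self._phase_inoculation()
        accepters, n_broadcast = self._phase_broadcast(rejections)
        n_search = self._phase_search(accepters, rejections)
        self._phase_prune()
        record = collect_round_metrics(
            self.round_index,
            self.citizens,
            self.population,
            n_communications=n_broadcast + n_search,
            n_correct_rejections=rejections[RejectionKind.CORRECT_REJECTION],
            n_false_positives=rejections[RejectionKind.FALSE_POSITIVE],
        )
        self.metrics.append(record)
        if self.round_index in self.snapshot_rounds:
            from .metrics import snapshot_frame

            self.snapshots[self.round_index] = snapshot_frame(self.citizens)
        return record

    def all_settled(self) -> bool:
        return all(not c.active for c in self.citizens)

    def run(self) -> RunResult:
        while self.round_index < self.config.rounds:
            self.run_round()
            if self.all_settled():
                break
        return RunResult(
            config=self.config,
            seed=self.seed,
            metrics=self.metrics,
            citizens=self.citizens,
            final_round=self.round_index,
            snapshots=self.snapshots,
        )


def run_simulation(
    config: ScenarioConfig,
    seed: int | None = None,
    snapshot_rounds: tuple[int, ...] = (),
) -> RunResult:
    """Run one scenario to completion; fully reproducible from (config, seed)."""
    return Simulation(config, seed=seed, snapshot_rounds=snapshot_rounds).run()


def replicate_seed(master_seed: int, index: int) -> int:
    """Counter-based per-replicate seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_grid(
    base: ScenarioConfig,
    training_regimes: tuple[str, ...] = tuple(sorted(TRAINING_REGIMES)),
    broadcaster_conditions: tuple[str, ...] = BROADCASTER_CONDITIONS,
    base_mcs_levels: tuple[str, ...] = ("low", "medium", "high"),
    replicates: int | None = None,
    master_seed: int | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a manipulation grid with replicates.

    Every (training regime x broadcaster condition x sensitivity level)
    permutation is run ``replicates`` times with counter-derived seeds.
    Returns ``(per_round, aggregate)``: one tidy row per (condition,
    replicate, round), and the replicate mean per (condition, round).
    """
    replicates = base.replicates if replicates is None else replicates
    master_seed = base.seed if master_seed is None else master_seed
    conditions = list(itertools.product(
        training_regimes, broadcaster_conditions, base_mcs_levels
    ))
    rows = []
    run_counter = 0
    for regime, bc, level in conditions:
        config = base.with_overrides(
            training_regime=regime, broadcaster_condition=bc, base_mcs_level=level
        )
        for rep in range(replicates):
            seed = replicate_seed(master_seed, run_counter)
            run_counter += 1
            if progress:
                logger.info("grid run %d: %s/%s/%s rep %d seed %d",
                            run_counter, regime, bc, level, rep, seed)
            result = run_simulation(config, seed=seed)
            frame = result.metrics_frame()
            frame.insert(0, "training_regime", regime)
            frame.insert(1, "broadcaster_condition", bc)
            frame.insert(2, "base_mcs_level", level)
            frame.insert(3, "replicate", rep)
            frame.insert(4, "seed", seed)
            rows.append(frame)
    per_round = pd.concat(rows, ignore_index=True)
    keys = ["training_regime", "broadcaster_condition", "base_mcs_level", "round"]
    aggregate = (
        per_round.drop(columns=["replicate", "seed"])
        .groupby(keys, sort=True)
        .mean()
        .reset_index()
    )
    return per_round, aggregate
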
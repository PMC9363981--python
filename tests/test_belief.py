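"""Belief-distribution, credibility and confidence-update unit tests.

The frequency-weighted mean/SD are checked against a brute-force oracle
that literally replicates each history value ``frequency`` times.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misinoc import (
    BeliefState,
    CredibilityParams,
    RawInfoItem,
    build_weighted_distribution,
    credibility_weight,
    initialize_belief,
    item_frequency,
    passes_credibility,
    push_information,
    push_no_information,
    relative_credibility,
    temporal_weight,
    update_confidence,
)
from misinoc.belief import HISTORY_LENGTH


def expand_brute_force(history):
    """Independent oracle: the literal frequency-expanded multiset."""
    values = np.concatenate(
        [np.full(item_frequency(it), it.value) for it in history]
    )
    return values.mean(), values.std()


def make_history(values, weights):
    return [
        RawInfoItem(value=v, cred_weight=w, position=i + 1)
        for i, (v, w) in enumerate(zip(values, weights))
    ]


class TestTemporalWeight:
    @pytest.mark.parametrize("position,expected", [(1, 1), (2, 4), (3, 9), (4, 16), (5, 25)])
    def test_square_law(self, position, expected):
        assert temporal_weight(position) == expected

    @pytest.mark.parametrize("position", [0, 6, -1])
    def test_out_of_range(self, position):
        with pytest.raises(ValueError):
            temporal_weight(position)


class TestCredibilityWeight:
    @pytest.mark.parametrize(
        "height,influence,expected", [(0.8, 0.3, 48.0), (0.2, 0.3, 12.0), (0.5, 0.3, 30.0)]
    )
    def test_worked_values(self, height, influence, expected):
        assert credibility_weight(height, influence) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            credibility_weight(-0.1, 0.3)


class TestWeightedDistribution:
    def test_initialization_frequencies(self):
        """Constant weight 5 yields the 5..125 expansion, oldest to newest."""
        history = make_history([0.1, 0.3, 0.5, 0.7, 0.9], [5] * 5)
        assert [item_frequency(it) for it in history] == [5, 20, 45, 80, 125]

    def test_constant_values_collapse(self):
        history = make_history([0.3] * 5, [5] * 5)
        mu, sigma = build_weighted_distribution(history)
        assert mu == pytest.approx(0.3)
        assert sigma == pytest.approx(0.0)

    def test_worked_mean(self):
        """Four items at 0.4 and the newest at 0.6 give mean 135/275."""
        history = make_history([0.4, 0.4, 0.4, 0.4, 0.6], [5] * 5)
        mu, _ = build_weighted_distribution(history)
        assert mu == pytest.approx(135 / 275)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            build_weighted_distribution([])

    @settings(derandomize=True, max_examples=100)
    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5),
        weights=st.lists(st.floats(0.5, 80.0), min_size=5, max_size=5),
    )
    def test_matches_brute_force_expansion(self, values, weights):
        history = make_history(values, weights[: len(values)])
        mu, sigma = build_weighted_distribution(history)
        mu_ref, sigma_ref = expand_brute_force(history)
        assert mu == pytest.approx(mu_ref, abs=1e-9)
        assert sigma == pytest.approx(sigma_ref, abs=1e-9)


class TestRelativeCredibility:
    def setup_method(self):
        self.state = BeliefState(mu_own=0.5, sigma_own=0.1)

    def test_peak_identity(self):
        assert relative_credibility(0.5, self.state) == pytest.approx(1.0)

    def test_one_sigma(self):
        assert relative_credibility(0.6, self.state) == pytest.approx(math.exp(-0.5))

    def test_two_sigma_with_bonus(self):
        got = relative_credibility(0.7, self.state, bonus=0.3)
        assert got == pytest.approx(math.exp(-2) + 0.3)

    def test_symmetric_and_decreasing(self):
        left = relative_credibility(0.42, self.state)
        right = relative_credibility(0.58, self.state)
        assert left == pytest.approx(right)
        xs = [0.5, 0.55, 0.6, 0.7, 0.9]
        rels = [relative_credibility(x, self.state) for x in xs]
        assert all(a > b for a, b in zip(rels, rels[1:]))

    def test_zero_sigma_floor(self):
        """A collapsed distribution still accepts its own peak."""
        state = BeliefState(mu_own=0.5, sigma_own=0.0)
        assert relative_credibility(0.5, state) == pytest.approx(1.0)
        assert passes_credibility(0.5, state)
        assert not passes_credibility(0.6, state)

    def test_cutoff(self):
        assert passes_credibility(0.6, self.state)  # exp(-0.5) > 0.5
        assert not passes_credibility(0.7, self.state)  # exp(-2) < 0.5


class TestUpdateConfidence:
    def test_neutral_credibility_is_identity(self):
        for p in np.linspace(0.01, 0.99, 23):
            assert update_confidence(p, 0.5) == pytest.approx(p, abs=1e-12)

    def test_hand_expanded_oracle(self):
        # P(E|H) at cred c: 0.8 c^2 + (0.65 + 0.35) c (1-c) + 0.2 (1-c)^2
        for cred in (0.0, 0.8, 1.0):
            c = cred
            p_e_h = 0.8 * c * c + 0.65 * c * (1 - c) + 0.35 * (1 - c) * c + 0.2 * (1 - c) ** 2
            p_e_nh = 0.2 * c * c + 0.35 * c * (1 - c) + 0.65 * (1 - c) * c + 0.8 * (1 - c) ** 2
            expected = 0.05 * p_e_h / (0.05 * p_e_h + 0.95 * p_e_nh)
            assert update_confidence(0.05, cred) == pytest.approx(expected, abs=1e-12)
        assert update_confidence(0.05, 0.8) == pytest.approx(0.1006, abs=1e-4)
        assert update_confidence(0.05, 1.0) == pytest.approx(0.1739, abs=1e-4)

    def test_strictly_increasing_in_credibility(self):
        posts = [update_confidence(0.3, c) for c in np.linspace(0.0, 1.0, 21)]
        assert all(a < b for a, b in zip(posts, posts[1:]))

    def test_direction_around_neutral(self):
        assert update_confidence(0.4, 0.7) > 0.4
        assert update_confidence(0.4, 0.3) < 0.4

    def test_repeated_updates_converge(self):
        p = 0.05
        for _ in range(200):
            p = update_confidence(p, 0.8)
        assert p > 0.999
        q = 0.95
        for _ in range(200):
            q = update_confidence(q, 0.2)
        assert q < 0.001

    def test_bonus_inflated_credibility_clamped(self):
        assert update_confidence(0.3, 1.3) == update_confidence(0.3, 1.0)


class TestInitializeBelief:
    def test_contract(self, rng):
        state = initialize_belief(rng)
        assert state.confidence == 0.05
        assert len(state.history) == HISTORY_LENGTH
        assert [it.position for it in state.history] == [1, 2, 3, 4, 5]
        assert all(0.0 <= it.value <= 1.0 for it in state.history)
        assert all(it.cred_weight == 5.0 for it in state.history)
        mu_ref, sigma_ref = expand_brute_force(state.history)
        assert state.mu_own == pytest.approx(mu_ref)
        assert state.sigma_own == pytest.approx(sigma_ref)

    def test_degenerate_prior(self, rng):
        state = initialize_belief(rng, prior_sd=0.0)
        assert state.mu_own == pytest.approx(0.5)
        assert state.sigma_own == pytest.approx(0.0)


class TestPushInformation:
    def test_new_item_weight_and_positions(self, rng):
        state = initialize_belief(rng)
        push_information(state, 0.6, 0.8)
        assert len(state.history) == HISTORY_LENGTH
        newest = state.history[-1]
        assert newest.value == 0.6
        assert newest.cred_weight == pytest.approx(48.0)
        assert [it.position for it in state.history] == [1, 2, 3, 4, 5]

    def test_retained_weights_refreshed(self, rng):
        """Old items are re-weighted against the pre-update overlay."""
        state = initialize_belief(rng)
        mu0, sig0 = state.mu_own, state.sigma_own
        push_information(state, mu0, 1.0)
        for it in state.history[:-1]:
            z = (it.value - mu0) / sig0
            expected = math.exp(-0.5 * z * z) * 60.0
            assert it.cred_weight == pytest.approx(expected)

    def test_repeated_coherent_pushes_concentrate(self, rng):
        state = initialize_belief(rng)
        target = state.mu_own
        sigmas = [state.sigma_own]
        for _ in range(8):
            push_information(state, target, 1.0)
            sigmas.append(state.sigma_own)
        assert all(a >= b for a, b in zip(sigmas, sigmas[1:]))
        assert state.sigma_own < 1e-6
        assert state.mu_own == pytest.approx(target, abs=1e-9)

    def test_oracle_equivalence_after_push(self, rng):
        state = initialize_belief(rng)
        push_information(state, 0.7, 0.4)
        mu_ref, sigma_ref = expand_brute_force(state.history)
        assert state.mu_own == pytest.approx(mu_ref, abs=1e-9)
        assert state.sigma_own == pytest.approx(sigma_ref, abs=1e-9)

    def test_out_of_range_value_rejected(self, rng):
        state = initialize_belief(rng)
        with pytest.raises(ValueError):
            push_information(state, 1.2, 0.5)


class TestPushNoInformation:
    def test_widens_concentrated_state(self):
        history = make_history([0.5] * 5, [60.0] * 5)
        state = BeliefState(history=history)
        state.rebuild()
        assert state.sigma_own == pytest.approx(0.0)
        push_no_information(state)
        assert state.sigma_own > 0.05
        values = sorted(it.value for it in state.history[-2:])
        assert values == [0.01, 0.999]
        mu_ref, sigma_ref = expand_brute_force(state.history)
        assert state.sigma_own == pytest.approx(sigma_ref, abs=1e-9)
        assert state.mu_own == pytest.approx(mu_ref, abs=1e-9)

    def test_history_length_preserved(self, rng):
        state = initialize_belief(rng)
        push_no_information(state)
        assert len(state.history) == HISTORY_LENGTH
        assert [it.position for it in state.history] == [1, 2, 3, 4, 5]


class TestParamValidation:
    def test_cutoff_range(self):
        with pytest.raises(ValueError):
            CredibilityParams(cred_cutoff=1.5)

    def test_halo_floor(self):
        with pytest.raises(ValueError):
            CredibilityParams(halo=0.5)

    def test_item_invariants(self):
        with pytest.raises(ValueError):
            RawInfoItem(value=1.5, cred_weight=5, position=1)
        with pytest.raises(ValueError):
            RawInfoItem(value=0.5, cred_weight=-1, position=1)
        with pytest.raises(ValueError):
            RawInfoItem(value=0.5, cred_weight=5, position=7)
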
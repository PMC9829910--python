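import numpy as np
import pytest
from hypothesis import given, strategies as st

from rivalscreen.core import Eye, ProtocolStateError
from rivalscreen.observers import ObserverProfile
from rivalscreen.staircase import (
    BALANCED,
    IMBALANCED,
    StaircaseConfig,
    StaircaseState,
    classify_brightness,
    finalize_game,
    run_brightness_game,
    run_brightness_session,
    staircase_step,
)

from conftest import grid_deltas, observer_with_attenuation


class TestStaircaseStep:
    def test_choice_moves_disparity_against_chosen_eye(self, config):
        state = StaircaseState.new(config, start_disparity=0.3)
        staircase_step(state, Eye.OD)
        assert state.current_disparity == 0.0
        assert state.trace == [(0.3, Eye.OD)]
        staircase_step(state, Eye.OS)  # opposite choice: a crossing
        assert state.current_disparity == 0.3
        assert len(state.crossing_pairs) == 1

    def test_crossing_recorded_between_opposite_responses(self, config):
        state = StaircaseState.new(config, start_disparity=0.3)
        staircase_step(state, Eye.OD)
        staircase_step(state, Eye.OD)
        assert not state.crossing_pairs
        staircase_step(state, Eye.OS)
        assert state.crossings == [-0.15]  # midpoint between 0.0 and -0.3

    def test_finishes_after_required_crossings(self, config):
        state = StaircaseState.new(config, start_disparity=0.3)
        for eye in (Eye.OD, Eye.OS, Eye.OD):
            staircase_step(state, eye)
        assert state.finished
        assert len(state.crossing_pairs) == config.required_crossings

    def test_stepping_finished_state_raises(self, config):
        state = StaircaseState.new(config, start_disparity=0.3)
        for eye in (Eye.OD, Eye.OS, Eye.OD):
            staircase_step(state, eye)
        with pytest.raises(ProtocolStateError):
            staircase_step(state, Eye.OD)

    def test_disparity_clamped_to_grid_edges(self, config):
        state = StaircaseState.new(config, start_disparity=1.8)
        staircase_step(state, Eye.OS)
        assert state.current_disparity == 1.8


class TestConfigValidation:
    def test_defaults_valid(self):
        cfg = StaircaseConfig()
        assert cfg.trial_budget == 52

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(step=0.0),
            dict(max_disparity=1.7),          # not a step multiple
            dict(start_disparity=2.1),        # beyond max
            dict(start_disparity=0.2),        # off grid
            dict(required_crossings=1),
            dict(balance_rule="majority"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StaircaseConfig(**kwargs)


class TestParameterRecovery:
    @pytest.mark.parametrize("delta", grid_deltas())
    def test_noiseless_endpoint_equals_attenuation_from_any_start(self, delta, config):
        observer = observer_with_attenuation(delta)
        for start in grid_deltas():
            result = run_brightness_game(observer, config, seed=11, start_disparity=start)
            assert result.endpoint == delta, (delta, start)

    def test_repeated_games_reproduce_endpoint(self, config):
        observer = observer_with_attenuation(0.3)
        results = run_brightness_session(observer, config, seed=5)
        assert [r.endpoint for r in results] == [0.3, 0.3, 0.3]

    def test_two_step_attenuation(self, config):
        observer = observer_with_attenuation(0.6)
        assert run_brightness_game(observer, config, seed=1).endpoint == 0.6

    def test_antisymmetry_under_eye_swap(self, config):
        for delta in (0.3, 0.9, 1.5):
            observer = observer_with_attenuation(delta)
            mirrored = observer.mirrored()
            a = run_brightness_game(observer, config, seed=2).endpoint
            b = run_brightness_game(mirrored, config, seed=2).endpoint
            assert a == -b == delta

    def test_never_reversing_observer_hits_ceiling(self, config):
        observer = observer_with_attenuation(1.8)
        result = run_brightness_game(observer, config, seed=0)
        assert result.ceiling
        assert result.endpoint == 1.8
        assert result.trials <= config.trial_budget


class TestTerminationAndGrid:
    @given(st.lists(st.sampled_from([Eye.OD, Eye.OS]), min_size=0, max_size=200))
    def test_terminates_within_budget_for_arbitrary_responses(self, responses):
        config = StaircaseConfig()
        state = StaircaseState.new(config)
        for eye in responses:
            if state.finished:
                break
            staircase_step(state, eye)
        assert len(state.responses) <= config.trial_budget
        if len(responses) >= config.trial_budget:
            assert state.finished

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_noisy_observer_game_ends_with_on_grid_stimuli(self, seed):
        config = StaircaseConfig()
        observer = ObserverProfile(decision_noise=0.4)
        result = run_brightness_game(observer, config, seed=seed)
        assert result.trials <= config.trial_budget
        levels = [d / config.step for d, _ in result.trace]
        assert all(abs(l - round(l)) < 1e-9 for l in levels)
        assert all(abs(d) <= config.max_disparity + 1e-9 for d, _ in result.trace)

    def test_mean_absolute_endpoint_monotone_in_attenuation(self, config):
        """With fixed decision noise, larger true disparities give larger
        measured disparities on average."""
        seeds = np.random.SeedSequence(17).spawn(200)
        means = []
        for delta in (0.0, 0.3, 0.6, 0.9, 1.2):
            observer = observer_with_attenuation(delta, noise=0.15)
            vals = [
                abs(run_brightness_game(observer, config, seed=s).endpoint)
                for s in seeds
            ]
            means.append(np.mean(vals))
        assert all(a <= b for a, b in zip(means, means[1:]))


class TestClassification:
    def test_all_zero_endpoints_balanced(self, config):
        cls = classify_brightness([0.0, 0.0, 0.0], config)
        assert cls.label == BALANCED
        assert cls.net_imbalance == 0.0

    def test_consistent_one_eye_deficit_imbalanced(self, config):
        cls = classify_brightness([0.3, 0.3, 0.3], config)
        assert cls.label == IMBALANCED
        assert cls.net_imbalance == 0.3

    def test_alternating_preference_counts_as_balanced(self, config):
        """Endpoints 0.3 OS, 0.3 OD, 0.0 — the treated amblyope's pattern —
        show no consistent one-eye deficit."""
        cls = classify_brightness([0.3, -0.3, 0.0], config)
        assert cls.label == BALANCED

    def test_two_same_signed_games_suffice_for_imbalance(self, config):
        cls = classify_brightness([0.0, 0.6, 0.3], config)
        assert cls.label == IMBALANCED
        assert cls.net_imbalance == 0.6

    def test_net_sum_rule_variant(self):
        config = StaircaseConfig(balance_rule="net-sum")
        assert classify_brightness([0.3, -0.3, 0.0], config).label == BALANCED
        assert classify_brightness([0.3, 0.0, 0.0], config).label == IMBALANCED

    def test_wrong_game_count_rejected(self, config):
        with pytest.raises(ValueError):
            classify_brightness([0.0, 0.0], config)


def test_finalize_requires_finished_state(config):
    state = StaircaseState.new(config)
    with pytest.raises(ProtocolStateError):
        finalize_game(state)


def test_session_alternates_start_side(config):
    observer = observer_with_attenuation(0.0)
    observer.decision_noise = 0.0
    results = run_brightness_session(observer, config, seed=3)
    starts = [r.trace[0][0] for r in results]
    assert starts == [1.8, -1.8, 1.8]
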
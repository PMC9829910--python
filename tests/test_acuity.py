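import numpy as np
import pytest

from rivalscreen.core import (
    ChartLadder,
    DEFAULT_LADDER,
    Eye,
    ProtocolStateError,
    VisualAcuity,
    snellen_to_logmar,
)
from rivalscreen.observers import ObserverProfile, make_archetype
from rivalscreen.acuity import (
    AcuityRunState,
    acuity_step,
    run_acuity_test,
    run_eye_protocol,
)


def _per_eye(od, os_):
    return {Eye.OD: od, Eye.OS: os_}


def observer_with_threshold(logmar, refractive=0.0, noise=0.0):
    return ObserverProfile(
        neural_logmar=_per_eye(logmar, logmar),
        refractive_logmar=_per_eye(refractive, refractive),
        decision_noise=noise,
    )


def smallest_passing_size(ladder, threshold):
    """Closed-form expectation: the smallest chart line whose logMAR is at
    or above the observer's effective threshold (None = below floor)."""
    passing = [s for s in ladder if snellen_to_logmar(s) >= threshold - 5e-3]
    return min(passing) if passing else None


class TestAcuityStep:
    def test_three_correct_advance_and_reset(self):
        state = AcuityRunState.new(60)
        for _ in range(3):
            acuity_step(state, pair_is_match=True, response_yes=True)
        assert state.current_size == 50
        assert state.correct_at_size == 0
        assert not state.second_chance_active
        assert state.completed_sizes == [60]

    def test_first_error_opens_second_chance_of_three_pairs(self):
        state = AcuityRunState.new(40)
        acuity_step(state, pair_is_match=True, response_yes=False)
        assert state.second_chance_active
        assert state.second_chance_remaining == 3
        assert not state.ended

    def test_error_during_second_chance_ends_run(self):
        state = AcuityRunState.new(40)
        acuity_step(state, pair_is_match=True, response_yes=False)
        acuity_step(state, pair_is_match=False, response_yes=True)
        assert state.ended
        assert state.outcome is None  # resolution happens at session level

    def test_earlier_corrects_count_inside_second_chance(self):
        state = AcuityRunState.new(40)
        acuity_step(state, True, True)
        acuity_step(state, True, True)
        acuity_step(state, True, False)  # error after two corrects
        acuity_step(state, False, False)  # third correct -> advance
        assert state.current_size == 30
        assert not state.second_chance_active

    def test_completing_smallest_line_sets_outcome(self):
        state = AcuityRunState.new(20)
        for _ in range(3):
            acuity_step(state, True, True)
        assert state.ended
        assert state.outcome == VisualAcuity(20)

    def test_stepping_ended_run_raises(self):
        state = AcuityRunState.new(40)
        acuity_step(state, True, False)
        acuity_step(state, True, False)
        with pytest.raises(ProtocolStateError):
            acuity_step(state, True, True)

    def test_start_size_must_be_on_ladder(self):
        with pytest.raises(ValueError):
            AcuityRunState.new(45)


class TestRunAcuityTest:
    def test_perfect_observer_reads_bottom_line(self):
        observer = observer_with_threshold(0.0)
        assert run_acuity_test(observer, Eye.OD, seed=1) == VisualAcuity(20)

    @pytest.mark.parametrize("threshold", [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3])
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_noiseless_recovery_matches_closed_form(self, threshold, seed):
        observer = observer_with_threshold(threshold)
        expected = smallest_passing_size(DEFAULT_LADDER, threshold)
        result = run_acuity_test(observer, Eye.OD, seed=seed)
        assert result == VisualAcuity(expected)

    def test_threshold_above_start_line_triggers_restart_from_top(self):
        """An observer who cannot resolve the 20/60 start line restarts at
        20/400 and still gets a valid measurement."""
        observer = observer_with_threshold(0.6)  # 20/80
        trials = []
        result = run_acuity_test(observer, Eye.OD, seed=2, collect_trials=trials)
        assert result == VisualAcuity(80)
        assert trials[0].size == 60  # first run starts at 20/60
        restart = [t for t in trials if t.size == 400]
        assert restart  # second run walked down from the top

    def test_unresolvable_chart_records_below_floor(self):
        observer = observer_with_threshold(1.5)
        result = run_acuity_test(observer, Eye.OD, seed=3)
        assert result.below_floor

    def test_trial_count_within_bound(self):
        bound = 6 * len(DEFAULT_LADDER) * 2  # worst case incl. the restart
        for threshold in (0.0, 0.4, 0.8, 1.5):
            for noise in (0.0, 0.3):
                observer = observer_with_threshold(threshold, noise=noise)
                trials = []
                run_acuity_test(observer, Eye.OD, seed=5, collect_trials=trials)
                assert len(trials) <= bound

    def test_same_seed_reproduces_trial_sequence(self):
        observer = observer_with_threshold(0.5, noise=0.2)
        t1, t2 = [], []
        r1 = run_acuity_test(observer, Eye.OD, seed=11, collect_trials=t1)
        r2 = run_acuity_test(observer, Eye.OD, seed=11, collect_trials=t2)
        assert r1 == r2
        assert t1 == t2

    def test_match_mismatch_marginal_frequency_is_half(self):
        """The presented pairs are drawn 50/50; tally over ~10^4 trials."""
        observer = observer_with_threshold(0.0, noise=0.5)
        matches = total = 0
        for seed in range(600):
            trials = []
            run_acuity_test(observer, Eye.OD, seed=seed, collect_trials=trials)
            matches += sum(t.pair_is_match for t in trials)
            total += len(trials)
        assert total >= 10_000
        assert abs(matches / total - 0.5) < 0.05


class TestRunEyeProtocol:
    def test_refractive_loss_normalizes_through_pinhole(self):
        observer = make_archetype("refractive", refractive=0.3)
        outcome = run_eye_protocol(observer, Eye.OD, seed=1)
        assert outcome.unaided == VisualAcuity(40)
        assert outcome.pinhole_required
        assert outcome.pinhole == VisualAcuity(20)

    def test_amblyopic_loss_resists_pinhole(self, amblyope_observer):
        outcome = run_eye_protocol(amblyope_observer, Eye.OS, seed=1)
        assert outcome.unaided == VisualAcuity(40)
        assert outcome.pinhole == VisualAcuity(40)
        assert outcome.best == VisualAcuity(40)

    def test_mild_loss_does_not_trigger_pinhole(self):
        observer = observer_with_threshold(0.1)  # records 20/25
        outcome = run_eye_protocol(observer, Eye.OD, seed=1)
        assert outcome.unaided == VisualAcuity(25)
        assert not outcome.pinhole_required
        assert outcome.pinhole is None

    def test_exactly_20_30_triggers_pinhole(self):
        observer = observer_with_threshold(0.176)  # 20/30 line exactly
        outcome = run_eye_protocol(observer, Eye.OD, seed=1)
        assert outcome.unaided == VisualAcuity(30)
        assert outcome.pinhole_required

    def test_below_floor_triggers_pinhole(self):
        observer = observer_with_threshold(1.5)
        outcome = run_eye_protocol(observer, Eye.OD, seed=1)
        assert outcome.unaided.below_floor
        assert outcome.pinhole_required
        assert outcome.pinhole.below_floor

    @pytest.mark.parametrize("neural, refractive", [(0.0, 0.0), (0.0, 0.3), (0.3, 0.0), (0.2, 0.4), (0.5, 0.3)])
    def test_pinhole_never_worse_than_unaided_for_noiseless_profiles(self, neural, refractive):
        observer = observer_with_threshold(neural, refractive=refractive)
        outcome = run_eye_protocol(observer, Eye.OD, seed=4)
        if outcome.pinhole is not None and not outcome.unaided.below_floor:
            assert not outcome.pinhole.below_floor
            assert outcome.pinhole.logmar <= outcome.unaided.logmar

    def test_pinhole_threshold_never_exceeds_unaided_threshold(self):
        """Model-level guarantee behind the pinhole rule, for any profile."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            observer = ObserverProfile(
                neural_logmar=_per_eye(*rng.uniform(0, 1.2, 2)),
                refractive_logmar=_per_eye(*rng.uniform(0, 0.6, 2)),
            )
            for eye in Eye:
                assert observer.effective_threshold(eye, True) <= observer.effective_threshold(eye, False)


def test_custom_ladder_is_honoured():
    ladder = ChartLadder((400, 200, 60, 30, 25, 20))
    observer = observer_with_threshold(0.35)  # between 20/40 and 20/50
    result = run_acuity_test(observer, Eye.OD, ladder=ladder, seed=1)
    assert result == VisualAcuity(60)  # coarser chart: next passing line up
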
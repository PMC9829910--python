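"""The tumbling-E match/mismatch acuity protocol, per eye.

Two equally sized Es are shown; the subject answers YES when their
orientations match and NO otherwise. Three correct responses at a size
advance the run to the next smaller chart line. The first incorrect
response at a size opens a second chance of up to three further E pairs at
that size: reaching three correct responses at the size (counting the ones
given before the error) still advances, while a second incorrect response
ends the run. Because at most three corrects are ever needed, the second
chance always resolves — it cannot run out of pairs inconclusively.

The recorded acuity for an eye is the smallest chart line with three
correct responses over the whole session. A run that ends without
completing any line from its start size (typically 20/60) is restarted
once from the largest line, 20/400; failing to complete even the 20/400
line records the acuity as "worse than 20/400".

When the recorded unaided acuity is 20/30 or worse the test is repeated
through a pinhole disc, which removes refractive blur: acuity that fails
to normalize through the pinhole points to a non-refractive (amblyopic)
deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ChartLadder, DEFAULT_LADDER, Eye, ProtocolStateError, VisualAcuity
from .observers import ObserverProfile, acuity_choice

__all__ = [
    "AcuityTrial",
    "AcuityRunState",
    "AcuityOutcome",
    "acuity_step",
    "run_acuity_test",
    "run_eye_protocol",
    "PINHOLE_CUTOFF",
]

#: Snellen denominator at or above which the pinhole retest is required.
PINHOLE_CUTOFF = 30

#: Pairs shown in the second chance opened by a first error at a size.
SECOND_CHANCE_PAIRS = 3

#: Corrects needed to complete a line.
CORRECT_TO_ADVANCE = 3


@dataclass(frozen=True)
class AcuityTrial:
    """One presented E pair and the subject's YES/NO response."""

    size: float
    pair_is_match: bool
    response_yes: bool

    @property
    def correct(self) -> bool:
        return self.pair_is_match == self.response_yes


@dataclass
class AcuityRunState:
    """State of one run of the self-test from a given start size."""

    ladder: ChartLadder
    current_size: float
    correct_at_size: int = 0
    second_chance_active: bool = False
    second_chance_remaining: int = 0
    trials: list = field(default_factory=list)
    completed_sizes: list = field(default_factory=list)
    ended: bool = False
    outcome: VisualAcuity | None = None

    @classmethod
    def new(cls, start_size: float, ladder: ChartLadder = DEFAULT_LADDER) -> "AcuityRunState":
        if start_size not in ladder:
            raise ValueError(f"start size 20/{start_size} is not on the chart ladder")
        return cls(ladder=ladder, current_size=start_size)


def acuity_step(
    state: AcuityRunState,
    pair_is_match: bool,
    response_yes: bool,
    ladder: ChartLadder | None = None,
) -> AcuityRunState:
    """Apply one YES/NO response; mutates and returns ``state``.

    ``pair_is_match`` is the ground truth of the pair that was presented
    (drawn before the response). The run ends either by completing the
    smallest line (outcome set to that line) or by a second incorrect
    response at a size (outcome left for the session-level resolution in
    :func:`run_acuity_test`).
    """
    ladder = ladder or state.ladder
    if state.ended:
        raise ProtocolStateError("cannot step an ended acuity run")
    trial = AcuityTrial(state.current_size, pair_is_match, response_yes)
    state.trials.append(trial)
    if trial.correct:
        state.correct_at_size += 1
        if state.second_chance_active:
            state.second_chance_remaining -= 1
        if state.correct_at_size >= CORRECT_TO_ADVANCE:
            state.completed_sizes.append(state.current_size)
            nxt = ladder.next_smaller(state.current_size)
            if nxt is None:
                state.ended = True
                state.outcome = VisualAcuity(state.current_size)
            else:
                state.current_size = nxt
                state.correct_at_size = 0
                state.second_chance_active = False
                state.second_chance_remaining = 0
    else:
        if state.second_chance_active:
            state.ended = True
        else:
            state.second_chance_active = True
            state.second_chance_remaining = SECOND_CHANCE_PAIRS
    return state


def _drive_run(
    observer: ObserverProfile,
    eye: Eye,
    start_size: float,
    pinhole: bool,
    ladder: ChartLadder,
    rng: np.random.Generator,
) -> AcuityRunState:
    state = AcuityRunState.new(start_size, ladder)
    while not state.ended:
        pair_is_match = bool(rng.random() < 0.5)
        response = acuity_choice(observer, eye, state.current_size, pinhole, pair_is_match, rng)
        acuity_step(state, pair_is_match, response)
    return state


def run_acuity_test(
    observer: ObserverProfile,
    eye: Eye,
    start_size: float = 60,
    pinhole: bool = False,
    ladder: ChartLadder = DEFAULT_LADDER,
    seed: int = 0,
    collect_trials: list | None = None,
) -> VisualAcuity:
    """Run the self-test for one eye and return the recorded acuity.

    Match/mismatch pairs are drawn 50/50 from the seeded generator. If the
    run from ``start_size`` ends without completing a single line, it is
    restarted once from the top of the ladder (20/400); the recorded acuity
    is the smallest line completed across both runs, or the below-floor
    record if none was.

    ``collect_trials``, when given, receives every presented trial (for
    session logging).
    """
    rng = np.random.default_rng(seed)
    first = _drive_run(observer, eye, start_size, pinhole, ladder, rng)
    completed = list(first.completed_sizes)
    trials = list(first.trials)
    if not completed and start_size != ladder.largest:
        second = _drive_run(observer, eye, ladder.largest, pinhole, ladder, rng)
        completed += second.completed_sizes
        trials += second.trials
    if collect_trials is not None:
        collect_trials.extend(trials)
    if completed:
        return VisualAcuity(min(completed))
    return VisualAcuity.worse_than_floor()


@dataclass
class AcuityOutcome:
    """Per-eye result of the acuity protocol, including the pinhole retest
    when the unaided acuity triggered it (20/30 or worse)."""

    eye: Eye
    unaided: VisualAcuity
    pinhole: VisualAcuity | None = None
    pinhole_required: bool = False
    unaided_trials: list = field(default_factory=list)
    pinhole_trials: list = field(default_factory=list)

    @property
    def best(self) -> VisualAcuity:
        """The acuity after the protocol's correction step: pinhole result
        when the retest was administered, unaided otherwise."""
        return self.pinhole if self.pinhole is not None else self.unaided


def run_eye_protocol(
    observer: ObserverProfile,
    eye: Eye,
    ladder: ChartLadder = DEFAULT_LADDER,
    seed: int = 0,
    start_size: float = 60,
) -> AcuityOutcome:
    """Full per-eye acuity protocol: unaided test, then the pinhole retest
    if and only if the unaided acuity is 20/30 or worse."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    unaided_seed, pinhole_seed = ss.spawn(2)
    unaided_trials: list = []
    unaided = run_acuity_test(
        observer, eye, start_size, pinhole=False, ladder=ladder,
        seed=unaided_seed, collect_trials=unaided_trials,
    )
    outcome = AcuityOutcome(eye=eye, unaided=unaided, unaided_trials=unaided_trials)
    if unaided.is_worse_than_or_equal(PINHOLE_CUTOFF):
        outcome.pinhole_required = True
        pinhole_trials: list = []
        outcome.pinhole = run_acuity_test(
            observer, eye, start_size, pinhole=True, ladder=ladder,
            seed=pinhole_seed, collect_trials=pinhole_trials,
        )
        outcome.pinhole_trials = pinhole_trials
    return outcome
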
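"""The interocular brightness-disparity game.

Two rival spaceships — one visible only to the right eye, one only to the
left, through crossed polarizers — are shown with a physical log-brightness
offset, and the subject taps the one that looks brighter. After each tap
the offset moves one fixed step against the chosen eye: keep choosing the
bottom (right-eye) ship and the pair is re-drawn with the right ship one
step dimmer. The adaptive track therefore walks toward the subject's
perceived-equality point, and the game ends once the responses have
reversed direction across that point the required number of times
("crossed and re-crossed").

Disparities live on a fixed grid of ``step`` log-unit increments spanning
``-max_disparity .. +max_disparity`` (defaults 0.3 and 1.8), positive
meaning the right-eye ship is physically brighter. Internally levels are
integers (multiples of ``step``), so grid arithmetic is exact.

The per-game endpoint is the interocular attenuation the track recovered:
each reversal brackets the equality point between two consecutive
presented levels, and the endpoint is minus the mean of those bracket
midpoints, snapped to the step grid (ties toward zero). Because a
noiseless observer overshoots the equality level by one step on each
approach, the brackets sit symmetrically around it and the endpoint equals
the observer's true attenuation exactly for any on-grid attenuation and
any start level. Endpoints are reported with positive sign meaning a
left-eye (OS) brightness deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core import Eye, ProtocolStateError
from .observers import ObserverProfile, brightness_choice

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "GameResult",
    "BrightnessClassification",
    "staircase_step",
    "run_brightness_game",
    "run_brightness_session",
    "classify_brightness",
]

BALANCED = "balanced"
IMBALANCED = "imbalanced"


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the brightness game and of the 2-of-3 session rule.

    ``balance_rule`` selects how "net zero imbalance in two of three games"
    is scored: ``"sign-discordance"`` (default) calls a session balanced
    when at least ``games_required_net_zero`` endpoints are exactly zero or
    when the nonzero endpoints disagree in sign (alternating ocular
    preference); ``"net-sum"`` calls it balanced when the signed endpoints
    sum to zero.
    """

    step: float = 0.3
    max_disparity: float = 1.8
    start_disparity: float = 1.8
    required_crossings: int = 2
    games_per_subject: int = 3
    games_required_net_zero: int = 2
    balance_rule: str = "sign-discordance"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if abs(self.max_disparity / self.step - round(self.max_disparity / self.step)) > 1e-9:
            raise ValueError("max_disparity must be an integer multiple of step")
        if abs(self.start_disparity) > self.max_disparity + 1e-9:
            raise ValueError("|start_disparity| must not exceed max_disparity")
        if abs(self.start_disparity / self.step - round(self.start_disparity / self.step)) > 1e-9:
            raise ValueError("start_disparity must lie on the step grid")
        if self.required_crossings < 2:
            raise ValueError("required_crossings must be >= 2")
        if self.balance_rule not in ("sign-discordance", "net-sum"):
            raise ValueError(f"unknown balance_rule {self.balance_rule!r}")

    @property
    def max_level(self) -> int:
        return round(self.max_disparity / self.step)

    @property
    def start_level(self) -> int:
        return round(self.start_disparity / self.step)

    @property
    def trial_budget(self) -> int:
        """Hard trial cap guaranteeing termination: twice a full sweep of
        the grid per required crossing (52 at the defaults)."""
        return 2 * (2 * self.max_level + 1) * self.required_crossings

    def level_to_disparity(self, level: int) -> float:
        return round(level * self.step, 10)


@dataclass
class StaircaseState:
    """Trial-by-trial state of one brightness game."""

    config: StaircaseConfig
    current_level: int
    responses: list = field(default_factory=list)  # (level:int, Eye) pairs
    crossing_pairs: list = field(default_factory=list)  # (level, level) brackets
    finished: bool = False
    ceiling: bool = False

    @classmethod
    def new(cls, config: StaircaseConfig, start_disparity: float | None = None) -> "StaircaseState":
        start = config.start_level if start_disparity is None else round(start_disparity / config.step)
        if abs(start) > config.max_level:
            raise ValueError("start disparity outside the grid")
        return cls(config=config, current_level=start)

    @property
    def current_disparity(self) -> float:
        return self.config.level_to_disparity(self.current_level)

    @property
    def trace(self) -> list:
        """Responses as (disparity in log units, chosen eye)."""
        return [(self.config.level_to_disparity(l), eye) for l, eye in self.responses]

    @property
    def crossings(self) -> list:
        """Signed disparities (bracket midpoints) at which responses
        reversed across the equality point."""
        return [
            round((a + b) / 2 * self.config.step, 10) for a, b in self.crossing_pairs
        ]


def staircase_step(
    state: StaircaseState, chosen_eye: Eye, config: StaircaseConfig | None = None
) -> StaircaseState:
    """Advance the staircase by one response; mutates and returns ``state``.

    The disparity moves one step against the chosen eye (right-eye tap
    decreases it, left-eye tap increases it), clamped to the grid edges.
    A crossing is recorded whenever two consecutive responses choose
    opposite eyes; the game finishes at ``required_crossings`` crossings or
    at the trial budget (the latter flags ``ceiling``).
    """
    config = config or state.config
    if state.finished:
        raise ProtocolStateError("cannot step a finished brightness game")
    level = state.current_level
    if state.responses and state.responses[-1][1] is not chosen_eye:
        state.crossing_pairs.append((state.responses[-1][0], level))
    state.responses.append((level, chosen_eye))
    if len(state.crossing_pairs) >= config.required_crossings:
        state.finished = True
        return state
    if len(state.responses) >= config.trial_budget:
        state.finished = True
        state.ceiling = True
        return state
    move = -1 if chosen_eye is Eye.OD else +1
    state.current_level = max(-config.max_level, min(config.max_level, level + move))
    return state


@dataclass(frozen=True)
class GameResult:
    """Signed per-game endpoint (log units; positive = OS deficit) plus the
    full response trace."""

    endpoint: float
    trials: int
    trace: tuple
    crossings: tuple
    ceiling: bool = False


def _snap_to_grid(q: Fraction) -> int:
    """Nearest integer to ``q`` with exact ties resolved toward zero."""
    sign = -1 if q < 0 else 1
    a = abs(q)
    n = a.numerator // a.denominator
    frac = a - n
    if frac > Fraction(1, 2):
        n += 1
    return sign * n


def finalize_game(state: StaircaseState) -> GameResult:
    """Resolve a finished staircase into its signed endpoint."""
    if not state.finished:
        raise ProtocolStateError("game is not finished")
    cfg = state.config
    if state.ceiling or len(state.crossing_pairs) < cfg.required_crossings:
        # Never (or not often enough) reversed: report the clamped extreme.
        endpoint = round(-state.current_disparity, 10)
        ceiling = True
    else:
        # endpoint = -mean of bracket midpoints, snapped to the step grid:
        # midpoint of bracket (a, b) is (a + b)/2 levels, so the mean over
        # k brackets is sum(a + b) / (2k) levels — kept exact as a Fraction.
        levels = Fraction(
            -sum(a + b for a, b in state.crossing_pairs), 2 * len(state.crossing_pairs)
        )
        endpoint = round(_snap_to_grid(levels) * cfg.step, 10)
        ceiling = False
    return GameResult(
        endpoint=endpoint,
        trials=len(state.responses),
        trace=tuple(state.trace),
        crossings=tuple(state.crossings),
        ceiling=ceiling,
    )


def run_brightness_game(
    observer: ObserverProfile,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int = 0,
    start_disparity: float | None = None,
) -> GameResult:
    """Play one full brightness game with a simulated observer."""
    rng = np.random.default_rng(seed)
    state = StaircaseState.new(config, start_disparity)
    previous: Eye | None = None
    while not state.finished:
        choice = brightness_choice(observer, state.current_disparity, rng, previous)
        staircase_step(state, choice)
        previous = choice
    return finalize_game(state)


def run_brightness_session(
    observer: ObserverProfile,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int = 0,
) -> list:
    """Play the subject's full set of games (three by default).

    The start level alternates sign across games (+start, -start, +start,
    ...) so any bias from the starting side cancels over the session.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(config.games_per_subject)
    results = []
    for i, child in enumerate(child_seeds):
        start = config.start_disparity * (1 if i % 2 == 0 else -1)
        rng = np.random.default_rng(child)
        state = StaircaseState.new(config, start)
        previous: Eye | None = None
        while not state.finished:
            choice = brightness_choice(observer, state.current_disparity, rng, previous)
            staircase_step(state, choice)
            previous = choice
        results.append(finalize_game(state))
    return results


@dataclass(frozen=True)
class BrightnessClassification:
    """Session-level balanced/imbalanced call over the subject's games."""

    endpoints: tuple
    label: str
    net_imbalance: float


def classify_brightness(
    results: list, config: StaircaseConfig = StaircaseConfig()
) -> BrightnessClassification:
    """Score the session: a normal subject must reach a net-zero brightness
    imbalance in ``games_required_net_zero`` of the games.

    Under the default sign-discordance rule, sessions whose nonzero
    endpoints point to opposite eyes (alternating ocular preference, the
    signature of a treated amblyope) also count as balanced: no single eye
    shows a consistent deficit.
    """
    if len(results) != config.games_per_subject:
        raise ValueError(
            f"expected {config.games_per_subject} game results, got {len(results)}"
        )
    endpoints = tuple(r.endpoint if isinstance(r, GameResult) else float(r) for r in results)
    nonzero = [e for e in endpoints if e != 0.0]
    if config.balance_rule == "net-sum":
        net = round(sum(endpoints), 10)
        balanced = net == 0.0
    else:
        zeros = len(endpoints) - len(nonzero)
        discordant = bool(nonzero) and min(nonzero) < 0 < max(nonzero)
        balanced = zeros >= config.games_required_net_zero or discordant
        net = 0.0 if balanced else max(nonzero, key=abs)
    return BrightnessClassification(
        endpoints=endpoints,
        label=BALANCED if balanced else IMBALANCED,
        net_imbalance=0.0 if balanced else net,
    )
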
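"""Generative simulated observers for the three screening protocols.

An :class:`ObserverProfile` is the minimal perceptual model needed to
answer every trial the protocols can present:

* **Brightness** — each eye attenuates log-luminance additively by a fixed
  amount. For a stimulus pair with physical log-brightness disparity ``d``
  (positive = the right eye's spaceship physically brighter), the perceived
  disparity is ``d + (delta_OS - delta_OD)``: dimming the left eye makes the
  right-eye image look relatively brighter. A noiseless observer picks the
  eye with the larger perceived brightness; with ``decision_noise`` sigma
  the choice is logistic in the perceived disparity.
* **Acuity** — each eye's threshold splits into a neural component (not
  correctable by a pinhole; the amblyopic deficit) and a refractive
  component (optical blur, removed entirely by a pinhole). A noiseless
  observer answers a tumbling-E pair correctly iff the letter's logMAR is
  at or above the eye's effective threshold, and incorrectly below it; a
  noisy observer guesses 50/50 below threshold, the chance level of the
  YES/NO matching task.
* **Colour** — a per-eye defect axis (red-green or blue-yellow/tritan).
  The observer misses shape-present plates on the defective axis with
  probability ``color_miss_prob`` and answers every other plate correctly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Eye, snellen_to_logmar

__all__ = [
    "ColorAxis",
    "ObserverProfile",
    "brightness_choice",
    "acuity_choice",
    "color_choice",
    "make_archetype",
    "ARCHETYPE_TRUTH_LABELS",
]

# Tolerance for "letter size at or above threshold" so that a profile built
# from a nominal 0.3 logMAR (20/40) threshold passes the 20/40 line, whose
# exact logMAR is log10(2) = 0.30103.
_THRESHOLD_EPS = 5e-3


class ColorAxis(str, enum.Enum):
    """Colour-confusion axis probed by pseudoisochromatic plates."""

    NONE = "none"
    RED_GREEN = "red-green"  # protan/deutan axis
    TRITAN = "tritan"        # blue-yellow axis


def _per_eye(od: float, os_: float) -> dict:
    return {Eye.OD: od, Eye.OS: os_}


@dataclass
class ObserverProfile:
    """Parameters of one simulated subject.

    Attributes
    ----------
    brightness_attenuation
        Per-eye attenuation of perceived log-luminance, in log units, >= 0.
        The interocular brightness disparity the staircase estimates is
        ``delta_OS - delta_OD`` (positive = left-eye deficit).
    neural_logmar
        Per-eye acuity floor in logMAR not correctable by a pinhole.
    refractive_logmar
        Per-eye refractive blur in logMAR, >= 0, removed by a pinhole.
    color_axis
        Per-eye colour-defect axis (:class:`ColorAxis.NONE` for normal).
    decision_noise
        Logistic noise sigma for brightness choices, in log units; 0 means
        fully deterministic responses in every protocol.
    color_miss_prob
        Probability of missing a shape-present plate on the defective axis.
    fails_demonstration
        Archetype flag for a subject who cannot do the colour task at all
        (fails the demonstration plates and never qualifies).
    label
        Free-text archetype tag carried into cohort truth labels.
    """

    brightness_attenuation: dict = field(default_factory=lambda: _per_eye(0.0, 0.0))
    neural_logmar: dict = field(default_factory=lambda: _per_eye(0.0, 0.0))
    refractive_logmar: dict = field(default_factory=lambda: _per_eye(0.0, 0.0))
    color_axis: dict = field(
        default_factory=lambda: {Eye.OD: ColorAxis.NONE, Eye.OS: ColorAxis.NONE}
    )
    decision_noise: float = 0.0
    color_miss_prob: float = 1.0
    fails_demonstration: bool = False
    label: str = "normal"

    def __post_init__(self) -> None:
        for eye in Eye:
            if self.brightness_attenuation[eye] < 0:
                raise ValueError("brightness attenuation must be >= 0")
            if self.refractive_logmar[eye] < 0:
                raise ValueError("refractive component must be >= 0")
        if self.decision_noise < 0:
            raise ValueError("decision noise must be >= 0")

    @property
    def interocular_attenuation(self) -> float:
        """delta_OS - delta_OD, the signed brightness disparity in log units
        (positive = left-eye deficit)."""
        return (
            self.brightness_attenuation[Eye.OS]
            - self.brightness_attenuation[Eye.OD]
        )

    def effective_threshold(self, eye: Eye, pinhole: bool) -> float:
        """The eye's acuity threshold in logMAR for the given viewing mode."""
        t = self.neural_logmar[eye]
        if not pinhole:
            t += self.refractive_logmar[eye]
        return t

    def mirrored(self) -> "ObserverProfile":
        """The profile with the two eyes' parameters swapped."""

        def swap(d: dict) -> dict:
            return {Eye.OD: d[Eye.OS], Eye.OS: d[Eye.OD]}

        return replace(
            self,
            brightness_attenuation=swap(self.brightness_attenuation),
            neural_logmar=swap(self.neural_logmar),
            refractive_logmar=swap(self.refractive_logmar),
            color_axis=swap(self.color_axis),
        )


def brightness_choice(
    observer: ObserverProfile,
    disparity: float,
    rng: np.random.Generator,
    previous_choice: Eye | None = None,
) -> Eye:
    """Which spaceship the observer taps as brighter.

    ``disparity`` is the physical log-brightness offset of the right-eye
    (bottom) spaceship over the left-eye (top) one. The perceived offset is
    ``disparity + (delta_OS - delta_OD)``.

    A noiseless observer chooses the right eye when the perceived offset is
    positive and the left when negative. At exact perceived equality the
    choice is a tie; the observer then repeats the previous choice (first
    trial: right). Repeating the previous choice carries the staircase one
    step past the equality level on each approach, so the two reversals
    bracket the equality point symmetrically from both sides — which is
    what lets the game read the attenuation off the reversal levels exactly.

    With ``decision_noise`` sigma > 0 the right eye is chosen with
    probability ``1 / (1 + exp(-perceived / sigma))``.
    """
    perceived = disparity + observer.interocular_attenuation
    if observer.decision_noise > 0:
        p_right = 1.0 / (1.0 + np.exp(-perceived / observer.decision_noise))
        return Eye.OD if rng.random() < p_right else Eye.OS
    if perceived > 1e-12:
        return Eye.OD
    if perceived < -1e-12:
        return Eye.OS
    return previous_choice if previous_choice is not None else Eye.OD


def acuity_choice(
    observer: ObserverProfile,
    eye: Eye,
    size: float,
    pinhole: bool,
    pair_is_match: bool,
    rng: np.random.Generator,
) -> bool:
    """YES/NO response to a tumbling-E pair of the given Snellen size.

    The response is correct iff the letter's logMAR is at or above the
    eye's effective threshold. Below threshold a noiseless observer is
    always wrong (keeping the whole run seed-independent); a noisy one
    guesses at the 50% chance level of the matching task.
    """
    letter_logmar = snellen_to_logmar(size)
    threshold = observer.effective_threshold(eye, pinhole)
    if letter_logmar >= threshold - _THRESHOLD_EPS:
        correct = True
    elif observer.decision_noise > 0:
        correct = bool(rng.random() < 0.5)
    else:
        correct = False
    return pair_is_match if correct else (not pair_is_match)


def color_choice(observer: ObserverProfile, eye: Eye, plate, rng: np.random.Generator) -> bool:
    """Whether the observer identifies the plate correctly.

    Demonstration plates are answered correctly unless the profile is the
    explicit "unable" archetype. Test plates are missed only when the
    plate's axis matches the eye's defect axis, with probability
    ``color_miss_prob``.
    """
    if plate.kind.value == "demonstration":
        return not observer.fails_demonstration
    axis = observer.color_axis[eye]
    if plate.shape_present and plate.axis == axis and axis is not ColorAxis.NONE:
        return not bool(rng.random() < observer.color_miss_prob)
    return True


# ---------------------------------------------------------------------------
# Archetype library: the subject types the screening cohort is composed of.
# ---------------------------------------------------------------------------

#: truth label each archetype carries into screening evaluation
ARCHETYPE_TRUTH_LABELS = {
    "normal": "normal",
    "amblyope": "unilateral-amblyope",
    "refractive": "refractive",
    "treated-amblyope": "treated-amblyope",
    "color-defect": "color-defect",
}


def make_archetype(name: str, **params) -> ObserverProfile:
    """Build a named observer archetype.

    Archetypes
    ----------
    ``normal``
        No attenuation, 20/20 thresholds, no colour defect.
    ``amblyope``
        Unilateral amblyopia: brightness attenuation ``delta`` (default 0.6
        log units) and a pinhole-resistant neural acuity loss
        ``neural`` (default 0.3 logMAR, i.e. 20/40) in ``eye`` (default OS);
        optionally an acquired ``tritan`` defect in the same eye.
    ``refractive``
        Uncorrected refractive error ``refractive`` logMAR (default 0.3) in
        both eyes, fully correctable by the pinhole; no amblyopia.
    ``treated-amblyope``
        Successfully treated amblyope: 20/20 acuity, zero net attenuation;
        with ``decision_noise`` left at 0 the brightness endpoints come out
        0.0, and small per-game biases are modelled at the cohort level.
    ``color-defect``
        Hereditary bilateral colour defect along ``axis`` (default
        red-green), otherwise normal.
    """
    eye = Eye(params.pop("eye", "OS"))
    noise = params.pop("decision_noise", 0.0)
    if name == "normal":
        profile = ObserverProfile(label="normal")
    elif name == "amblyope":
        delta = params.pop("delta", 0.6)
        neural = params.pop("neural", 0.3)
        tritan = params.pop("tritan", False)
        att = {eye: delta, eye.fellow: 0.0}
        neu = {eye: neural, eye.fellow: 0.0}
        axes = {eye: ColorAxis.TRITAN if tritan else ColorAxis.NONE,
                eye.fellow: ColorAxis.NONE}
        profile = ObserverProfile(
            brightness_attenuation=att, neural_logmar=neu,
            color_axis=axes, label="amblyope",
        )
    elif name == "refractive":
        refr = params.pop("refractive", 0.3)
        profile = ObserverProfile(
            refractive_logmar=_per_eye(refr, refr), label="refractive"
        )
    elif name == "treated-amblyope":
        profile = ObserverProfile(label="treated-amblyope")
    elif name == "color-defect":
        axis = ColorAxis(params.pop("axis", "red-green"))
        profile = ObserverProfile(
            color_axis={Eye.OD: axis, Eye.OS: axis}, label="color-defect"
        )
    else:
        raise ValueError(f"unknown archetype {name!r}")
    if params:
        raise TypeError(f"unexpected parameters for {name!r}: {sorted(params)}")
    profile.decision_noise = noise
    return profile
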
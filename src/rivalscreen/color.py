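"""Digital pseudoisochromatic (HRR-style) colour-vision test, per eye.

The subject first sees the demonstration plates, which any subject with
normal task comprehension can identify regardless of colour vision; a
single demonstration error disqualifies the eye from testing (the result
is "unclassified", signalling a retest, not a defect). A qualified eye
then sees the test plates in a seeded pseudo-random order. Test plates
probe one of two colour-confusion axes — red-green (protan/deutan) or
blue-yellow (tritan) — and errors are tallied per axis; reaching the
defect threshold (two errors by default) on an axis labels the eye with a
defect on that axis.

Comparing the two eyes separates the aetiology: identical bilateral
defects suggest a hereditary defect, while a defect confined to one eye
suggests an acquired/ocular cause (as in an amblyopic eye).

The packaged plate set (4 demonstration + 20 test plates: 14 red-green,
6 tritan) mirrors the structure of the AO-HRR series; the artwork itself
is out of scope and plates are abstracted to (id, kind, axis) records in
``data/hrr_plates.json``. Counts and threshold are configurable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import Eye
from .observers import ColorAxis, ObserverProfile, color_choice

__all__ = [
    "PlateKind",
    "ColorPlate",
    "ColorEyeResult",
    "ColorClassification",
    "ColorTestError",
    "load_default_plates",
    "run_color_test",
    "classify_color",
    "DEFECT_THRESHOLD",
]

#: Errors on one axis at or above which the eye is labelled defective.
DEFECT_THRESHOLD = 2

LABEL_NORMAL = "normal"
LABEL_RED_GREEN = "red-green defect"
LABEL_BLUE_YELLOW = "blue-yellow defect"
LABEL_UNCLASSIFIED = "unclassified"

CATEGORY_NORMAL = "normal"
CATEGORY_HEREDITARY = "bilateral-identical"
CATEGORY_ACQUIRED = "monocular"
CATEGORY_DISCORDANT = "bilateral-discordant"

_AXIS_LABELS = {
    ColorAxis.RED_GREEN: LABEL_RED_GREEN,
    ColorAxis.TRITAN: LABEL_BLUE_YELLOW,
}


class ColorTestError(RuntimeError):
    """Raised when classification is requested for an unqualified eye; the
    appropriate action is a retest, not a defect label."""


class PlateKind(str, enum.Enum):
    DEMONSTRATION = "demonstration"
    TEST = "test"


@dataclass(frozen=True)
class ColorPlate:
    """One plate: an identifier, its role, and the axis it probes."""

    plate_id: str
    kind: PlateKind
    axis: ColorAxis = ColorAxis.NONE
    shape_present: bool = True

    def __post_init__(self) -> None:
        if self.kind is PlateKind.DEMONSTRATION and self.axis is not ColorAxis.NONE:
            raise ValueError("demonstration plates carry no confusion axis")
        if self.kind is PlateKind.TEST and self.shape_present and self.axis is ColorAxis.NONE:
            raise ValueError("shape-present test plates must carry a confusion axis")


def load_default_plates() -> list:
    """The packaged plate set."""
    raw = json.loads(
        resources.files("rivalscreen").joinpath("data/hrr_plates.json").read_text()
    )
    return [
        ColorPlate(
            plate_id=p["plate_id"],
            kind=PlateKind(p["kind"]),
            axis=ColorAxis(p.get("axis", "none")),
            shape_present=p.get("shape_present", True),
        )
        for p in raw["plates"]
    ]


@dataclass
class ColorEyeResult:
    """Per-eye outcome: qualification, per-axis error tally, and label."""

    eye: Eye
    qualified: bool
    errors_by_axis: dict = field(default_factory=dict)
    label: str = LABEL_UNCLASSIFIED
    responses: list = field(default_factory=list)  # (plate_id, correct)


def _label_from_errors(errors_by_axis: dict, threshold: int) -> str:
    over = {ax: n for ax, n in errors_by_axis.items() if n >= threshold}
    if not over:
        return LABEL_NORMAL
    # With errors above threshold on both axes, label by the worse axis;
    # a tie goes to red-green, by far the more prevalent defect.
    worst = max(over, key=lambda ax: (over[ax], ax is ColorAxis.RED_GREEN))
    return _AXIS_LABELS[worst]


def run_color_test(
    observer: ObserverProfile,
    eye: Eye,
    plates: list | None = None,
    seed: int = 0,
    defect_threshold: int = DEFECT_THRESHOLD,
) -> ColorEyeResult:
    """Administer the colour test to one eye.

    Demonstration plates come first, in fixed order; any error among them
    leaves the eye unqualified and no test plates are shown. Test plates
    follow in a seeded pseudo-random permutation.
    """
    if plates is None:
        plates = load_default_plates()
    demo = [p for p in plates if p.kind is PlateKind.DEMONSTRATION]
    test = [p for p in plates if p.kind is PlateKind.TEST]
    if not demo or not test:
        raise ValueError("plate set needs at least one demonstration and one test plate")
    rng = np.random.default_rng(seed)
    result = ColorEyeResult(eye=eye, qualified=True)
    for plate in demo:
        correct = color_choice(observer, eye, plate, rng)
        result.responses.append((plate.plate_id, correct))
        if not correct:
            result.qualified = False
            result.label = LABEL_UNCLASSIFIED
            return result
    errors = {ColorAxis.RED_GREEN: 0, ColorAxis.TRITAN: 0}
    order = rng.permutation(len(test))
    for i in order:
        plate = test[i]
        correct = color_choice(observer, eye, plate, rng)
        result.responses.append((plate.plate_id, correct))
        if not correct and plate.axis in errors:
            errors[plate.axis] += 1
    result.errors_by_axis = errors
    result.label = _label_from_errors(errors, defect_threshold)
    return result


@dataclass(frozen=True)
class ColorClassification:
    """Both eyes' results and the hereditary/acquired call."""

    od: ColorEyeResult
    os: ColorEyeResult
    category: str

    @property
    def defective_eyes(self) -> list:
        return [r.eye for r in (self.od, self.os) if r.label not in (LABEL_NORMAL,)]


def classify_color(od: ColorEyeResult, os_: ColorEyeResult) -> ColorClassification:
    """Combine the two eyes into a hereditary/acquired classification.

    Identical bilateral defects are classified hereditary; a defect in
    exactly one eye is classified acquired (monocular). Discordant
    bilateral defects get their own category — the scheme cannot call them
    either way.
    """
    for r in (od, os_):
        if not r.qualified:
            raise ColorTestError(
                f"{r.eye.value} did not qualify on the demonstration plates; retest required"
            )
    od_defect = od.label != LABEL_NORMAL
    os_defect = os_.label != LABEL_NORMAL
    if not od_defect and not os_defect:
        category = CATEGORY_NORMAL
    elif od_defect and os_defect:
        category = CATEGORY_HEREDITARY if od.label == os_.label else CATEGORY_DISCORDANT
    else:
        category = CATEGORY_ACQUIRED
    return ColorClassification(od=od, os=os_, category=category)
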
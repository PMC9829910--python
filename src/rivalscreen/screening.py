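"""Per-subject screening orchestration, cohort simulation, referral rules
and diagnostic-performance metrics.

A full screening session runs, for each subject: three brightness games
(start side alternating), the per-eye acuity protocol with the pinhole
retest rule, and the per-eye colour test. A subject is referred for
complete ophthalmological examination when any of these flags an abnormal
result:

* brightness session classified imbalanced (a consistent one-eye deficit),
* acuity after the pinhole correction step still worse than 20/30 in
  either eye (refractive error alone normalizes through the pinhole), or
* a monocular colour defect (acquired pattern).

Cohorts are mixtures of observer archetypes; screening a simulated cohort
against its known truth labels yields a confusion matrix and the usual
screening statistics (sensitivity, specificity, prevalence), reported as
percentages at clinical-report precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import Eye, round_percent
from .observers import ARCHETYPE_TRUTH_LABELS, ObserverProfile, make_archetype
from .staircase import (
    IMBALANCED,
    BrightnessClassification,
    StaircaseConfig,
    classify_brightness,
    run_brightness_session,
)
from .acuity import AcuityOutcome, run_acuity_test, run_eye_protocol, PINHOLE_CUTOFF
from .core import ChartLadder, DEFAULT_LADDER
from .color import (
    ColorClassification,
    ColorEyeResult,
    CATEGORY_ACQUIRED,
    classify_color,
    run_color_test,
    DEFECT_THRESHOLD,
)

__all__ = [
    "ScreeningConfig",
    "SubjectRecord",
    "ScreeningMetrics",
    "screen_subject",
    "simulate_cohort",
    "screen_cohort",
    "evaluate_screening",
    "measure_cohort_acuity",
    "load_cohort_spec",
    "load_school_cohort_spec",
    "REASON_BRIGHTNESS",
    "REASON_ACUITY",
    "REASON_COLOR",
]

REASON_BRIGHTNESS = "brightness-imbalance"
REASON_ACUITY = "subnormal-pinhole-acuity"
REASON_COLOR = "monocular-color-defect"


@dataclass(frozen=True)
class ScreeningConfig:
    """Configuration shared by every subject of a screening session."""

    staircase: StaircaseConfig = StaircaseConfig()
    ladder: ChartLadder = DEFAULT_LADDER
    start_size: float = 60
    defect_threshold: int = DEFECT_THRESHOLD
    acuity_referral_cutoff: float = PINHOLE_CUTOFF


@dataclass
class SubjectRecord:
    """One subject's complete screening session."""

    subject_id: str
    truth_label: str
    brightness: BrightnessClassification
    games: list
    acuity: dict  # Eye -> AcuityOutcome
    color_od: ColorEyeResult
    color_os: ColorEyeResult
    color_category: str | None
    referred: bool
    referral_reasons: list
    seed: int | None = None
    acuity_measures: dict = field(default_factory=dict)  # name -> {Eye: AcuityOutcome}


def screen_subject(
    observer: ObserverProfile,
    config: ScreeningConfig = ScreeningConfig(),
    seed: int = 0,
    subject_id: str = "S000",
    truth_label: str | None = None,
) -> SubjectRecord:
    """Run all three protocols on one observer and apply the referral rule."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_bright, s_od, s_os, s_cod, s_cos = ss.spawn(5)

    games = run_brightness_session(observer, config.staircase, s_bright)
    brightness = classify_brightness(games, config.staircase)

    acuity = {
        Eye.OD: run_eye_protocol(observer, Eye.OD, config.ladder, s_od, config.start_size),
        Eye.OS: run_eye_protocol(observer, Eye.OS, config.ladder, s_os, config.start_size),
    }

    color_od = run_color_test(observer, Eye.OD, seed=s_cod, defect_threshold=config.defect_threshold)
    color_os = run_color_test(observer, Eye.OS, seed=s_cos, defect_threshold=config.defect_threshold)
    if color_od.qualified and color_os.qualified:
        color_category = classify_color(color_od, color_os).category
    else:
        color_category = None

    reasons = []
    if brightness.label == IMBALANCED:
        reasons.append(REASON_BRIGHTNESS)
    if any(
        acuity[eye].best.is_worse_than(config.acuity_referral_cutoff) for eye in Eye
    ):
        reasons.append(REASON_ACUITY)
    if color_category == CATEGORY_ACQUIRED:
        reasons.append(REASON_COLOR)

    record = SubjectRecord(
        subject_id=subject_id,
        truth_label=truth_label or ARCHETYPE_TRUTH_LABELS.get(observer.label, observer.label),
        brightness=brightness,
        games=games,
        acuity=acuity,
        color_od=color_od,
        color_os=color_os,
        color_category=color_category,
        referred=bool(reasons),
        referral_reasons=reasons,
        seed=seed if isinstance(seed, int) else None,
    )
    record.acuity_measures["ipad"] = acuity
    return record


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _normalize_spec(spec) -> list:
    """Accept ``{"archetype-name": count, ...}`` or
    ``{"groups": [{"archetype": ..., "count": ..., "params": {...}}, ...]}``
    (or the bare group list) and return the group list."""
    if isinstance(spec, dict) and "groups" in spec:
        groups = spec["groups"]
    elif isinstance(spec, dict):
        groups = [{"archetype": name, "count": n} for name, n in spec.items()]
    else:
        groups = list(spec)
    return groups


def simulate_cohort(spec, seed: int = 0) -> list:
    """Build the requested mixture of observer archetypes.

    Returns a list of ``(ObserverProfile, truth_label)`` pairs, exactly as
    many as requested and in a deterministic order. ``seed`` is accepted
    for interface symmetry with the protocol runners; with the archetypes'
    fixed parameters the construction involves no random draws.
    """
    groups = _normalize_spec(spec)
    cohort = []
    for group in groups:
        name = group["archetype"]
        count = int(group["count"])
        if count < 0:
            raise ValueError("group counts must be >= 0")
        params = dict(group.get("params", {}))
        truth = group.get("truth_label", ARCHETYPE_TRUTH_LABELS.get(name, name))
        for _ in range(count):
            cohort.append((make_archetype(name, **params), truth))
    if not cohort:
        raise ValueError("cohort specification produced no subjects")
    return cohort


def load_cohort_spec(path) -> list:
    """Read a cohort specification JSON file (group-list format)."""
    with open(path) as f:
        return _normalize_spec(json.load(f))


def load_school_cohort_spec() -> list:
    """The packaged 204-child school-screening cohort: 202 subjects without
    brightness imbalance and 2 unilateral amblyopes (left-eye attenuation
    0.3 and 0.6 log units)."""
    raw = json.loads(
        resources.files("rivalscreen").joinpath("data/school_cohort_204.json").read_text()
    )
    return _normalize_spec(raw)


def screen_cohort(
    cohort: list,
    config: ScreeningConfig = ScreeningConfig(),
    seed: int = 0,
) -> list:
    """Screen every (observer, truth_label) pair of a simulated cohort."""
    ss = np.random.SeedSequence(seed)
    records = []
    for i, ((observer, truth), child) in enumerate(zip(cohort, ss.spawn(len(cohort)))):
        records.append(
            screen_subject(
                observer, config, child, subject_id=f"S{i:03d}", truth_label=truth
            )
        )
    return records


# ---------------------------------------------------------------------------
# Diagnostic performance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningMetrics:
    """Confusion matrix and screening statistics (percentages rounded at
    clinical-report precision, integers by default)."""

    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int
    sensitivity: float
    specificity: float
    prevalence: float

    @property
    def n(self) -> int:
        return (
            self.true_positives + self.false_positives
            + self.true_negatives + self.false_negatives
        )


def evaluate_screening(
    records: list,
    target_condition: str = "unilateral-amblyope",
    positive_rule=None,
    decimals: int = 0,
) -> ScreeningMetrics:
    """Confusion matrix of a referral rule against the cohort truth labels.

    ``positive_rule`` is the set of referral reasons that count as a
    screen-positive (e.g. ``{REASON_BRIGHTNESS}`` for brightness-only
    screening); ``None`` uses the overall referral decision.
    """
    if not records:
        raise ValueError("no records to evaluate")
    rule = None if positive_rule is None else set(positive_rule)
    tp = fp = tn = fn = 0
    for r in records:
        truth = r.truth_label == target_condition
        positive = r.referred if rule is None else bool(rule & set(r.referral_reasons))
        if truth and positive:
            tp += 1
        elif truth:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    if tp + fn == 0:
        raise ValueError(
            f"no subject with condition {target_condition!r}: sensitivity undefined"
        )
    if tn + fp == 0:
        raise ValueError(
            f"every subject has condition {target_condition!r}: specificity undefined"
        )
    n = tp + fp + tn + fn
    return ScreeningMetrics(
        true_positives=tp,
        false_positives=fp,
        true_negatives=tn,
        false_negatives=fn,
        sensitivity=round_percent(tp, tp + fn, decimals),
        specificity=round_percent(tn, tn + fp, decimals),
        prevalence=round_percent(tp + fn, n, decimals),
    )


# ---------------------------------------------------------------------------
# Second acuity administration (method comparison)
# ---------------------------------------------------------------------------

def measure_cohort_acuity(
    records: list,
    cohort: list,
    name: str,
    seed: int = 0,
    config: ScreeningConfig = ScreeningConfig(),
) -> None:
    """Re-measure every eye with an independent administration of the
    acuity protocol and attach it to the records as measure ``name``.

    Unlike the screening pass, both the unaided and the pinhole
    measurement are taken for every eye (the design of a method-comparison
    study), so agreement can be analysed with or without the pinhole.
    """
    if len(records) != len(cohort):
        raise ValueError("records and cohort lengths differ")
    ss = np.random.SeedSequence(seed)
    for record, (observer, _), child in zip(records, cohort, ss.spawn(len(records))):
        eyes = {}
        for eye, eye_ss in zip(Eye, child.spawn(2)):
            s_unaided, s_pinhole = eye_ss.spawn(2)
            unaided = run_acuity_test(
                observer, eye, config.start_size, pinhole=False,
                ladder=config.ladder, seed=s_unaided,
            )
            pinhole = run_acuity_test(
                observer, eye, config.start_size, pinhole=True,
                ladder=config.ladder, seed=s_pinhole,
            )
            eyes[eye] = AcuityOutcome(
                eye=eye, unaided=unaided, pinhole=pinhole, pinhole_required=True
            )
        record.acuity_measures[name] = eyes
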
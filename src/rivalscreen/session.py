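"""Session persistence: one JSON document per screened subject.

The document carries the schema version, the subject's identifiers, the
full per-trial traces of all three protocols, the outcomes, and the
referral decision, so a stored session can be re-evaluated without
re-running the simulation. Writing is canonical (sorted keys, fixed
indentation), which makes write -> read -> write byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from .core import Eye, VisualAcuity
from .observers import ColorAxis
from .acuity import AcuityOutcome, AcuityTrial
from .color import ColorEyeResult
from .staircase import BrightnessClassification, GameResult
from .screening import SubjectRecord

__all__ = [
    "SCHEMA_VERSION",
    "SchemaVersionError",
    "session_to_dict",
    "session_from_dict",
    "write_session",
    "read_session",
]

SCHEMA_VERSION = 1


class SchemaVersionError(ValueError):
    """The session document's schema version is missing or unsupported."""


# --- encoding ---------------------------------------------------------------

def _va(v: VisualAcuity | None):
    if v is None:
        return None
    return {"snellen_denominator": v.snellen_denominator, "below_floor": v.below_floor}


def _trial(t: AcuityTrial):
    return {"size": t.size, "pair_is_match": t.pair_is_match, "response_yes": t.response_yes}


def _acuity_outcome(o: AcuityOutcome):
    return {
        "eye": o.eye.value,
        "unaided": _va(o.unaided),
        "pinhole": _va(o.pinhole),
        "pinhole_required": o.pinhole_required,
        "unaided_trials": [_trial(t) for t in o.unaided_trials],
        "pinhole_trials": [_trial(t) for t in o.pinhole_trials],
    }


def _game(g: GameResult):
    return {
        "endpoint": g.endpoint,
        "trials": g.trials,
        "ceiling": g.ceiling,
        "crossings": list(g.crossings),
        "trace": [{"disparity": d, "chosen_eye": e.value, "timestamp": None} for d, e in g.trace],
    }


def _color_eye(c: ColorEyeResult):
    return {
        "eye": c.eye.value,
        "qualified": c.qualified,
        "errors_by_axis": {ax.value: n for ax, n in c.errors_by_axis.items()},
        "label": c.label,
        "responses": [[pid, ok] for pid, ok in c.responses],
    }


def session_to_dict(record: SubjectRecord) -> dict:
    extra = {
        name: {eye.value: _acuity_outcome(o) for eye, o in eyes.items()}
        for name, eyes in record.acuity_measures.items()
        if name != "ipad"
    }
    return {
        "schema_version": SCHEMA_VERSION,
        "subject_id": record.subject_id,
        "truth_label": record.truth_label,
        "seed": record.seed,
        "brightness": {
            "endpoints": list(record.brightness.endpoints),
            "label": record.brightness.label,
            "net_imbalance": record.brightness.net_imbalance,
            "games": [_game(g) for g in record.games],
        },
        "acuity": {eye.value: _acuity_outcome(record.acuity[eye]) for eye in Eye},
        "color": {
            "od": _color_eye(record.color_od),
            "os": _color_eye(record.color_os),
            "category": record.color_category,
        },
        "referred": record.referred,
        "referral_reasons": list(record.referral_reasons),
        "extra_acuity_measures": extra,
    }


# --- decoding ---------------------------------------------------------------

def _va_from(d):
    if d is None:
        return None
    return VisualAcuity(d["snellen_denominator"], d["below_floor"])


def _trial_from(d):
    return AcuityTrial(d["size"], d["pair_is_match"], d["response_yes"])


def _acuity_outcome_from(d):
    return AcuityOutcome(
        eye=Eye(d["eye"]),
        unaided=_va_from(d["unaided"]),
        pinhole=_va_from(d["pinhole"]),
        pinhole_required=d["pinhole_required"],
        unaided_trials=[_trial_from(t) for t in d["unaided_trials"]],
        pinhole_trials=[_trial_from(t) for t in d["pinhole_trials"]],
    )


def _game_from(d):
    return GameResult(
        endpoint=d["endpoint"],
        trials=d["trials"],
        ceiling=d["ceiling"],
        crossings=tuple(d["crossings"]),
        trace=tuple((t["disparity"], Eye(t["chosen_eye"])) for t in d["trace"]),
    )


def _color_eye_from(d):
    return ColorEyeResult(
        eye=Eye(d["eye"]),
        qualified=d["qualified"],
        errors_by_axis={ColorAxis(ax): n for ax, n in d["errors_by_axis"].items()},
        label=d["label"],
        responses=[(pid, ok) for pid, ok in d["responses"]],
    )


def session_from_dict(doc: dict) -> SubjectRecord:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported session schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    acuity = {Eye(k): _acuity_outcome_from(v) for k, v in doc["acuity"].items()}
    record = SubjectRecord(
        subject_id=doc["subject_id"],
        truth_label=doc["truth_label"],
        brightness=BrightnessClassification(
            endpoints=tuple(doc["brightness"]["endpoints"]),
            label=doc["brightness"]["label"],
            net_imbalance=doc["brightness"]["net_imbalance"],
        ),
        games=[_game_from(g) for g in doc["brightness"]["games"]],
        acuity=acuity,
        color_od=_color_eye_from(doc["color"]["od"]),
        color_os=_color_eye_from(doc["color"]["os"]),
        color_category=doc["color"]["category"],
        referred=doc["referred"],
        referral_reasons=list(doc["referral_reasons"]),
        seed=doc["seed"],
    )
    record.acuity_measures["ipad"] = acuity
    for name, eyes in doc.get("extra_acuity_measures", {}).items():
        record.acuity_measures[name] = {
            Eye(k): _acuity_outcome_from(v) for k, v in eyes.items()
        }
    return record


def write_session(record: SubjectRecord, path) -> Path:
    """Write one subject's session document; returns the path written."""
    path = Path(path)
    path.write_text(json.dumps(session_to_dict(record), indent=2, sort_keys=True) + "\n")
    return path


def read_session(path) -> SubjectRecord:
    """Read a session document back into a :class:`SubjectRecord`."""
    with open(path) as f:
        return session_from_dict(json.load(f))
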
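"""Bland–Altman agreement between two acuity measures.

Two measurement methods applied to the same eyes are compared through the
paired differences ``first - second`` (in logMAR): the mean difference
``d`` estimates the bias between the methods, and, for approximately
normal differences, about 95% of them fall within the limits of agreement
``d ± 2·SD``. The 2·SD multiplier (rather than 1.96) follows the original
formulation of the method and is configurable.

Eyes, not subjects, are the pairing unit; within-subject correlation
between fellow eyes is ignored. Eyes recorded below the chart floor
("worse than 20/400") have no numeric logMAR and are excluded from pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Eye, round_percent

__all__ = [
    "AgreementResult",
    "bland_altman",
    "percent_improvement",
    "agreement_from_sessions",
]


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of paired differences (logMAR)."""

    n: int
    d: float               # mean difference first - second
    sd: float              # sample SD of the differences (n-1 denominator)
    lower: float           # d - multiplier * sd
    upper: float           # d + multiplier * sd
    excluded: int = 0      # pairs dropped (below-floor or missing)


def bland_altman(first, second, sd_multiplier: float = 2.0) -> AgreementResult:
    """Limits of agreement between two paired series of logMAR acuities.

    ``d`` is the mean of ``first - second``; ``sd`` the sample standard
    deviation of the differences; the limits are ``d ± sd_multiplier·sd``.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("bland_altman needs two equal-length 1-d series")
    if a.size < 2:
        raise ValueError("bland_altman needs at least two pairs")
    diffs = a - b
    d = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementResult(
        n=int(a.size),
        d=d,
        sd=sd,
        lower=d - sd_multiplier * sd,
        upper=d + sd_multiplier * sd,
    )


def percent_improvement(before: float, after: float, decimals: int = 0) -> float:
    """Relative improvement ``100·(before - after)/before`` as a rounded
    percentage (e.g. mean logMAR 0.11 unaided vs 0.05 with pinhole -> 55)."""
    if before <= 0:
        raise ValueError("percent_improvement needs a positive 'before' value")
    return round_percent(before - after, before, decimals)


def _extract(outcome, pinhole: bool):
    va = outcome.pinhole if (pinhole and outcome.pinhole is not None) else outcome.unaided
    return None if va.below_floor else va.logmar


def agreement_from_sessions(
    records,
    measure_a: str,
    measure_b: str,
    pinhole: bool = False,
    sd_multiplier: float = 2.0,
) -> AgreementResult:
    """Bland–Altman agreement between two named acuity measures stored on
    screening records, pairing by eye.

    With ``pinhole`` the pinhole measurement is used where one was taken
    (falling back to the unaided value for eyes that never needed the
    retest). Eyes below the chart floor in either measure are excluded and
    counted in ``excluded``.
    """
    firsts, seconds, excluded = [], [], 0
    for record in records:
        for eye in Eye:
            try:
                out_a = record.acuity_measures[measure_a][eye]
                out_b = record.acuity_measures[measure_b][eye]
            except KeyError:
                excluded += 1
                continue
            va_a = _extract(out_a, pinhole)
            va_b = _extract(out_b, pinhole)
            if va_a is None or va_b is None:
                excluded += 1
                continue
            firsts.append(va_a)
            seconds.append(va_b)
    if len(firsts) < 2:
        raise ValueError("fewer than two usable eye pairs for agreement analysis")
    result = bland_altman(firsts, seconds, sd_multiplier)
    return AgreementResult(
        n=result.n, d=result.d, sd=result.sd,
        lower=result.lower, upper=result.upper, excluded=excluded,
    )
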
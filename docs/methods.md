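# Methods

This note documents the models behind the protocol engines, the
conventions the package commits to where the clinical procedure leaves
room, and what the simulations do and do not show about real screening.

## Units and reporting conventions

Acuity is handled as Snellen fractions 20/x and as logMAR
(`log10(x/20)`); conversions round-trip exactly on chart lines. Acuity
worse than the largest presentable optotype is recorded as "worse than
20/400" with an explicit below-floor flag rather than a sentinel number,
so statistics must consciously exclude or cap such eyes (the Bland–Altman
layer excludes them and reports the count).

All rates (sensitivity, specificity, prevalence, percent improvement)
are percentages rounded **half away from zero** at integer precision by
default. This single convention reproduces standard clinical-report
arithmetic (1/121 → 0.83% at two decimals; 2/204 → 1%).

The chart ladder defaults to the standard Snellen progression
400, 200, 100, 80, 60, 50, 40, 30, 25, 20. Only the endpoints, the 20/60
start line and the 20/30 pinhole cutoff are fixed by the protocol;
intermediate lines follow common clinical charts and are configurable.

## Brightness-rivalry staircase

**Stimulus model.** Disparities live on a grid of `step` = 0.3 log-unit
increments over ±`max_disparity` = 1.8, positive = right-eye ship
physically brighter. Levels are integers internally, so grid arithmetic
is exact in floating point.

**Transition rule.** One fixed-size step against the chosen eye per
response, clamped at the grid edges. A reversal ("crossing") is recorded
whenever consecutive responses choose opposite eyes; the game ends after
two crossings, or at a hard trial budget of
`2·(2·max/step + 1)·crossings` (52 at defaults) that guarantees
termination for arbitrary response sequences. The budget path flags the
result as a ceiling measurement and reports the clamped extreme.

**Endpoint rule.** Each crossing brackets the perceived-equality point
between two consecutively presented levels. The endpoint is minus the
mean of the bracket midpoints, snapped to the step grid with ties toward
zero, reported with positive sign = left-eye (OS) deficit. Combined with
the observer tie rule below, this recovers any on-grid attenuation
*exactly*, from every start level: a noiseless observer overshoots the
equality level by one step on each approach, so the two brackets sit
symmetrically around it and their midpoints average to the true value.
Snapping to the full step grid also makes the endpoint robust to the
half-step jitter that near-equality guessing produces in noisy
observers.

**Start level.** Games start at the +1.8 extreme (an extreme start makes
the first crossing informative), with the sign alternating +/−/+ across
the three games of a session to cancel starting-side bias.

**Session rule.** "Net zero imbalance in two of three games" is scored,
by default, as: balanced iff at least two endpoints are exactly zero *or*
the nonzero endpoints disagree in sign. The sign-discordance clause is
required for the alternating-ocular-preference pattern of a treated
amblyope (endpoints 0.3 OS / 0.3 OD / 0.0) to count as balanced — no
single eye shows a consistent deficit. A stricter signed-sum reading
(`balance_rule="net-sum"`) is available behind the configuration switch.

## Observer model

Brightness perception is additive attenuation in log luminance per eye:
the perceived offset of a stimulus with physical disparity `d` is
`d + (δ_OS − δ_OD)`. This is the minimal model consistent with
log-unit-valued equality endpoints. Noiseless observers choose the
physically-perceived-brighter ship; at exact perceived equality they
repeat their previous choice (first trial: right). With decision noise
σ > 0 the right eye is chosen with probability `logistic(perceived/σ)`.

Acuity thresholds split per eye into a **neural** component (not
correctable by pinhole — the amblyopic deficit) and a **refractive**
component (≥ 0, removed entirely by the pinhole). A response is correct
iff the letter's logMAR is at or above the eye's effective threshold
(with a 0.005 tolerance so a nominal 0.3 threshold passes the 20/40
line, exactly logMAR 0.30103). Below threshold, a noiseless observer is
always wrong — this keeps the whole protocol seed-independent and makes
the recorded acuity equal the closed form "smallest chart line at or
above threshold" for every seed — while an observer with any decision
noise guesses at the 50% chance level of the YES/NO matching task, which
is what makes line-to-line measurement variability (and the 20/400
failure path under guessing) reachable. There is no psychometric slope
between lines; that is a documented simplification.

Colour vision is a per-eye confusion axis (none / red-green / tritan).
The observer misses shape-present plates on the defective axis with
probability 1 by default and answers everything else correctly;
demonstration plates are always answered correctly except by the
explicit "unable" archetype.

## Acuity protocol conventions

* **Second chance.** The first error at a size opens up to three further
  pairs at that size; reaching three corrects at the size (counting those
  before the error) advances, a second error ends the run. Since at most
  three corrects are ever outstanding, the second chance always resolves.
* **Restart.** A run that completes no line from its start size (default
  20/60) restarts once from 20/400; the recorded acuity is the smallest
  line completed across both runs. Completing no line at all records the
  below-floor value.
* **Pinhole.** Administered per eye, only when the unaided recorded
  acuity is 20/30 or worse (or below floor).

## Colour protocol conventions

The packaged plate set (4 demonstration plates, 14 red-green and
6 tritan test plates) mirrors the structure of the AO-HRR series; the
artwork is abstracted to (id, kind, axis) records and the counts are
configurable. Scoring: ≥ 2 errors on an axis labels the eye defective on
that axis (errors above threshold on both axes are labelled by the worse
axis, ties to red-green). Identical bilateral defects classify as
hereditary, a strictly monocular defect as acquired; discordant
bilateral defects get their own category rather than being forced into
either. Only the acquired (monocular) pattern contributes to referral.

## Screening and evaluation

Referral reasons, each independently sufficient: brightness session
imbalanced; post-pinhole acuity worse than 20/30 in either eye; monocular
colour defect. The packaged 204-subject cohort contains 202 subjects
without brightness imbalance and two unilateral amblyopes (attenuations
0.3 and 0.6 log units OS; the second with a pinhole-resistant 20/40 OS
and an acquired tritan defect OS). Treated amblyopes carry a non-target
truth label for unilateral-amblyopia detection: their alternating
preference pattern classifies balanced by design. With noiseless
observers and every amblyope attenuated by at least one grid step,
brightness-only screening is error-free for every seed — a theorem of
the model (the staircase recovers on-grid attenuations exactly), not an
empirical claim about children.

Bland–Altman agreement uses eyes, not subjects, as the pairing unit and
ignores within-subject correlation between fellow eyes. Limits are
d ± 2·SD with the sample (n−1) standard deviation; the multiplier is
configurable. Published summaries of this analysis are typically printed
from unrounded intermediates, so the package validates printed-summary
arithmetic (reconstructing limits from given d and SD) rather than
unavailable raw data.

## Simulation scales and the noise sweep

The test suite and the acceptance script run the full 204-subject cohort
(all three protocols per subject, ~2 s), a 63-subject / 126-eye method
comparison for agreement, and a decision-noise sweep of 5 noise levels ×
300 seeded normal observers. The sweep grid spans σ = 0.05–0.3 log
units, i.e. up to the staircase step size: in that operating regime
specificity degrades monotonically as noise blurs the equality point.
Well beyond the step size the sign-discordance session rule turns the
curve back up — random sessions increasingly produce discordant
endpoints, which score as balanced — so the monotone-degradation
property is stated, and tested, for the sub-step regime.

## Known limitations

* No psychometric slopes: responses are step functions of threshold
  (plus optional chance-level guessing), so simulated variability is
  coarser than real children's.
* No attention lapses, learning, fatigue or response-time modelling; the
  observed testing-time distributions of a live screening are out of
  scope.
* Brightness attenuation is additive in log luminance and constant
  across the session; real suppression can be stimulus-dependent.
* The plate set is structural only; colourimetry, severity grading and
  other plate systems (Ishihara) are not modelled.
* Passing simulations demonstrate internal consistency of the protocols
  and their analysis, not field performance on real children.
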
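# rivalscreen

Simulation engines for tablet-based paediatric vision screening.

Unilateral amblyopia ("lazy eye") is the leading cause of permanent vision
loss in children, and most instrument-based screeners detect its *risk
factors* (refractive error, strabismus) rather than the condition itself.
A screening battery that children can self-administer as a game on a
tablet measures amblyopia more directly through three tests:

1. **Interocular brightness rivalry** — through crossed polarizers each
   eye sees only one of two spaceships; the child taps the brighter one.
   The physical log-brightness offset between the ships is driven by an
   adaptive staircase (steps of 0.3 log units over ±1.8) until the child's
   responses cross and re-cross the perceived-equality point. The signed
   per-game endpoint estimates the interocular brightness disparity, and a
   child passes when two of three games come out at net zero. A
   consistent one-eye brightness deficit is the amblyopia signal.
2. **Tumbling-E acuity** — same/different matching of E pairs from 20/400
   down to 20/20; three correct responses advance a line, a second error
   at a line ends the run. Acuities of 20/30 or worse are re-tested
   through a pinhole, which removes refractive blur: only loss that
   *resists* the pinhole suggests amblyopia.
3. **HRR-style colour plates** — per-eye red-green / blue-yellow testing
   with demonstration-plate qualification; a defect confined to one eye
   suggests an acquired (e.g. amblyopic) cause.

This package re-implements the three protocols as deterministic, seedable
state machines, adds generative simulated observers (normal children,
unilateral amblyopes with pinhole-resistant loss, pure refractive errors,
treated amblyopes with alternating ocular preference, colour-defect
subjects), and an evaluation layer — sensitivity/specificity of referral
rules against cohort truth labels, and Bland–Altman limits of agreement
(d ± 2·SD of paired logMAR differences) between acuity measures — so the
whole screening method can be exercised and validated end to end without
human subjects.

## Worked example

A simulated undetected amblyope (left-eye brightness attenuation 0.6 log
units, pinhole-resistant 20/40 OS):

```text
$ rivalscreen brightness --attenuation 0.6 --eye OS --seed 7
seed: 7
game 1: endpoint +0.60 log units (12 trials)
game 2: endpoint +0.60 log units (8 trials)
game 3: endpoint +0.60 log units (12 trials)
classification: imbalanced (net imbalance +0.60)
```

Each game's staircase reverses twice around the same point: a +0.60
log-unit endpoint means the left eye needs a 0.6 log-unit brightness
advantage before the two ships look equal — a left-eye deficit. Fewer
than two games at net zero, all deficits on the same side: the session is
classified imbalanced and the child would be referred.

```text
$ rivalscreen acuity --threshold-os 0.3 --seed 7
seed: 7
OD: unaided 20/20
OS: unaided 20/40, pinhole 20/40
```

The left eye reads only the 20/40 line (logMAR 0.3); because that is
worse than 20/30 the protocol retests through the pinhole, and the
unchanged 20/40 marks the loss as non-refractive. The same subject run
through the full battery:

```text
$ rivalscreen screen --archetype amblyope --seed 7
brightness: imbalanced (endpoints [0.6, 0.6, 0.6])
acuity OD: 20/20
acuity OS: 20/40 -> pinhole 20/40
colour: normal
referred: True ['brightness-imbalance', 'subnormal-pinhole-acuity']
```

Whole cohorts are simulated and evaluated the same way (`rivalscreen
cohort`, `evaluate`, `agreement`, `report`), and every command echoes its
seed: identical invocations produce byte-identical session files.

The same functionality is available as a library:

```python
from rivalscreen import make_archetype, run_brightness_session, classify_brightness

observer = make_archetype("amblyope", delta=0.6, neural=0.3)
games = run_brightness_session(observer, seed=7)
print([g.endpoint for g in games])        # [0.6, 0.6, 0.6]
print(classify_brightness(games).label)   # imbalanced
```

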
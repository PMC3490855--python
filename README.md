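# rdksim

Simulated psychophysics of **motion transparency**: how motion noise turns
direction *repulsion* between two overlapping moving dot fields into
direction *attraction*.

When two random-dot patches drift through the same aperture in different
directions, observers see two transparent motion sheets whose angular
separation looks **wider** than it is (direction repulsion). As motion
coherence drops — a growing fraction of dots moving in random directions —
the perceived separation shrinks, crosses the veridical value near 80%
coherence, and becomes **narrower** than veridical (direction attraction).
`rdksim` packages that entire experimental logic as tested, reproducible
simulation code: no human subjects, no downloads.

## What is in the box

* **Stimuli** (`rdksim.stimulus`) — two overlapping random-dot patches in a
  7.5° aperture (3.4 dots/deg² per patch, 5°/s, 100 Hz, 3 s, unlimited dot
  lifetime with antipodal wrap-around), per-patch coherence *c*, component
  directions 90° ± Δ/2; plus the static two-line comparison stimulus.
* **Synthetic observers** (`rdksim.observer`) — a parametric observer whose
  mean percept is

  ```
  perceived(Δ, c) = Δ · (1 + b(c) · R(Δ))
  ```

  with a signed coherence gain `b(c)` (zero at the 80%-coherence crossover,
  positive above, negative below) and a unimodal separation-tuning profile
  `R(Δ)` peaking at Δ* = 25°; the attraction branch keeps a low-level floor
  at large Δ. A population observer — direction-tuned channels with broad
  mutual inhibition and a noise-dependent segmentation→integration shift —
  demonstrates the same sign pattern mechanistically.
* **Staircase engine** (`rdksim.staircase`) — the adaptive 1-up/1-down
  matching procedure: 3° steps, seven reversals to stop, matching angle =
  mean of the last four reversal angles, zero-floor rule for merged
  percepts.
* **Experiment designs** (`rdksim.experiment`) — Experiment 1
  (Δ ∈ {30°, 60°} × coherence 50–100%) and Experiment 2
  (coherence ∈ {60%, 100%} × Δ from 15° to 120°), four subjects × four
  staircases per condition, fully seeded.
* **Statistics** (`rdksim.analysis`) — perceived-minus-veridical differences
  and veridically normalized effects, one-way ANOVA, two-way
  repeated-measures ANOVA (subject-interaction error terms), and the
  Wilcoxon signed-rank test with an exact small-sample null distribution —
  all implemented from sums of squares / rank enumeration and cross-checked
  against independent oracles in the tests.

## Worked example

A single staircase at 30° separation and 60% coherence:

```bash
$ rdksim staircase --delta 30 --coherence 0.6 --seed 7
matching angle: 15.50 deg (reversals_complete, 16 trials, 7 reversals)
```

The observer's mean percept in this condition is ≈16°: strong attraction
(the veridical separation is 30°), recovered by the staircase in a
human-realistic 16 trials.

A full Experiment-2-style study from the library:

```python
import rdksim as r
from rdksim.experiment import default_cohort

cohort = default_cohort(4, seed=1)
dataset = r.run_experiment(r.design_experiment2(), cohort, seed=2)
report = r.experiment2_report(dataset)
```

Selected per-condition means (± SE across the 4 simulated subjects):

```
 Δ (deg)  coherence  perceived (deg)  normalized effect
    25       0.6          9.6 ± 0.6       -0.62
    25       1.0         37.9 ± 0.5       +0.51
    30       0.6         14.9 ± 0.6       -0.50
    30       1.0         42.1 ± 0.4       +0.40
   120       0.6        108.0 ± 0.3       -0.10
   120       1.0        123.2 ± 0.4       +0.03
```

Repulsion at full coherence, attraction at 60%, both strongest near 25° and
declining with separation — with attraction retaining a low-level effect at
120° where repulsion is minimal. The analysis battery prints:

```
coherence: F(1,3) = 1.51e+03, p = 3.8e-05
direction_separation: F(7,21) = 0.275, p = 0.96
coherence x direction_separation: F(7,21) = 253, p = 8.1e-19
median attraction magnitude: 13.7 deg; signed-rank p = 8.3e-07
```

i.e. a significant coherence main effect and coherence × separation
interaction, and no pooled separation effect (the normalized attraction and
repulsion profiles mirror each other).

The same pipeline is available from the shell:

```bash
rdksim simulate --design exp2 --seed 2 --out results/
rdksim analyze --dataset results/experiment2_seed2.csv
rdksim figures --dataset results/experiment2_seed2.csv --out results/
```

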
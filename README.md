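# songctx

Analysis of **learned contextual control over birdsong syllable
sequencing** — for researchers studying how songbirds (e.g. Bengalese
finches) adapt the probabilities of alternative syllable sequences to
arbitrary sensory cues.

In the underlying paradigm, a bird whose song branches variably (say
"ab-c" vs "ab-d") experiences alternating blocks of colored light; in each
context a different target sequence triggers aversive white noise (WN),
and interleaved *probe* blocks present the cues without reinforcement.
`songctx` takes annotated song bouts organized in such context blocks and
quantifies:

- **sequence probability** per bout, block and day:
  p = n_Y / (n_Y + n_G) over renditions of the two targets, with the
  normal-approximation CI p ± 1.96·√(p(1−p)/n);
- **switch-triggered shifts**: admissible context switches (same-day,
  songless blocks merged, silent double-switches discarded) and the shift
  magnitude, mean(first 5 post bouts) − mean(last 5 pre bouts);
- **acquisition dynamics**: per-switch OLS fits of the post-switch
  trajectory — intercept = immediate cue-driven shift, slope =
  within-block learning rate — and their trends over training, which
  dissociate the two adaptation processes;
- **transition-matrix structure**: collapsed first-order transition
  matrices per context (intro / repeat / chunk states), branch points
  (outgoing probabilities strictly inside 3–97%), the green−yellow
  difference matrix, **branch-point specificity** (the share of absolute
  contextual difference at branch points that falls on the branch point(s)
  immediately preceding the targets) and **transition entropy**
  H = Σ_x p(x) Σ_y −p(y|x) log₂ p(y|x);
- a **synthetic experiment generator** that simulates the full protocol —
  block schedules, song emission from a transition diagram, imperfect WN
  targeting, and a two-process learning model (saturating immediate shift
  + capped within-block drift) — with per-bout ground truth, so every
  estimator is validated by parameter recovery.

## Worked example

Simulate a trained bird (immediate shift saturated at ±0.25 around
p₀ = 0.5, no within-block drift) and measure the shifts:

```python
from songctx import (LearningDynamics, ScheduleConfig, default_diagram,
                     simulate_experiment, extract_switches, shift_magnitude)
import numpy as np

log, truth = simulate_experiment(
    default_diagram(),
    LearningDynamics(delta_max=0.25, tau_blocks=1e-9, s_within=0.0),
    ScheduleConfig(n_days=12), seed=3)
switches = extract_switches(log)
for color in ("green", "yellow"):
    shifts = [e.delta_p for e in (shift_magnitude(s) for s in switches
              if s.to_block.color == color) if e is not None]
    print(color, len(shifts), round(float(np.mean(shifts)), 3))
```

prints

```
green 61 0.476
yellow 63 -0.483
```

i.e. the pipeline recovers the generated two-context separation of
2·delta_max = 0.5: shifts into green are positive (the yellow target
escapes WN there, its probability rises) and shifts into yellow negative.
The narrative scripts in `examples/` walk through each capability —
generation, probabilities and CIs, switch-triggered averages, the
two-process dissociation, and transition-matrix specificity/entropy — each
printing the numbers it computes and what they mean.

A thin CLI covers the same pipeline for shell use:

```bash
songctx generate --seed 1 --out run1        # song log + ground truth
songctx analyze  --log run1/log --out rep1  # tables + summary.json
songctx recover  --data run1                # bias/RMSE vs ground truth
```

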
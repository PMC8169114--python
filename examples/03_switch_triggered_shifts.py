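"""Switch-triggered averages and shift magnitudes in a trained bird.

Extracts admissible context switches (same-day, songless blocks merged,
silent double switches discarded), then measures the immediate probability
shift at the light change: mean of the first five post-switch bouts minus
mean of the last five pre-switch bouts.
"""

import numpy as np

from songctx import (
    LearningDynamics,
    ScheduleConfig,
    default_diagram,
    extract_switches,
    shift_magnitude,
    simulate_experiment,
    switch_triggered_average,
)

log, _ = simulate_experiment(
    default_diagram(),
    LearningDynamics(delta_max=0.25, tau_blocks=1e-9, s_within=0.0),
    ScheduleConfig(n_days=12),
    seed=3,
)

switches = extract_switches(log)
print(f"admissible switches: {len(switches)}")

for to_color in ("green", "yellow"):
    sel = [s for s in switches if s.to_block.color == to_color]
    shifts = [e.delta_p for e in map(shift_magnitude, sel) if e is not None]
    print(f"into {to_color}: n={len(shifts)} "
          f"mean shift = {np.mean(shifts):+.3f} "
          f"(SEM {np.std(shifts, ddof=1)/np.sqrt(len(shifts)):.3f})")

avg = switch_triggered_average(
    [s for s in switches if s.to_block.color == "yellow"]
)
i0 = avg.positions.index(0)
print("switch-triggered average into yellow, positions -3..2:",
      [round(m, 3) for m in avg.mean[i0 - 3 : i0 + 3]])

# With a saturated immediate shift of 0.25 per context the shift into green
# is about +0.50 and into yellow about -0.50 (the two contexts sit at
# p = 0.75 and p = 0.25); the aligned average steps abruptly at position 0.
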
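"""Simulate a context-dependent sequencing experiment with known truth.

Builds a ten-day training protocol for a synthetic Bengalese finch —
alternating green/yellow light blocks with ~1/3 probe blocks, white-noise
(WN) reinforcement of one target sequence per context, and a two-process
learning model — then prints what was generated.
"""

from songctx import (
    LearningDynamics,
    ScheduleConfig,
    default_diagram,
    simulate_experiment,
)

dyn = LearningDynamics(p0=0.5, delta_max=0.25, tau_blocks=20.0, s_within=0.005)
cfg = ScheduleConfig(n_days=10)
log, truth = simulate_experiment(default_diagram(), dyn, cfg, seed=42)

n_probe = sum(b.block_type == "probe" for b in log.blocks)
print(f"bouts: {len(log.bouts)}  blocks: {len(log.blocks)} "
      f"({n_probe} probe)")
print(f"first bout: {''.join(log.bouts[0].labels)}")
print(f"targets: yellow={''.join(log.targets.target_y)} "
      f"green={''.join(log.targets.target_g)}")
print(f"true branch probability spans "
      f"{min(truth.p_true):.3f}-{max(truth.p_true):.3f}")

# The first bout is a raw syllable string (intro notes, chunk 'aab', then
# the variable branch to 'c' or 'd').  The true probability of the
# yellow-target branch starts at p0 = 0.5 and spreads apart between
# contexts as the simulated bird learns the light cues.
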
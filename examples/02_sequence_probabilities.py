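"""Per-bout and pooled sequence probabilities with confidence intervals.

Sequence probability is the within-bout share of the yellow target among
all target renditions, p = n_Y / (n_Y + n_G); pooled estimates carry a
normal-approximation 95% CI.
"""

from songctx import (
    LearningDynamics,
    ScheduleConfig,
    bout_probability,
    default_diagram,
    pooled_probability,
    simulate_experiment,
)

log, _ = simulate_experiment(
    default_diagram(),
    LearningDynamics(delta_max=0.25, tau_blocks=1e-9),  # already trained
    ScheduleConfig(n_days=2),
    seed=7,
)

bout = log.bouts[0]
sp = bout_probability(bout, log.targets)
print(f"bout 0: labels={''.join(bout.labels)}")
print(f"  n_Y={sp.n_y} n_G={sp.n_g} -> p={sp.p:.3f}")

day0 = [b for b in log.bouts if b.day == 0]
pooled = pooled_probability(day0, log.targets)
print(f"day 0 pooled over {pooled.n} renditions: "
      f"p = {pooled.p:.3f} +- {pooled.ci_half_width:.3f} (95% CI)")

# The pooled day value sits near 0.5 because the day mixes green blocks
# (p pushed up to 0.75) and yellow blocks (pushed down to 0.25); the CI
# half-width shrinks as 1/sqrt(n renditions).
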
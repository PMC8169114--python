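import pytest

from songctx import (
    ContextBlock,
    LearningDynamics,
    ScheduleConfig,
    SongBout,
    SongLog,
    TargetPair,
    default_diagram,
    simulate_experiment,
)


def make_bout(bout_id, day, time_s, block_id, labels, wn_hits=None):
    return SongBout(
        bout_id=bout_id, day=day, time_s=time_s, labels=tuple(labels),
        block_id=block_id, wn_hits=wn_hits,
    )


@pytest.fixture
def targets():
    return TargetPair(target_y=tuple("abd"), target_g=tuple("abc"))


@pytest.fixture
def tiny_log(targets):
    """Two adjacent same-day blocks (green WN then yellow WN), 3+4 bouts."""
    blocks = [
        ContextBlock(0, 0, 0.0, 3600.0, "green", "wn", tuple("abc")),
        ContextBlock(1, 0, 3600.0, 7200.0, "yellow", "wn", tuple("abd")),
    ]
    bouts = [
        make_bout(0, 0, 100.0, 0, "iaabdaabd"),   # p = 1.0
        make_bout(1, 0, 200.0, 0, "iaabdaabc"),   # p = 0.5
        make_bout(2, 0, 300.0, 0, "iaabd"),       # p = 1.0
        make_bout(3, 0, 3700.0, 1, "iaabc"),      # p = 0.0
        make_bout(4, 0, 3800.0, 1, "iaabcaabd"),  # p = 0.5
        make_bout(5, 0, 3900.0, 1, "iaabc"),      # p = 0.0
        make_bout(6, 0, 4000.0, 1, "iaabc"),      # p = 0.0
    ]
    return SongLog(bouts=bouts, blocks=blocks, targets=targets)


@pytest.fixture(scope="session")
def trained_log():
    """Saturated two-process bird: immediate shift only, 6 days."""
    dyn = LearningDynamics(
        p0=0.5, delta_max=0.25, tau_blocks=1e-9, s_within=0.0
    )
    cfg = ScheduleConfig(n_days=6)
    log, truth = simulate_experiment(default_diagram(), dyn, cfg, seed=7)
    return log, truth


@pytest.fixture(scope="session")
def stationary_log():
    """No learning at all: every bout drawn at the baseline probability."""
    dyn = LearningDynamics(p0=0.5, delta_max=0.0, s_within=0.0)
    cfg = ScheduleConfig(n_days=6)
    log, truth = simulate_experiment(default_diagram(), dyn, cfg, seed=11)
    return log, truth
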
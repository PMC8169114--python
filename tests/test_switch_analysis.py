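import numpy as np
import pytest

from songctx import (
    ContextBlock,
    SongLog,
    acquisition_fits,
    acquisition_trends,
    display_smooth,
    extract_switches,
    shift_magnitude,
    switch_triggered_average,
)
from songctx.switch_analysis import SwitchEvent, bin_series
from tests.conftest import make_bout


def _block(bid, day, t0, t1, color, btype="wn", target="abc"):
    return ContextBlock(
        bid, day, t0, t1, color, btype,
        tuple(target) if btype == "wn" else None,
    )


def _bouts_for(block, n, labels, start_id):
    dt = block.duration_s / (n + 1)
    return [
        make_bout(start_id + k, block.day, block.start_s + (k + 1) * dt,
                  block.block_id, labels)
        for k in range(n)
    ]


def _log(blocks, bouts_spec, targets):
    """bouts_spec: list of (block, n_bouts, labels)."""
    bouts, i = [], 0
    for block, n, labels in bouts_spec:
        bs = _bouts_for(block, n, labels, i)
        bouts.extend(bs)
        i += n
    return SongLog(bouts=bouts, blocks=blocks, targets=targets)


class TestExtractSwitches:
    def test_simple_adjacent_switch(self, targets):
        g = _block(0, 0, 0.0, 100.0, "green")
        y = _block(1, 0, 100.0, 200.0, "yellow", target="abd")
        log = _log([g, y], [(g, 3, "iaabd"), (y, 4, "iaabc")], targets)
        sw = extract_switches(log)
        assert len(sw) == 1
        assert sw[0].switch_class == (("green", "wn"), ("yellow", "wn"))
        assert sw[0].pre_series == (1.0, 1.0, 1.0)
        assert sw[0].post_series == (0.0, 0.0, 0.0, 0.0)

    def test_songless_same_color_block_merged(self, targets):
        g1 = _block(0, 0, 0.0, 100.0, "green")
        gp = _block(1, 0, 100.0, 200.0, "green", btype="probe")
        g2 = _block(2, 0, 200.0, 300.0, "green")
        log = _log([g1, gp, g2], [(g1, 3, "iaabd"), (g2, 2, "iaabd")], targets)
        assert extract_switches(log) == []

    def test_merged_period_concatenates_series(self, targets):
        y = _block(0, 0, 0.0, 100.0, "yellow", target="abd")
        g1 = _block(1, 0, 100.0, 200.0, "green")
        gp = _block(2, 0, 200.0, 300.0, "green", btype="probe")
        g2 = _block(3, 0, 300.0, 400.0, "green")
        log = _log(
            [y, g1, gp, g2],
            [(y, 3, "iaabc"), (g1, 3, "iaabd"), (g2, 2, "iaabd")],
            targets,
        )
        sw = extract_switches(log)
        assert len(sw) == 1
        assert len(sw[0].post_series) == 5  # green period spans both blocks

    def test_double_silent_switch_discarded(self, targets):
        g1 = _block(0, 0, 0.0, 100.0, "green")
        y = _block(1, 0, 100.0, 200.0, "yellow", target="abd")
        g2 = _block(2, 0, 200.0, 300.0, "green")
        log = _log([g1, y, g2], [(g1, 3, "iaabd"), (g2, 3, "iaabd")], targets)
        assert extract_switches(log) == []

    def test_overnight_switch_excluded(self, targets):
        g = _block(0, 0, 0.0, 100.0, "green")
        y = _block(1, 1, 86400.0, 86500.0, "yellow", target="abd")
        log = _log([g, y], [(g, 3, "iaabd"), (y, 3, "iaabc")], targets)
        assert extract_switches(log) == []

    def test_class_filter(self, trained_log):
        log, _ = trained_log
        wanted = {
            (("green", "probe"), ("yellow", "probe")),
            (("yellow", "probe"), ("green", "probe")),
        }
        sw = extract_switches(log, class_filter=wanted)
        assert sw and all(s.switch_class in wanted for s in sw)

    def test_switch_indices_are_training_ordinals(self, trained_log):
        log, _ = trained_log
        sw = extract_switches(log)
        assert [s.switch_index for s in sw] == list(range(len(sw)))


class TestShiftMagnitude:
    def _sw(self, pre, post):
        g = _block(0, 0, 0.0, 1.0, "green")
        y = _block(1, 0, 1.0, 2.0, "yellow", target="abd")
        return SwitchEvent(g, y, 0, tuple(pre), tuple(post))

    def test_five_bout_windows(self):
        est = shift_magnitude(self._sw([0.8] * 5, [0.3] * 5))
        assert est.delta_p == pytest.approx(-0.5)
        assert est.first_last_delta == pytest.approx(-0.5)

    def test_window_shrinks_to_available(self):
        est = shift_magnitude(self._sw([0.6, 0.7, 0.8], [0.2, 0.4, 0.3]))
        assert est.delta_p == pytest.approx(0.3 - 0.7)
        assert (est.n_pre, est.n_post) == (3, 3)

    def test_window_takes_last_pre_first_post(self):
        est = shift_magnitude(
            self._sw([0.0] * 5 + [1.0] * 5, [1.0] * 5 + [0.0] * 5)
        )
        assert est.delta_p == pytest.approx(0.0)

    def test_too_few_bouts_absent(self):
        assert shift_magnitude(self._sw([0.6, 0.7], [0.2, 0.4, 0.3])) is None


class TestSwitchTriggeredAverage:
    def _sw(self, pre, post):
        g = _block(0, 0, 0.0, 1.0, "green")
        y = _block(1, 0, 1.0, 2.0, "yellow", target="abd")
        return SwitchEvent(g, y, 0, tuple(pre), tuple(post))

    def test_identical_switches(self):
        sw = self._sw([0.8, 0.7], [0.2, 0.3])
        avg = switch_triggered_average([sw, sw])
        assert avg.positions == (-2, -1, 0, 1)
        assert avg.mean == (0.8, 0.7, 0.2, 0.3)
        assert avg.sem == (0.0, 0.0, 0.0, 0.0)

    def test_half_support_truncation(self):
        sws = [
            self._sw([0.5], [0.1, 0.2]),
            self._sw([0.5], [0.1, 0.2]),
            self._sw([0.5], [0.1] * 9),
            self._sw([0.5], [0.1] * 9),
        ]
        avg = switch_triggered_average(sws, min_fraction=0.5)
        # post positions 0-1 from all four, 2-8 from exactly half
        assert avg.positions == (-1,) + tuple(range(9))
        assert avg.n[1:] == (4, 4) + (2,) * 7

    def test_alignment_pre_indices_count_backwards(self):
        avg = switch_triggered_average([self._sw([0.1, 0.9], [0.4])])
        assert avg.at(-1) == 0.9 and avg.at(-2) == 0.1 and avg.at(0) == 0.4


class TestAcquisition:
    def _sw(self, color_to, pre, post, idx=0):
        a = _block(0, 0, 0.0, 1.0, "green" if color_to == "yellow" else "yellow")
        b = _block(1, 0, 1.0, 2.0, color_to,
                   target="abd" if color_to == "yellow" else "abc")
        return SwitchEvent(a, b, idx, tuple(pre), tuple(post))

    def test_exact_linear_curve(self):
        post = [0.1 + 0.01 * k for k in range(10)]
        fits = acquisition_fits([self._sw("green", [0.0, 0.0], post)])
        assert fits[0].intercept == pytest.approx(0.1)
        assert fits[0].slope == pytest.approx(0.01)

    def test_inversion_for_switches_into_yellow(self):
        # decreasing probability into yellow is adaptive -> positive after
        # inversion
        post = [0.4 - 0.02 * k for k in range(6)]
        fits = acquisition_fits([self._sw("yellow", [0.8, 0.8], post)])
        assert fits[0].intercept == pytest.approx(0.4)  # -(0.4 - 0.8)
        assert fits[0].slope == pytest.approx(0.02)

    def test_short_post_series_skipped(self):
        fits = acquisition_fits([self._sw("green", [0.5], [0.5])])
        assert fits == []

    def test_trends_constant_fits(self):
        sws = [self._sw("green", [0.0, 0.0], [0.2, 0.2, 0.2], idx=k)
               for k in range(5)]
        tr = acquisition_trends(acquisition_fits(sws))
        assert tr.slope_of_intercepts == pytest.approx(0.0)
        assert tr.slope_of_slopes == pytest.approx(0.0)

    def test_trends_growing_intercepts(self):
        sws = [
            self._sw("green", [0.0, 0.0],
                     [0.01 * k, 0.01 * k, 0.01 * k], idx=k)
            for k in range(10)
        ]
        tr = acquisition_trends(acquisition_fits(sws))
        assert tr.slope_of_intercepts == pytest.approx(0.01)
        assert tr.slope_of_slopes == pytest.approx(0.0, abs=1e-12)

    def test_trends_need_three_fits(self):
        fits = acquisition_fits(
            [self._sw("green", [0.0], [0.1, 0.2]) for _ in range(2)]
        )
        with pytest.raises(ValueError):
            acquisition_trends(fits)

    def test_slope_recovery_from_generator(self, targets):
        # within-block drift of 0.005/bout, no immediate shift, long blocks
        from songctx import LearningDynamics, ScheduleConfig, default_diagram, simulate_experiment
        dyn = LearningDynamics(p0=0.5, delta_max=0.0, s_within=0.005, l_max=0.4)
        cfg = ScheduleConfig(
            interval_bounds_s=(5400.0, 7200.0), n_days=30, probe_fraction=0.0
        )
        log, _ = simulate_experiment(default_diagram(), dyn, cfg, seed=21)
        fits = acquisition_fits(extract_switches(log))
        assert len(fits) >= 100
        mean_slope = float(np.mean([f.slope for f in fits]))
        assert mean_slope == pytest.approx(0.005, abs=0.002)


class TestDisplaySmoothing:
    def test_constant_series_unchanged(self):
        out = display_smooth([0.4] * 30, boxcar=9)
        assert np.allclose(out, 0.4)

    def test_interior_impulse_mass_preserved(self):
        y = np.zeros(30)
        y[15] = 1.0
        out = display_smooth(y, boxcar=9)
        spread = np.flatnonzero(out)
        assert len(spread) == 9
        assert out.sum() == pytest.approx(1.0)

    def test_bins_of_seven(self):
        assert len(bin_series(np.arange(14.0), 7)) == 2
        assert bin_series(np.arange(14.0), 7)[0] == pytest.approx(3.0)
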
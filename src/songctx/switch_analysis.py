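"""Context switches: extraction, shift magnitudes, acquisition dynamics.

A *context switch* is the boundary between two adjacent light blocks on the
same day.  Admissibility rules, applied in order:

1. a block in which the bird produced no song is merged into an adjacent
   block of the same color (the switch is invisible to the bird);
2. if the light switched two or more times with no intervening song, those
   switches are discarded;
3. overnight (day-boundary) switches are excluded — a day starting with the
   previous day's closing color is treated as a separate context.

*Shift magnitude* is the mean sequence probability over the first five bouts
of the new block minus the mean over the last five bouts of the old block;
switches need at least three bouts on each side, and the five-bout window
shrinks to what is available.  Acquisition is quantified by per-switch
linear fits to the post-switch bout series (after inverting switches into
yellow so the adaptive direction is positive, and subtracting the pre-switch
mean): the intercept estimates the immediate cue-driven shift, the slope the
within-block learning rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_stats import bout_probability
from .song_data import ContextBlock, SongLog, TargetPair

__all__ = [
    "SwitchEvent",
    "ShiftEstimate",
    "AcquisitionFit",
    "AcquisitionTrends",
    "AlignedAverage",
    "extract_switches",
    "shift_magnitude",
    "switch_triggered_average",
    "acquisition_fits",
    "acquisition_trends",
    "display_smooth",
    "bin_series",
]


@dataclass(frozen=True)
class SwitchEvent:
    """An admissible transition between two adjacent same-day blocks."""

    from_block: ContextBlock
    to_block: ContextBlock
    switch_index: int
    pre_series: tuple[float, ...]   # time order, ending at the switch
    post_series: tuple[float, ...]  # time order, starting at the switch
    pre_bout_ids: tuple[int, ...] = ()
    post_bout_ids: tuple[int, ...] = ()

    @property
    def switch_class(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (
            (self.from_block.color, self.from_block.block_type),
            (self.to_block.color, self.to_block.block_type),
        )

    @property
    def day(self) -> int:
        return self.to_block.day


@dataclass(frozen=True)
class ShiftEstimate:
    """Signed probability shift at one switch."""

    delta_p: float
    n_pre: int
    n_post: int
    first_last_delta: float


@dataclass(frozen=True)
class AcquisitionFit:
    """Per-switch OLS fit of normalized probability vs post-bout index."""

    intercept: float
    slope: float
    switch_index: int
    direction_normalized: bool = True


@dataclass(frozen=True)
class AcquisitionTrends:
    """Linear trends of per-switch intercepts and slopes over training."""

    slope_of_intercepts: float
    se_of_intercept_trend: float
    slope_of_slopes: float
    se_of_slope_trend: float


@dataclass(frozen=True)
class AlignedAverage:
    """Switch-triggered mean +- SEM at aligned bout positions.

    Positions are negative for pre-switch bouts (-1 = last bout before the
    switch) and non-negative for post-switch bouts (0 = first bout after).
    """

    positions: tuple[int, ...]
    mean: tuple[float, ...]
    sem: tuple[float, ...]
    n: tuple[int, ...]

    def at(self, position: int) -> float:
        return self.mean[self.positions.index(position)]


def _merge_songless(
    blocks: list[ContextBlock], has_song: dict[int, bool]
) -> tuple[list[ContextBlock], set[tuple[int, int]]]:
    """Apply the songless-block rules within one day.

    Returns the surviving blocks plus the set of inadmissible junctions
    (pairs of surviving block_ids whose boundary hides >=2 silent switches).
    When both neighbors share a songless block's color it merges backward
    (into the earlier block).
    """
    blocks = list(blocks)
    changed = True
    while changed:
        changed = False
        for i, b in enumerate(blocks):
            if has_song.get(b.block_id, False):
                continue
            prev_b = blocks[i - 1] if i > 0 else None
            next_b = blocks[i + 1] if i + 1 < len(blocks) else None
            if prev_b is not None and prev_b.color == b.color:
                blocks.pop(i)  # absorbed backward; prev keeps its identity
                changed = True
                break
            if next_b is not None and next_b.color == b.color:
                blocks.pop(i)
                changed = True
                break
    # a silent block left between two different-colored neighbors means the
    # light switched at least twice with no song: that junction is discarded
    bad_junctions: set[tuple[int, int]] = set()
    survivors: list[ContextBlock] = []
    silent_gap = False
    for b in blocks:
        if has_song.get(b.block_id, False):
            if silent_gap and survivors:
                bad_junctions.add((survivors[-1].block_id, b.block_id))
            survivors.append(b)
            silent_gap = False
        else:
            silent_gap = True
    return survivors, bad_junctions


def extract_switches(
    log: SongLog,
    class_filter: Iterable[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    targets: TargetPair | None = None,
    reference: str = "yellow",
) -> list[SwitchEvent]:
    """Admissible context switches with attached per-bout probabilities.

    Bouts without either target are discarded before attaching series; a
    block counts as songless when it contains no bouts at all.  Switch
    indices are ordinals over all admissible switches in time order (so they
    track training progression), assigned before any ``class_filter`` so
    that filtering does not renumber.  ``class_filter`` entries are
    ``((from_color, from_type), (to_color, to_type))`` pairs.
    """
    targets = targets or log.targets
    bouts_by_block: dict[int, list[tuple[int, float]]] = {
        b.block_id: [] for b in log.blocks
    }
    has_song: dict[int, bool] = {b.block_id: False for b in log.blocks}
    for bout in log.bouts:
        has_song[bout.block_id] = True
        sp = bout_probability(bout, targets, reference)
        if sp is not None:
            bouts_by_block[bout.block_id].append((bout.bout_id, sp.p))

    by_day: dict[int, list[ContextBlock]] = {}
    for blk in log.blocks:
        by_day.setdefault(blk.day, []).append(blk)

    switches: list[SwitchEvent] = []
    idx = 0
    for day in sorted(by_day):
        survivors, bad = _merge_songless(by_day[day], has_song)
        # coalesce adjacent same-color survivors (the light never visibly
        # changed color between them, e.g. after absorbing a silent probe);
        # junctions hiding >=2 silent color changes stay separate but their
        # switch is discarded below
        periods: list[tuple[ContextBlock, int, list[tuple[int, float]]]] = []
        for blk in survivors:
            series = bouts_by_block[blk.block_id]
            if (
                periods
                and periods[-1][0].color == blk.color
                and (periods[-1][1], blk.block_id) not in bad
            ):
                head, _, vals = periods[-1]
                periods[-1] = (head, blk.block_id, vals + series)
            else:
                periods.append((blk, blk.block_id, list(series)))
        for (a, a_last, pre), (b, _, post) in zip(periods, periods[1:]):
            if (a_last, b.block_id) in bad or a.color == b.color:
                continue
            switches.append(
                SwitchEvent(
                    from_block=a,
                    to_block=b,
                    switch_index=idx,
                    pre_series=tuple(p for _, p in pre),
                    post_series=tuple(p for _, p in post),
                    pre_bout_ids=tuple(i for i, _ in pre),
                    post_bout_ids=tuple(i for i, _ in post),
                )
            )
            idx += 1
    if class_filter is not None:
        wanted = set(class_filter)
        switches = [s for s in switches if s.switch_class in wanted]
    return switches


def shift_magnitude(
    sw: SwitchEvent, window: int = 5, min_bouts: int = 3
) -> ShiftEstimate | None:
    """Probability shift across one switch, or ``None`` if underpowered.

    Requires at least ``min_bouts`` bouts on each side; averages over the
    first/last ``window`` bouts, shrinking to what is available.
    """
    n_pre, n_post = len(sw.pre_series), len(sw.post_series)
    if n_pre < min_bouts or n_post < min_bouts:
        return None
    pre = sw.pre_series[-min(window, n_pre):]
    post = sw.post_series[:min(window, n_post)]
    return ShiftEstimate(
        delta_p=float(np.mean(post) - np.mean(pre)),
        n_pre=len(pre),
        n_post=len(post),
        first_last_delta=sw.post_series[0] - sw.pre_series[-1],
    )


def switch_triggered_average(
    switches: Sequence[SwitchEvent], min_fraction: float = 0.5
) -> AlignedAverage:
    """Mean +- SEM of bout probabilities aligned to the switch.

    Positions contributed by fewer than ``min_fraction`` of the switches are
    dropped, so the tails of the average are always supported by at least
    that share of blocks.
    """
    if not switches:
        raise ValueError("need at least one switch")
    n_sw = len(switches)
    columns: dict[int, list[float]] = {}
    for sw in switches:
        for k, v in enumerate(reversed(sw.pre_series)):
            columns.setdefault(-(k + 1), []).append(v)
        for k, v in enumerate(sw.post_series):
            columns.setdefault(k, []).append(v)
    keep = sorted(
        pos for pos, vals in columns.items()
        if len(vals) >= min_fraction * n_sw
    )
    means, sems, ns = [], [], []
    for pos in keep:
        vals = np.array(columns[pos])
        means.append(float(vals.mean()))
        sems.append(
            float(vals.std(ddof=1) / math.sqrt(len(vals)))
            if len(vals) > 1 else float("nan")
        )
        ns.append(len(vals))
    return AlignedAverage(
        positions=tuple(keep), mean=tuple(means), sem=tuple(sems), n=tuple(ns)
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS y = a + b x; returns (a, b, se_b)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate regressor")
    b = float(np.sum((x - xm) * (y - ym)) / sxx)
    a = float(ym - b * xm)
    if n > 2:
        resid = y - (a + b * x)
        se_b = math.sqrt(float(np.sum(resid**2)) / (n - 2) / sxx)
    else:
        se_b = float("nan")
    return a, b, se_b


def acquisition_fits(
    switches: Sequence[SwitchEvent],
    window: int | None = None,
    yellow_color: str = "yellow",
) -> list[AcquisitionFit]:
    """Per-switch linear fits of the post-switch probability trajectory.

    Each curve is sign-inverted for switches *into* the yellow context (so
    the adaptive direction is positive for both switch directions), the mean
    pre-switch probability is subtracted, and normalized probability is
    regressed on post-bout index 0, 1, ... (optionally truncated to the
    first ``window`` bouts).  Switches with fewer than two post bouts or no
    pre bouts are skipped.
    """
    fits: list[AcquisitionFit] = []
    for sw in switches:
        post = np.asarray(sw.post_series, dtype=float)
        if window is not None:
            post = post[:window]
        if len(post) < 2 or len(sw.pre_series) == 0:
            continue
        sign = -1.0 if sw.to_block.color == yellow_color else 1.0
        y = sign * (post - float(np.mean(sw.pre_series)))
        x = np.arange(len(post), dtype=float)
        a, b, _ = _ols(x, y)
        fits.append(
            AcquisitionFit(intercept=a, slope=b, switch_index=sw.switch_index)
        )
    return fits


def acquisition_trends(fits: Sequence[AcquisitionFit]) -> AcquisitionTrends:
    """How the immediate shift (intercepts) and within-block learning rate
    (slopes) evolve over training: OLS of each against switch index."""
    if len(fits) < 3:
        raise ValueError("need at least three fits for a trend")
    x = np.array([f.switch_index for f in fits], dtype=float)
    ints = np.array([f.intercept for f in fits])
    slopes = np.array([f.slope for f in fits])
    _, b_i, se_i = _ols(x, ints)
    _, b_s, se_s = _ols(x, slopes)
    return AcquisitionTrends(
        slope_of_intercepts=b_i,
        se_of_intercept_trend=se_i,
        slope_of_slopes=b_s,
        se_of_slope_trend=se_s,
    )


def display_smooth(series: Sequence[float], boxcar: int = 9) -> np.ndarray:
    """Boxcar moving average for display only (never used in fits).

    Edges shrink to the valid part of the window, preserving series length
    and total mass up to edge effects.
    """
    y = np.asarray(series, dtype=float)
    if boxcar <= 1 or len(y) == 0:
        return y.copy()
    half = boxcar // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def bin_series(values: Sequence[float], bin_size: int = 7) -> np.ndarray:
    """Means over consecutive bins (e.g. groups of seven switches); a
    trailing partial bin is averaged over its actual size."""
    v = np.asarray(values, dtype=float)
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    return np.array(
        [v[i : i + bin_size].mean() for i in range(0, len(v), bin_size)]
    )
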
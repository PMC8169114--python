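"""Sequence probabilities, confidence intervals and feedback accuracy.

Sequence probability is defined within each song bout as the frequency of
the reference target (the yellow target by convention) relative to the total
count of both targets:

    p = n_Y / (n_Y + n_G)

Bouts containing neither target carry no information about the targeted
branch and are discarded.  95% confidence intervals on pooled counts use the
normal approximation p +- z * sqrt(p (1 - p) / n) with n = n_Y + n_G and
z = 1.96.  Probabilities are fractions internally; percent only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .song_data import ContextBlock, SongBout, SongLog, TargetPair

__all__ = [
    "SequenceProbability",
    "FeedbackAccuracy",
    "BoutSeries",
    "count_motif",
    "bout_probability",
    "pooled_probability",
    "block_bout_series",
    "feedback_accuracy",
    "compare_groups",
]


@dataclass(frozen=True)
class SequenceProbability:
    """A target-sequence probability with its rendition counts and CI."""

    p: float
    n_y: int
    n_g: int
    z: float = 1.96

    @property
    def n(self) -> int:
        return self.n_y + self.n_g

    @property
    def ci_half_width(self) -> float:
        return self.z * math.sqrt(self.p * (1.0 - self.p) / self.n)


@dataclass(frozen=True)
class FeedbackAccuracy:
    """WN targeting accuracy of the (simulated or real) online template.

    sensitivity = hits / (hits + misses) over renditions of the active
    target; specificity = correct_escapes / (correct_escapes + false_alarms)
    where escapes are un-hit renditions of the *inactive* context's target
    and false alarms are WN anywhere else.
    """

    hits: int
    misses: int
    correct_escapes: int
    false_alarms: int

    @property
    def sensitivity(self) -> float:
        total = self.hits + self.misses
        return self.hits / total if total else float("nan")

    @property
    def specificity(self) -> float:
        total = self.correct_escapes + self.false_alarms
        return self.correct_escapes / total if total else float("nan")


@dataclass(frozen=True)
class BoutSeries:
    """Per-bout probabilities within one block, in time order."""

    values: tuple[float, ...]

    @property
    def mean(self) -> float | None:
        return float(np.mean(self.values)) if self.values else None

    @property
    def sem(self) -> float | None:
        # sample SD with n-1; undefined for fewer than two bouts
        if len(self.values) < 2:
            return None
        return float(np.std(self.values, ddof=1) / math.sqrt(len(self.values)))


def count_motif(labels: Sequence[str], motif: Sequence[str]) -> int:
    """Count (possibly overlapping) occurrences of ``motif`` in ``labels``.

    Overlap counting is order-independent and simple; the reinforced targets
    used in practice cannot self-overlap, so the choice is neutral there.
    """
    motif = tuple(motif)
    if not motif:
        raise ValueError("motif must be non-empty")
    labels = tuple(labels)
    m = len(motif)
    return sum(
        1 for i in range(len(labels) - m + 1) if labels[i : i + m] == motif
    )


def bout_probability(
    bout: SongBout,
    targets: TargetPair,
    reference: str = "yellow",
    z: float = 1.96,
) -> SequenceProbability | None:
    """Within-bout sequence probability of the reference target.

    Returns ``None`` for bouts containing neither target (discarded).
    ``reference`` selects which target the probability refers to
    (``'yellow'`` by convention).
    """
    n_y = count_motif(bout.labels, targets.target_y)
    n_g = count_motif(bout.labels, targets.target_g)
    if n_y + n_g == 0:
        return None
    num = n_y if reference == "yellow" else n_g
    return SequenceProbability(p=num / (n_y + n_g), n_y=n_y, n_g=n_g, z=z)


def pooled_probability(
    bouts: Iterable[SongBout],
    targets: TargetPair,
    reference: str = "yellow",
    z: float = 1.96,
) -> SequenceProbability:
    """Sequence probability from counts pooled across bouts (e.g. one day).

    Raises ``ValueError`` when no rendition of either target is present —
    distinct from the per-bout "discarded" outcome, because a pooled
    estimate was explicitly requested.
    """
    n_y = n_g = 0
    for bout in bouts:
        n_y += count_motif(bout.labels, targets.target_y)
        n_g += count_motif(bout.labels, targets.target_g)
    if n_y + n_g == 0:
        raise ValueError("no target renditions in the pooled bouts")
    num = n_y if reference == "yellow" else n_g
    return SequenceProbability(p=num / (n_y + n_g), n_y=n_y, n_g=n_g, z=z)


def block_bout_series(
    log: SongLog,
    block: ContextBlock | int,
    targets: TargetPair | None = None,
    reference: str = "yellow",
) -> BoutSeries:
    """Per-bout probabilities within one block, discarded bouts omitted."""
    targets = targets or log.targets
    values = []
    for bout in log.bouts_in(block):
        sp = bout_probability(bout, targets, reference)
        if sp is not None:
            values.append(sp.p)
    return BoutSeries(values=tuple(values))


def feedback_accuracy(
    log: SongLog,
    inactive_target_of: dict[int, tuple[str, ...]] | None = None,
) -> FeedbackAccuracy:
    """Measure realized WN accuracy from per-syllable hit flags.

    Considers WN-block bouts only.  A *hit* is WN on the final syllable of a
    rendition of the block's active target; renditions without WN there are
    *misses*.  Renditions of the other context's target (the inactive one)
    that received no WN are *correct escapes*; WN on an inactive-target
    rendition or on any other syllable is a *false alarm*.

    ``inactive_target_of`` optionally maps block_id to the inactive motif;
    by default it is the member of ``log.targets`` not active in the block.
    """
    hits = misses = escapes = false_alarms = 0
    pair = {log.targets.target_y, log.targets.target_g}
    for bout in log.bouts:
        block = log.block_of(bout)
        if block.block_type != "wn" or block.active_target is None:
            continue
        if bout.wn_hits is None:
            raise ValueError(f"bout {bout.bout_id} lacks wn_hits flags")
        active = tuple(block.active_target)
        if inactive_target_of is not None:
            inactive = tuple(inactive_target_of[block.block_id])
        else:
            others = pair - {active}
            inactive = next(iter(others)) if others else None
        labels, flags = bout.labels, bout.wn_hits
        active_ends = _rendition_ends(labels, active)
        inactive_ends = (
            _rendition_ends(labels, inactive) if inactive else set()
        )
        for j in active_ends:
            if flags[j]:
                hits += 1
            else:
                misses += 1
        for j in inactive_ends - active_ends:
            if flags[j]:
                false_alarms += 1
            else:
                escapes += 1
        for j, f in enumerate(flags):
            if f and j not in active_ends and j not in inactive_ends:
                false_alarms += 1
    return FeedbackAccuracy(
        hits=hits, misses=misses, correct_escapes=escapes,
        false_alarms=false_alarms,
    )


def _rendition_ends(labels: Sequence[str], motif: Sequence[str]) -> set[int]:
    motif = tuple(motif)
    m = len(motif)
    return {
        i + m - 1
        for i in range(len(labels) - m + 1)
        if tuple(labels[i : i + m]) == motif
    }


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided nonparametric comparison of two samples.

    Wilcoxon rank-sum for unpaired data, Wilcoxon signed-rank for paired —
    appropriate for small cross-bird samples where normality cannot be
    assumed.  Returns ``(statistic, p_value)``.  Identical paired samples
    (all differences zero) have no evidence of a difference; reported as
    ``(0.0, 1.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal lengths")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = stats.ranksums(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
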
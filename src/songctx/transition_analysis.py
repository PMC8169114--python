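"""Collapsed transition diagrams, context differences, specificity, entropy.

Raw label sequences are first *collapsed* so that stereotyped structure does
not masquerade as sequencing variability: introductory notes become a single
intro state, maximal same-syllable runs become a single repeat state, and
fixed chunks (runs of near-deterministic transitions, or chunks supplied
explicitly per bird) become single states, with syllables appearing in
multiple chunks or positions renamed so each state is unique (e.g. the fixed
sequence 'abbc' would otherwise fake a 50%/50% branch at 'b').

From collapsed sequences a first-order row-stochastic transition matrix
p(y|x) is built, with preceding-state frequencies p(x).  *Branch points*
are states with at least two outgoing probabilities strictly between 3% and
97%.  Contextual reorganization is measured on the difference between two
contexts' matrices: *specificity* is the share of absolute difference over
branch-point cells that falls at the branch point(s) immediately preceding
the reinforced targets, and *transition entropy* is

    H = sum_x p(x) * sum_y -p(y|x) log2 p(y|x)

a preceding-state-frequency-weighted conditional entropy in bits.  The
base-2 log and p(x) weighting are this package's definition choices (stated
in the docs); entropy is computed after the same collapsing/renaming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .song_data import SongBout

__all__ = [
    "CollapseRules",
    "TransitionModel",
    "DifferenceMatrix",
    "collapse_sequences",
    "build_transition_model",
    "branch_points",
    "context_difference",
    "specificity",
    "transition_entropy",
    "targeted_branch_states",
]

END = "end"
INTRO = "intro"


@dataclass(frozen=True)
class CollapseRules:
    """Per-bird preprocessing rules for diagram simplification.

    ``chunk_threshold`` is the minimum transition probability for greedily
    chaining states into a fixed chunk; ``explicit_chunks`` (token tuples)
    override detection for birds whose chunks are known (the original
    identification also used gap durations, which label-only data lack).
    """

    intro_labels: frozenset[str] = frozenset()
    chunk_threshold: float = 0.97
    repeat_collapse: bool = True
    rename_duplicated_chunk_members: bool = True
    explicit_chunks: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not 0.5 < self.chunk_threshold <= 1.0:
            raise ValueError("chunk_threshold must be in (0.5, 1]")


@dataclass
class TransitionModel:
    """First-order transition statistics over collapsed states.

    ``matrix`` is row-stochastic (rows: states with >=1 outgoing
    transition; columns additionally include the end state); ``state_freq``
    is the relative frequency of each preceding state.
    """

    states: tuple[str, ...]
    matrix: pd.DataFrame
    state_freq: pd.Series
    counts: pd.DataFrame

    def p(self, x: str, y: str) -> float:
        if x in self.matrix.index and y in self.matrix.columns:
            return float(self.matrix.loc[x, y])
        return 0.0


@dataclass
class DifferenceMatrix:
    """Signed per-cell transition-probability difference, context A - B.

    By reporting convention A is the green context and B the yellow one, so
    transitions more frequent under green light are positive.
    ``branch_rows`` is the union of the two contexts' branch points.
    """

    diff: pd.DataFrame
    branch_rows: tuple[str, ...]
    sign_convention: str = "A(green) - B(yellow); more frequent in green -> positive"

    def branch_cells(self) -> pd.DataFrame:
        return self.diff.loc[list(self.branch_rows)]


# ---------------------------------------------------------------------------
# collapsing


def _collapse_intro(seq: Sequence[str], rules: CollapseRules) -> list[str]:
    tokens = list(seq)
    if not rules.intro_labels:
        return tokens
    j = 0
    while j < len(tokens) and tokens[j] in rules.intro_labels:
        j += 1
    return ([INTRO] if j > 0 else []) + tokens[j:]


def _repeat_tokens(seqs: Iterable[Sequence[str]]) -> set[str]:
    """Tokens that ever occur in a run of length >= 2 anywhere in the
    corpus: these are treated as repeat-phrase syllables, and *all* their
    runs (even length 1) collapse to one repeat state."""
    reps: set[str] = set()
    for seq in seqs:
        for x, y in zip(seq, seq[1:]):
            if x == y:
                reps.add(x)
    return reps


def _collapse_repeats(seq: Sequence[str], reps: set[str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(seq):
        tok = seq[i]
        j = i
        while j < len(seq) and seq[j] == tok:
            j += 1
        out.append(tok + "+" if tok in reps else tok)
        i = j
    return out


def _transition_counts(seqs: Iterable[Sequence[str]]) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    for seq in seqs:
        states = list(seq) + [END]
        for x, y in zip(states, states[1:]):
            counts.setdefault(x, {}).setdefault(y, 0)
            counts[x][y] += 1
    return counts


def _detect_chunks(
    seqs: list[list[str]], threshold: float
) -> list[tuple[str, ...]]:
    """Greedy chaining of near-deterministic transitions into chunks.

    A link x -> y joins a chunk when p(y|x) >= threshold and x is not the
    end of the corpus; chains are maximal and non-branching.
    """
    counts = _transition_counts(seqs)
    strong: dict[str, str] = {}
    for x, out in counts.items():
        if x == INTRO:  # the intro state is variable by definition
            continue
        total = sum(out.values())
        for y, c in out.items():
            if y not in (END, INTRO) and c / total >= threshold:
                strong[x] = y
    # heads: states that are not the strong successor of another state
    successors = set(strong.values())
    chunks = []
    for head in strong:
        if head in successors:
            continue
        chain = [head]
        seen = {head}
        while chain[-1] in strong:
            nxt = strong[chain[-1]]
            if nxt in seen:  # cycle guard
                break
            chain.append(nxt)
            seen.add(nxt)
        if len(chain) >= 2:
            chunks.append(tuple(chain))
    return chunks


def collapse_sequences(
    bouts: Iterable[SongBout | Sequence[str]],
    rules: CollapseRules,
) -> list[list[str]]:
    """Collapse raw label sequences into diagram states.

    Applied in order: intro summarization, repeat-phrase summarization,
    chunk merging (explicit chunks if supplied, else greedy detection on
    this corpus at ``chunk_threshold``), and renaming of duplicated chunk
    members.  A chunk state is named by its joined member tokens; a second
    distinct chunk with an identical name gets a numeric suffix.
    """
    seqs = [
        list(b.labels) if isinstance(b, SongBout) else list(b) for b in bouts
    ]
    if not seqs:
        raise ValueError("empty corpus")
    seqs = [_collapse_intro(s, rules) for s in seqs]
    if rules.repeat_collapse:
        reps = _repeat_tokens(seqs)
        seqs = [_collapse_repeats(s, reps) for s in seqs]
    if rules.explicit_chunks:
        chunks = [tuple(c) for c in rules.explicit_chunks]
    else:
        chunks = _detect_chunks(seqs, rules.chunk_threshold)
    if not chunks:
        return seqs
    # name chunks; duplicated names distinguished when renaming is on
    names: dict[tuple[str, ...], str] = {}
    used: set[str] = set()
    for c in chunks:
        compact = all(
            len(t) == 1 or (len(t) == 2 and t.endswith("+")) for t in c
        )
        base = "".join(c) if compact else "-".join(c)
        name = base
        k = 2
        while rules.rename_duplicated_chunk_members and name in used:
            name = f"{base}_{k}"
            k += 1
        names[c] = name
        used.add(name)
    ordered = sorted(names, key=len, reverse=True)  # longest match first
    out_seqs: list[list[str]] = []
    for seq in seqs:
        out: list[str] = []
        i = 0
        while i < len(seq):
            for c in ordered:
                if tuple(seq[i : i + len(c)]) == c:
                    out.append(names[c])
                    i += len(c)
                    break
            else:
                out.append(seq[i])
                i += 1
        out_seqs.append(out)
    return out_seqs


# ---------------------------------------------------------------------------
# transition model


def build_transition_model(sequences: Iterable[Sequence[str]]) -> TransitionModel:
    """Count consecutive state pairs and row-normalize.

    Each bout is terminated by an explicit end state; bout boundaries never
    create transitions.  ``state_freq`` is row totals over the grand total.
    """
    counts = _transition_counts(sequences)
    if not counts:
        raise ValueError("no transitions in corpus")
    rows = sorted(counts)
    cols = sorted({y for out in counts.values() for y in out} | set(rows))
    cmat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for x, out in counts.items():
        for y, c in out.items():
            cmat.loc[x, y] = c
    row_tot = cmat.sum(axis=1)
    matrix = cmat.div(row_tot, axis=0)
    state_freq = row_tot / row_tot.sum()
    return TransitionModel(
        states=tuple(rows), matrix=matrix, state_freq=state_freq, counts=cmat
    )


def branch_points(
    model: TransitionModel, lo: float = 0.03, hi: float = 0.97
) -> set[str]:
    """States with at least two outgoing probabilities strictly inside
    (lo, hi) — points of genuinely variable sequencing."""
    result = set()
    for x in model.matrix.index:
        row = model.matrix.loc[x]
        inside = ((row > lo) & (row < hi)).sum()
        if inside >= 2:
            result.add(x)
    return result


def context_difference(
    model_a: TransitionModel,
    model_b: TransitionModel,
    lo: float = 0.03,
    hi: float = 0.97,
) -> DifferenceMatrix:
    """Per-cell difference of two contexts' matrices over the unioned state
    set (missing cells are zero).  Branch rows are the union of the two
    contexts' branch points."""
    rows = sorted(set(model_a.matrix.index) | set(model_b.matrix.index))
    cols = sorted(set(model_a.matrix.columns) | set(model_b.matrix.columns))
    if not (set(model_a.matrix.index) & set(model_b.matrix.index)):
        raise ValueError(
            "contexts share no states; labeling is likely inconsistent"
        )
    a = model_a.matrix.reindex(index=rows, columns=cols, fill_value=0.0)
    b = model_b.matrix.reindex(index=rows, columns=cols, fill_value=0.0)
    branch = sorted(
        (branch_points(model_a, lo, hi) | branch_points(model_b, lo, hi))
    )
    return DifferenceMatrix(diff=a - b, branch_rows=tuple(branch))


def specificity(
    diff: DifferenceMatrix, targeted_branch_states: Iterable[str]
) -> float:
    """Share of branch-point contextual change at the targeted branch(es).

    Sum of |difference| over cells in targeted branch-point rows divided by
    the sum over all branch-point rows.  Raises when the two contexts do not
    differ at any branch point (the ratio is undefined).
    """
    targeted = set(targeted_branch_states)
    missing = targeted - set(diff.branch_rows)
    if missing:
        raise ValueError(
            f"targeted states are not branch points: {sorted(missing)}"
        )
    absdiff = diff.branch_cells().abs()
    denom = float(absdiff.to_numpy().sum())
    if denom == 0.0:
        raise ValueError("no contextual difference at any branch point")
    num = float(absdiff.loc[sorted(targeted)].to_numpy().sum())
    return num / denom


def _expand_state(name: str) -> tuple[str, ...]:
    """Minimal token expansion of a collapsed-state name.

    A repeat state ``x+`` emits at least one ``x``; a chunk named by its
    joined members emits each member once; the intro state emits nothing
    that could belong to a target.  Multi-token chunk names are joined with
    '-', single-character ones by concatenation with '+' markers inline.
    """
    if name in (INTRO, END):
        return ()
    if "-" in name:
        parts = name.split("-")
    else:
        parts, i = [], 0
        while i < len(name):
            tok = name[i]
            if i + 1 < len(name) and name[i + 1] == "+":
                i += 1
            parts.append(tok)
            i += 1
        return tuple(parts)
    return tuple(p.rstrip("+") for p in parts)


def targeted_branch_states(
    diff: DifferenceMatrix, targets: Iterable[Sequence[str]]
) -> set[str]:
    """Branch points immediately preceding the reinforced target sequences.

    A branch row x is targeted when, for some successor column y, the
    minimal token expansion of x followed by y contains a target motif with
    the occurrence crossing the x -> y boundary — i.e. producing the target
    requires taking that particular transition out of x.
    """
    motifs = [tuple(t) for t in targets]
    found: set[str] = set()
    for x in diff.branch_rows:
        ex = _expand_state(x)
        for y in diff.diff.columns:
            if y == END:
                continue
            ey = _expand_state(y)
            joint = ex + ey
            for m in motifs:
                L = len(m)
                for i in range(len(joint) - L + 1):
                    if joint[i : i + L] == m and i < len(ex) and i + L > len(ex):
                        found.add(x)
    return found


def transition_entropy(model: TransitionModel) -> float:
    """Preceding-state-frequency-weighted conditional entropy, in bits.

    H = sum_x p(x) H(row x), with 0 log 0 = 0.  Zero for a deterministic
    chain; log2(k) for a uniform k-way branch from a single state.
    """
    h = 0.0
    for x in model.matrix.index:
        row = model.matrix.loc[x].to_numpy(dtype=float)
        nz = row[row > 0.0]
        h_row = float(-(nz * np.log2(nz)).sum())
        h += float(model.state_freq.loc[x]) * h_row
    return h
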
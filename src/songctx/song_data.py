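"""Data model, file I/O and validation for annotated song logs.

The unit of analysis is the *song bout*: a continuous period of singing,
annotated offline as an ordered string of syllable labels.  Bouts are grouped
into *context blocks* — contiguous periods under one light color, during which
white-noise (WN) reinforcement may target one specific syllable sequence.

Labels are tokens, not necessarily single characters, so that collapsed or
renamed states (e.g. ``"b_2"``) survive a round trip through the text format.

On-disk format (UTF-8 delimited text, comma separated):

* bout file — header ``bout_id,day,time_s,block_id,labels,wn_hits``;
  ``labels`` is the token string joined with ``label_sep`` ('' for
  single-character labels, '.' for multi-token labels); ``wn_hits`` is a
  string of 0/1 flags of the same token length, or empty when absent.
* block file — header
  ``block_id,day,start_s,end_s,color,block_type,active_target``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "SongBout",
    "ContextBlock",
    "TargetPair",
    "SongLog",
    "SongLogError",
    "SongLogParseError",
    "SongLogValidationError",
    "read_song_log",
    "write_song_log",
    "validate_blocks",
    "split_labels",
    "join_labels",
]

BLOCK_TYPES = ("wn", "probe", "neutral")


class SongLogError(Exception):
    """Base class for song-log I/O and validation failures."""


class SongLogParseError(SongLogError):
    """A row of a bout/block file could not be parsed."""


class SongLogValidationError(SongLogError):
    """Parsed data violate a song-log invariant."""


def split_labels(s: str, sep: str = "") -> tuple[str, ...]:
    """Split a label string into tokens.

    With ``sep=''`` every character is a token (the common single-character
    annotation style); otherwise tokens are separated by ``sep``.
    """
    if sep == "":
        return tuple(s)
    return tuple(t for t in s.split(sep) if t)


def join_labels(tokens: Sequence[str], sep: str = "") -> str:
    if sep == "" and any(len(t) != 1 for t in tokens):
        raise ValueError(
            "multi-character tokens need an explicit label separator"
        )
    return sep.join(tokens)


@dataclass(frozen=True)
class SongBout:
    """One annotated song bout.

    ``wn_hits``, when present, flags per-syllable WN delivery (True where a
    noise burst was delivered, by convention on the final token of the
    triggering target rendition).
    """

    bout_id: int
    day: int
    time_s: float
    labels: tuple[str, ...]
    block_id: int
    wn_hits: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise SongLogValidationError(f"bout {self.bout_id}: empty labels")
        if self.wn_hits is not None and len(self.wn_hits) != len(self.labels):
            raise SongLogValidationError(
                f"bout {self.bout_id}: wn_hits length {len(self.wn_hits)} "
                f"!= labels length {len(self.labels)}"
            )


@dataclass(frozen=True)
class ContextBlock:
    """A contiguous period of one light color.

    ``block_type`` is ``'wn'`` (reinforced), ``'probe'`` (same cue, no WN) or
    ``'neutral'`` (third cue, never reinforced).  ``active_target`` is the
    syllable sequence punished in this block; absent for probe/neutral.
    """

    block_id: int
    day: int
    start_s: float
    end_s: float
    color: str
    block_type: str
    active_target: tuple[str, ...] | None = None

    def contains(self, time_s: float) -> bool:
        return self.start_s <= time_s < self.end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class TargetPair:
    """The two reinforced sequences: ``target_y`` punished under yellow
    light, ``target_g`` punished under green light."""

    target_y: tuple[str, ...]
    target_g: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.target_y or not self.target_g:
            raise SongLogValidationError("targets must be non-empty")
        if self.target_y == self.target_g:
            raise SongLogValidationError("targets must be distinct")


@dataclass
class SongLog:
    """A full single-bird experiment record: bouts, blocks, targets."""

    bouts: list[SongBout]
    blocks: list[ContextBlock]
    targets: TargetPair
    bird_id: str = "synthetic"
    palette: tuple[str, ...] = ("green", "yellow", "white")
    label_sep: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        self._block_index = {b.block_id: b for b in self.blocks}

    def block_of(self, bout: SongBout) -> ContextBlock:
        return self._block_index[bout.block_id]

    def bouts_in(self, block: ContextBlock | int) -> list[SongBout]:
        bid = block if isinstance(block, int) else block.block_id
        return [b for b in self.bouts if b.block_id == bid]

    def validate(self) -> None:
        """Raise :class:`SongLogValidationError` on the first violation."""
        for v in validate_blocks(self.blocks):
            raise SongLogValidationError(v)
        last_time: dict[int, float] = {}
        for bout in self.bouts:
            if bout.block_id not in self._block_index:
                raise SongLogValidationError(
                    f"bout {bout.bout_id}: unknown block {bout.block_id}"
                )
            block = self._block_index[bout.block_id]
            if not block.contains(bout.time_s):
                raise SongLogValidationError(
                    f"bout {bout.bout_id}: time {bout.time_s} outside block "
                    f"{block.block_id} [{block.start_s}, {block.end_s})"
                )
            if bout.day != block.day:
                raise SongLogValidationError(
                    f"bout {bout.bout_id}: day {bout.day} != block day "
                    f"{block.day}"
                )
            prev = last_time.get(bout.day)
            if prev is not None and bout.time_s <= prev:
                raise SongLogValidationError(
                    f"bout {bout.bout_id}: time not strictly increasing "
                    f"within day {bout.day}"
                )
            last_time[bout.day] = bout.time_s
        for c in {b.color for b in self.blocks}:
            if c not in self.palette:
                raise SongLogValidationError(f"unknown color token {c!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SongLog):
            return NotImplemented
        return (
            self.bouts == other.bouts
            and self.blocks == other.blocks
            and self.targets == other.targets
            and self.bird_id == other.bird_id
            and self.palette == other.palette
            and self.label_sep == other.label_sep
        )


def validate_blocks(blocks: Iterable[ContextBlock]) -> list[str]:
    """Check ContextBlock invariants; violations are data, not exceptions.

    Returns one human-readable message per violated rule, naming the block.
    """
    violations: list[str] = []
    by_day: dict[int, list[ContextBlock]] = {}
    for b in blocks:
        if b.end_s <= b.start_s:
            violations.append(f"block {b.block_id}: end_s <= start_s")
        if b.block_type not in BLOCK_TYPES:
            violations.append(
                f"block {b.block_id}: unknown block_type {b.block_type!r}"
            )
        if b.block_type in ("probe", "neutral") and b.active_target:
            violations.append(
                f"block {b.block_id}: {b.block_type} block must not carry an "
                "active_target"
            )
        if b.block_type == "wn" and not b.active_target:
            violations.append(f"block {b.block_id}: wn block needs a target")
        by_day.setdefault(b.day, []).append(b)
    for day, day_blocks in by_day.items():
        for a, b in zip(day_blocks, day_blocks[1:]):
            if b.start_s < a.end_s:
                violations.append(
                    f"block {b.block_id}: overlaps block {a.block_id} on day "
                    f"{day}"
                )
    days = [b.day for b in blocks]
    if days != sorted(days):
        violations.append("blocks: day order not ascending")
    return violations


# ---------------------------------------------------------------------------
# file I/O

_BOUT_COLS = ["bout_id", "day", "time_s", "block_id", "labels", "wn_hits"]
_BLOCK_COLS = [
    "block_id", "day", "start_s", "end_s", "color", "block_type",
    "active_target",
]


def _bout_path(path: Path) -> Path:
    return path / "bouts.csv" if path.is_dir() or path.suffix == "" else path


def write_song_log(log: SongLog, path: str | Path) -> None:
    """Write a song log as a directory of delimited-text files.

    ``path`` becomes a directory holding ``bouts.csv``, ``blocks.csv`` and
    ``meta.yaml``; readable back with :func:`read_song_log`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sep = log.label_sep
    bout_rows = [
        {
            "bout_id": b.bout_id,
            "day": b.day,
            "time_s": repr(b.time_s),
            "block_id": b.block_id,
            "labels": join_labels(b.labels, sep),
            "wn_hits": "".join("1" if h else "0" for h in b.wn_hits)
            if b.wn_hits is not None
            else "",
        }
        for b in log.bouts
    ]
    pd.DataFrame(bout_rows, columns=_BOUT_COLS).to_csv(
        path / "bouts.csv", index=False
    )
    block_rows = [
        {
            "block_id": blk.block_id,
            "day": blk.day,
            "start_s": repr(blk.start_s),
            "end_s": repr(blk.end_s),
            "color": blk.color,
            "block_type": blk.block_type,
            "active_target": join_labels(blk.active_target, sep)
            if blk.active_target
            else "",
        }
        for blk in log.blocks
    ]
    pd.DataFrame(block_rows, columns=_BLOCK_COLS).to_csv(
        path / "blocks.csv", index=False
    )
    meta = {
        "bird_id": log.bird_id,
        "palette": list(log.palette),
        "label_sep": sep,
        "notes": log.notes,
        "targets": {
            "target_y": join_labels(log.targets.target_y, sep),
            "target_g": join_labels(log.targets.target_g, sep),
        },
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_song_log(path: str | Path, validate: bool = True) -> SongLog:
    """Read a song log written by :func:`write_song_log`.

    Raises :class:`SongLogParseError` naming the offending row on malformed
    input and :class:`SongLogValidationError` when invariants fail (e.g. a
    bout timestamp outside every block, an unknown color token).
    """
    path = Path(path)
    if not path.exists():
        raise SongLogError(f"no such song log: {path}")
    meta = yaml.safe_load((path / "meta.yaml").read_text())
    sep = meta.get("label_sep", "")
    targets = TargetPair(
        target_y=split_labels(meta["targets"]["target_y"], sep),
        target_g=split_labels(meta["targets"]["target_g"], sep),
    )

    blocks_df = pd.read_csv(path / "blocks.csv", dtype=str, keep_default_na=False)
    blocks: list[ContextBlock] = []
    for i, row in enumerate(blocks_df.itertuples(index=False), start=2):
        try:
            blocks.append(
                ContextBlock(
                    block_id=int(row.block_id),
                    day=int(row.day),
                    start_s=float(row.start_s),
                    end_s=float(row.end_s),
                    color=row.color,
                    block_type=row.block_type,
                    active_target=split_labels(row.active_target, sep) or None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise SongLogParseError(f"blocks.csv row {i}: {exc}") from exc

    bouts_df = pd.read_csv(path / "bouts.csv", dtype=str, keep_default_na=False)
    bouts: list[SongBout] = []
    for i, row in enumerate(bouts_df.itertuples(index=False), start=2):
        try:
            hits = row.wn_hits if hasattr(row, "wn_hits") else ""
            bouts.append(
                SongBout(
                    bout_id=int(row.bout_id),
                    day=int(row.day),
                    time_s=float(row.time_s),
                    labels=split_labels(row.labels, sep),
                    block_id=int(row.block_id),
                    wn_hits=tuple(c == "1" for c in hits) if hits else None,
                )
            )
        except SongLogValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise SongLogParseError(f"bouts.csv row {i}: {exc}") from exc

    log = SongLog(
        bouts=bouts,
        blocks=blocks,
        targets=targets,
        bird_id=str(meta.get("bird_id", "unknown")),
        palette=tuple(meta.get("palette", ("green", "yellow", "white"))),
        label_sep=sep,
        notes=str(meta.get("notes", "")),
    )
    if validate:
        log.validate()
    return log
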
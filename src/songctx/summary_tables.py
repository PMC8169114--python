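"""Cross-bird summary statistics from published per-bird summary tables.

The published record of the context-training experiments ships per-figure
summary tables (per-bird shift magnitudes by switch class, per-bird context
differences at baseline and after training, per-bird branch-point
specificity).  These helpers recompute the headline group statistics from
such tables once they have been converted to delimited text with the
following schemas:

* shift table — ``bird_id,from_color,from_type,to_color,to_type,shift``
  (one row per bird and switch class; shift in probability units, signed);
* context-difference table — ``bird_id,phase,difference`` with phase in
  {baseline, trained} (difference in probability units, unsigned);
* specificity table — ``bird_id,specificity`` (fraction in [0, 1]).

The tables themselves are not bundled: place converted copies under a
directory of your choosing and point these loaders at them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "load_shift_table",
    "load_context_difference_table",
    "load_specificity_table",
    "mean_shift",
    "mean_context_difference",
    "median_specificity",
]


def load_shift_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"bird_id", "from_color", "from_type", "to_color", "to_type", "shift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    return df


def load_context_difference_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"bird_id", "phase", "difference"} - set(df.columns)
    if missing:
        raise ValueError(f"difference table missing columns: {sorted(missing)}")
    return df


def load_specificity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"bird_id", "specificity"} - set(df.columns)
    if missing:
        raise ValueError(f"specificity table missing columns: {sorted(missing)}")
    return df


def mean_shift(
    shifts: pd.DataFrame,
    to_color: str,
    to_type: str | None = None,
    from_color: str | None = None,
    from_type: str | None = None,
) -> float:
    """Across-bird mean shift magnitude for one switch class (per-bird
    values first, then the unweighted mean across birds)."""
    sel = shifts[shifts["to_color"] == to_color]
    if to_type is not None:
        sel = sel[sel["to_type"] == to_type]
    if from_color is not None:
        sel = sel[sel["from_color"] == from_color]
    if from_type is not None:
        sel = sel[sel["from_type"] == from_type]
    if sel.empty:
        raise ValueError("no rows match the requested switch class")
    return float(sel.groupby("bird_id")["shift"].mean().mean())


def mean_context_difference(diffs: pd.DataFrame, phase: str) -> float:
    sel = diffs[diffs["phase"] == phase]
    if sel.empty:
        raise ValueError(f"no rows for phase {phase!r}")
    return float(sel.groupby("bird_id")["difference"].mean().mean())


def median_specificity(spec: pd.DataFrame) -> float:
    return float(spec.groupby("bird_id")["specificity"].mean().median())
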
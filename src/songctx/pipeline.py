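"""Generate → analyze → recover orchestration.

Thin composition layer over the analysis modules: reads or generates a song
log, runs sequence statistics, switch analysis and transition analysis with
one set of parameters, and writes a reproducible report bundle (delimited
tables + JSON summary with a provenance block).  Identical config and seed
give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import synthetic_song as syn
from .sequence_stats import block_bout_series, pooled_probability
from .song_data import SongLog, TargetPair, read_song_log, split_labels, write_song_log
from .switch_analysis import (
    AcquisitionTrends,
    acquisition_fits,
    acquisition_trends,
    extract_switches,
    shift_magnitude,
)
from .transition_analysis import (
    CollapseRules,
    DifferenceMatrix,
    TransitionModel,
    build_transition_model,
    collapse_sequences,
    context_difference,
    specificity,
    targeted_branch_states,
    transition_entropy,
)

__all__ = ["RunConfig", "ReportBundle", "run_generate", "run_analyze",
           "run_recover", "load_scenario", "demo_scenario"]

log = logging.getLogger("songctx")


# ---------------------------------------------------------------------------
# scenario configuration


def demo_scenario() -> dict[str, Any]:
    """Bundled demonstration scenario: a trained bird with both learning
    processes active, ten days of probe-interleaved blocks."""
    return {
        "diagram": {
            "edges": {
                "start": {"A": 1.0},
                "A": {"d": 0.5, "c": 0.5},
                "d": {"e": 1.0},
                "c": {"e": 1.0},
                "e": {"f": 1.0},
                "f": {"g": 0.6, "h": 0.4},
                "g": {"A": 0.85, "end": 0.15},
                "h": {"A": 0.85, "end": 0.15},
            },
            "branch_state": "A",
            "yellow_edge": "d",
            "green_edge": "c",
            "chunks": {"A": ["a", "a", "b"]},
            "intro_state": "i",
            "intro_repeat": 0.5,
            "repeat_states": {"e": 0.6},
        },
        "dynamics": {
            "p0": 0.5, "delta_max": 0.25, "tau_blocks": 20.0,
            "s_within": 0.005, "l_max": 0.2, "clamp_eps": 0.01,
        },
        "schedule": {
            "interval_bounds_s": [3600.0, 5400.0],
            "probe_fraction": 1 / 3,
            "day_length_s": 50400.0,
            "n_days": 10,
            "bout_rate": 240.0,
            "colors": ["green", "yellow", "white"],
            "neutral_enabled": False,
        },
        "targets": {"target_y": "abd", "target_g": "abc"},
        "wn": {"sensitivity": 0.913, "false_alarm_rate": 0.005},
    }


def load_scenario(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return yaml.safe_load(fh)
    return dict(source)


def _build_scenario(sc: Mapping[str, Any]):
    d = sc["diagram"]
    diagram = syn.TransitionDiagram(
        edges={s: dict(o) for s, o in d["edges"].items()},
        branch_state=d["branch_state"],
        yellow_edge=d["yellow_edge"],
        green_edge=d["green_edge"],
        chunks={s: tuple(c) for s, c in d.get("chunks", {}).items()},
        intro_state=d.get("intro_state"),
        intro_repeat=float(d.get("intro_repeat", 0.5)),
        repeat_states={s: float(r) for s, r in d.get("repeat_states", {}).items()},
    )
    dyn = syn.LearningDynamics(**sc.get("dynamics", {}))
    cfg_raw = dict(sc.get("schedule", {}))
    if "interval_bounds_s" in cfg_raw:
        cfg_raw["interval_bounds_s"] = tuple(cfg_raw["interval_bounds_s"])
    if "colors" in cfg_raw:
        cfg_raw["colors"] = tuple(cfg_raw["colors"])
    cfg = syn.ScheduleConfig(**cfg_raw)
    t = sc.get("targets", {"target_y": "abd", "target_g": "abc"})
    sep = sc.get("label_sep", "")
    targets = TargetPair(
        target_y=split_labels(t["target_y"], sep),
        target_g=split_labels(t["target_g"], sep),
    )
    wn = sc.get("wn", {})
    return diagram, dyn, cfg, targets, wn


def _scenario_hash(sc: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(sc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_generate(
    scenario: str | Path | Mapping[str, Any],
    seed: int,
    outdir: str | Path,
) -> tuple[SongLog, syn.GroundTruth]:
    """Simulate a full experiment and write the song log, per-bout ground
    truth and a manifest (seed + scenario hash) under ``outdir``."""
    sc = load_scenario(scenario)
    diagram, dyn, cfg, targets, wn = _build_scenario(sc)
    song_log, truth = syn.simulate_experiment(
        diagram, dyn, cfg, seed, targets=targets,
        sensitivity=float(wn.get("sensitivity", 0.913)),
        false_alarm_rate=float(wn.get("false_alarm_rate", 0.005)),
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_song_log(song_log, outdir / "log")
    pd.DataFrame(
        {
            "bout_id": truth.bout_id,
            "p_true": truth.p_true,
            "shift_component": truth.shift_component,
            "drift_component": truth.drift_component,
        }
    ).to_csv(outdir / "truth.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(
            {"seed": seed, "scenario_sha256": _scenario_hash(sc)}, indent=2
        )
    )
    return song_log, truth


# ---------------------------------------------------------------------------
# analysis


@dataclass
class RunConfig:
    """Analysis parameters for one pipeline run."""

    window: int = 5
    min_bouts: int = 3
    min_fraction: float = 0.5
    reference: str = "yellow"
    intro_labels: frozenset[str] = frozenset({"i"})
    chunk_threshold: float = 0.97
    green: str = "green"
    yellow: str = "yellow"


@dataclass
class ReportBundle:
    """All pipeline outputs, regenerable from inputs + config alone."""

    per_day: pd.DataFrame
    per_block: pd.DataFrame
    switch_table: pd.DataFrame
    class_summary: pd.DataFrame
    trends: AcquisitionTrends | None
    model_green: TransitionModel | None
    model_yellow: TransitionModel | None
    difference: DifferenceMatrix | None
    targeted_states: tuple[str, ...]
    specificity: float | None
    entropy_green: float | None
    entropy_yellow: float | None
    discarded: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_day.to_csv(outdir / "per_day.csv", index=False)
        self.per_block.to_csv(outdir / "per_block.csv", index=False)
        self.switch_table.to_csv(outdir / "switches.csv", index=False)
        self.class_summary.to_csv(outdir / "class_summary.csv", index=False)
        for name, model in (
            ("green", self.model_green), ("yellow", self.model_yellow)
        ):
            if model is not None:
                model.matrix.round(6).to_csv(outdir / f"matrix_{name}.csv")
        if self.difference is not None:
            self.difference.diff.round(6).to_csv(outdir / "difference.csv")
        summary = {
            "specificity": self.specificity,
            "entropy_green_bits": self.entropy_green,
            "entropy_yellow_bits": self.entropy_yellow,
            "targeted_branch_states": list(self.targeted_states),
            "trends": None
            if self.trends is None
            else {
                "slope_of_intercepts": self.trends.slope_of_intercepts,
                "se_of_intercept_trend": self.trends.se_of_intercept_trend,
                "slope_of_slopes": self.trends.slope_of_slopes,
                "se_of_slope_trend": self.trends.se_of_slope_trend,
            },
            "discarded": self.discarded,
            "provenance": self.provenance,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _context_corpora(log_: SongLog, cfg: RunConfig):
    """Per-context bout corpora for matrix building: probe blocks when
    available (reinforcement-free singing), else WN blocks with a notice."""
    out = {}
    for color in (cfg.green, cfg.yellow):
        probe = [
            b for b in log_.bouts
            if log_.block_of(b).color == color
            and log_.block_of(b).block_type == "probe"
        ]
        if probe:
            out[color] = probe
        else:
            log.info(
                "no probe blocks in %s context; falling back to WN blocks",
                color,
            )
            out[color] = [
                b for b in log_.bouts
                if log_.block_of(b).color == color
                and log_.block_of(b).block_type == "wn"
            ]
    return out[cfg.green], out[cfg.yellow]


def run_analyze(
    song_log: SongLog | str | Path, cfg: RunConfig | None = None
) -> ReportBundle:
    """Run the full analysis battery on one song log."""
    cfg = cfg or RunConfig()
    if not isinstance(song_log, SongLog):
        song_log = read_song_log(song_log)
    targets = song_log.targets

    # per-day pooled probabilities
    by_day: dict[int, list] = {}
    for b in song_log.bouts:
        by_day.setdefault(b.day, []).append(b)
    day_rows = []
    for day in sorted(by_day):
        try:
            sp = pooled_probability(by_day[day], targets, cfg.reference)
        except ValueError:
            continue
        day_rows.append(
            {
                "day": day, "n_y": sp.n_y, "n_g": sp.n_g, "p": sp.p,
                "ci_half_width": sp.ci_half_width, "n_bouts": len(by_day[day]),
            }
        )
    per_day = pd.DataFrame(
        day_rows,
        columns=["day", "n_y", "n_g", "p", "ci_half_width", "n_bouts"],
    )

    # per-block bout-mean series
    block_rows = []
    for blk in song_log.blocks:
        series = block_bout_series(song_log, blk, targets, cfg.reference)
        block_rows.append(
            {
                "block_id": blk.block_id, "day": blk.day, "color": blk.color,
                "block_type": blk.block_type, "n_bouts": len(series.values),
                "p_mean": series.mean, "sem": series.sem,
            }
        )
    per_block = pd.DataFrame(block_rows)

    # switches and shifts
    switches = extract_switches(song_log, reference=cfg.reference)
    sw_rows = []
    n_too_few = 0
    for sw in switches:
        est = shift_magnitude(sw, cfg.window, cfg.min_bouts)
        if est is None:
            n_too_few += 1
        sw_rows.append(
            {
                "switch_index": sw.switch_index,
                "day": sw.day,
                "from_color": sw.from_block.color,
                "from_type": sw.from_block.block_type,
                "to_color": sw.to_block.color,
                "to_type": sw.to_block.block_type,
                "n_pre": len(sw.pre_series),
                "n_post": len(sw.post_series),
                "delta_p": None if est is None else est.delta_p,
                "first_last_delta": None if est is None else est.first_last_delta,
            }
        )
    switch_table = pd.DataFrame(
        sw_rows,
        columns=[
            "switch_index", "day", "from_color", "from_type", "to_color",
            "to_type", "n_pre", "n_post", "delta_p", "first_last_delta",
        ],
    )

    # per-class shift summary
    cls_rows = []
    if len(switch_table):
        ok = switch_table.dropna(subset=["delta_p"])
        for keys, grp in ok.groupby(
            ["from_color", "from_type", "to_color", "to_type"]
        ):
            vals = grp["delta_p"].to_numpy()
            cls_rows.append(
                {
                    "from_color": keys[0], "from_type": keys[1],
                    "to_color": keys[2], "to_type": keys[3],
                    "n": len(vals), "mean_shift": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else None,
                }
            )
    class_summary = pd.DataFrame(
        cls_rows,
        columns=[
            "from_color", "from_type", "to_color", "to_type", "n",
            "mean_shift", "sem",
        ],
    )

    # acquisition dynamics
    fits = acquisition_fits(switches, yellow_color=cfg.yellow)
    trends = acquisition_trends(fits) if len(fits) >= 3 else None

    # transition analysis on per-context corpora
    rules = CollapseRules(
        intro_labels=cfg.intro_labels, chunk_threshold=cfg.chunk_threshold
    )
    model_g = model_y = None
    diff = None
    spec_value = None
    ent_g = ent_y = None
    targeted: tuple[str, ...] = ()
    green_bouts, yellow_bouts = _context_corpora(song_log, cfg)
    if green_bouts and yellow_bouts:
        model_g = build_transition_model(collapse_sequences(green_bouts, rules))
        model_y = build_transition_model(collapse_sequences(yellow_bouts, rules))
        ent_g = transition_entropy(model_g)
        ent_y = transition_entropy(model_y)
        diff = context_difference(model_g, model_y)
        targeted = tuple(
            sorted(
                targeted_branch_states(
                    diff, [targets.target_y, targets.target_g]
                )
            )
        )
        if targeted:
            try:
                spec_value = specificity(diff, targeted)
            except ValueError as exc:
                log.info("specificity undefined: %s", exc)

    discarded = {
        "switches_total": len(switches),
        "switches_too_few_bouts": n_too_few,
        "bouts_total": len(song_log.bouts),
        "bouts_without_targets": len(song_log.bouts)
        - int(per_block["n_bouts"].sum() if len(per_block) else 0),
    }
    for k, v in discarded.items():
        log.info("pipeline count: %s = %s", k, v)

    return ReportBundle(
        per_day=per_day,
        per_block=per_block,
        switch_table=switch_table,
        class_summary=class_summary,
        trends=trends,
        model_green=model_g,
        model_yellow=model_y,
        difference=diff,
        targeted_states=targeted,
        specificity=spec_value,
        entropy_green=ent_g,
        entropy_yellow=ent_y,
        discarded=discarded,
        provenance={
            "bird_id": song_log.bird_id,
            "window": cfg.window,
            "min_bouts": cfg.min_bouts,
            "reference": cfg.reference,
        },
    )


# ---------------------------------------------------------------------------
# recovery against ground truth


def run_recover(
    song_log: SongLog,
    truth: syn.GroundTruth,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Bias and RMSE of pipeline estimates against generator ground truth.

    Shift estimates are compared per switch with the same windows applied to
    the true per-bout branch probabilities; per-switch fitted slopes are
    compared with slopes fit to the true probabilities.
    """
    cfg = cfg or RunConfig()
    p_true = dict(zip(truth.bout_id, truth.p_true))
    switches = extract_switches(song_log, reference=cfg.reference)
    sh_err, sl_err = [], []
    for sw in switches:
        est = shift_magnitude(sw, cfg.window, cfg.min_bouts)
        if est is None:
            continue
        pre_ids = sw.pre_bout_ids[-est.n_pre:]
        post_ids = sw.post_bout_ids[:est.n_post]
        true_shift = float(
            np.mean([p_true[i] for i in post_ids])
            - np.mean([p_true[i] for i in pre_ids])
        )
        sh_err.append(est.delta_p - true_shift)
        if len(sw.post_bout_ids) >= 2:
            sign = -1.0 if sw.to_block.color == cfg.yellow else 1.0
            x = np.arange(len(sw.post_bout_ids), dtype=float)
            yt = sign * np.array([p_true[i] for i in sw.post_bout_ids])
            ye = sign * np.asarray(sw.post_series)
            bt = np.polyfit(x, yt, 1)[0]
            be = np.polyfit(x, ye, 1)[0]
            sl_err.append(be - bt)
    rows = []
    for name, err in (("shift", sh_err), ("within_block_slope", sl_err)):
        if err:
            e = np.asarray(err)
            rows.append(
                {
                    "quantity": name, "n": len(e),
                    "bias": float(e.mean()),
                    "rmse": float(np.sqrt((e**2).mean())),
                }
            )
    return pd.DataFrame(rows, columns=["quantity", "n", "bias", "rmse"])
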
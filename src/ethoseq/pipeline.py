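"""Config-driven end-to-end runs and report rendering.

A run takes a cohort of per-second barcodes plus pellet logs (simulated
from a scenario's condition presets, or loaded from files), and produces a
report bundle: per-subject raster images, one group-average transition
heatmap per condition, a per-subject baseline-divergence table, feeding
summaries with cumulative threshold curves, a duration-vs-intake regression
panel, and a machine-readable JSON summary.  The JSON summary is the
canonical output; for a fixed config and master seed it is byte-identical
across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalogue import CONDITIONS, BehaviorCatalogue
from .ethogram import Ethogram, read_ethogram, segment_bouts, write_ethogram
from .feeding import (
    PelletLog,
    cumulative_threshold_curve,
    intake_mass,
    latency_to_threshold,
    read_pellet_log,
    write_pellet_log,
)
from .stats import duration_regression
from .transitions import (
    TransitionMatrix,
    average_matrices,
    baseline_divergence,
    count_transitions,
    extract_label_sequence,
    normalize_transitions,
    write_matrix_tsv,
)
from .simulate import SCENARIOS, make_condition_presets, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-loadable, flag-overridable."""

    outdir: str = "ethoseq_run"
    scenario: str = "female_intruder"
    food_present: bool = True
    input_dir: Optional[str] = None  # load files instead of simulating
    n_subjects: int = 16
    conditions: Sequence[str] = field(default_factory=lambda: list(CONDITIONS))
    baseline: str = "Fed"
    mode: str = "conditional"
    threshold_pellets: int = 5
    pellet_mass_g: float = 0.02
    duration_s: int = 1200
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _acquire(cfg: RunConfig):
    """Simulate or load the cohort: (subject, condition) -> (Ethogram, PelletLog)."""
    if cfg.input_dir is None:
        if cfg.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        return simulate_cohort(
            cfg.scenario,
            n_subjects=cfg.n_subjects,
            duration_s=cfg.duration_s,
            seed=cfg.seed,
            food_present=cfg.food_present,
            conditions=list(cfg.conditions),
        )
    bank = make_condition_presets(cfg.scenario, cfg.food_present)
    indir = Path(cfg.input_dir)
    out = {}
    for path in sorted(indir.glob("*.tsv")):
        e = read_ethogram(path, bank.catalogue)
        csv = path.with_suffix(".csv")
        log = read_pellet_log(csv, cfg.pellet_mass_g) if csv.exists() else PelletLog(())
        out[(e.subject_id, e.condition)] = (e, log)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``cfg.outdir``.

    Returns the JSON-serializable summary dict (also written to
    ``summary.json``).  Raises on an empty cohort or a cohort without the
    baseline condition.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _acquire(cfg)
    if not cohort:
        raise ValueError("empty cohort: no ethograms acquired")
    subjects = sorted({s for s, _ in cohort})
    conditions = [c for c in cfg.conditions if any(k[1] == c for k in cohort)]
    if cfg.baseline not in conditions:
        raise ValueError(f"baseline condition {cfg.baseline!r} missing from cohort")
    logger.info("cohort: %d subjects x %d conditions", len(subjects), len(conditions))

    # Per-subject transition matrices.
    matrices: dict[tuple[str, str], TransitionMatrix] = {}
    n_undefined = 0
    for (subject, cond), (e, _) in cohort.items():
        seq = extract_label_sequence(segment_bouts(e))
        m = normalize_transitions(
            count_transitions(seq, e.catalogue.labels), cfg.mode
        )
        if m.undefined:
            n_undefined += 1
            logger.warning("subject %s condition %s: <2 bouts, matrix undefined", subject, cond)
        matrices[(subject, cond)] = m
    logger.info("transition matrices: %d computed, %d undefined", len(matrices), n_undefined)

    # Group-average matrix per condition.
    group_avg = {
        cond: average_matrices([matrices[(s, cond)] for s in subjects])
        for cond in conditions
    }
    for cond, m in group_avg.items():
        write_matrix_tsv(m, outdir / f"matrix_{cond}.tsv")

    # Baseline divergences, one row per subject x non-baseline condition.
    div_rows = []
    for subject in subjects:
        per_cond = {c: matrices[(subject, c)] for c in conditions}
        for r in baseline_divergence(per_cond, cfg.baseline, subject):
            div_rows.append(r)
    div_df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "condition": r.condition,
                "baseline": r.baseline,
                "cosine_distance": r.distance,
            }
            for r in div_rows
        ],
        columns=["subject_id", "condition", "baseline", "cosine_distance"],
    )
    div_df.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    logger.info("divergence: %d subject-condition pairs", len(div_df))

    # Feeding metrics.
    feed_rows = []
    n_censored = 0
    latencies_by_cond: dict[str, list] = {c: [] for c in conditions}
    for (subject, cond), (e, log) in cohort.items():
        lat = latency_to_threshold(
            log, subject, cfg.threshold_pellets, censor_time_s=float(cfg.duration_s)
        )
        if not lat.reached:
            n_censored += 1
        latencies_by_cond[cond].append(lat)
        feed_rows.append(
            {
                "subject_id": subject,
                "condition": cond,
                "intake_g": round(intake_mass(log, subject), 10),
                "latency_s": round(lat.latency_s, 6),
                "reached_threshold": lat.reached,
            }
        )
    feed_df = pd.DataFrame(feed_rows).sort_values(["condition", "subject_id"])
    feed_df.to_csv(outdir / "feeding.tsv", sep="\t", index=False)
    logger.info("feeding: %d rows, %d censored latencies", len(feed_df), n_censored)

    # Duration-vs-intake regression: first interactive behavior (the
    # scenario's hallmark social behavior) against intake, pooled over the
    # cohort.
    catalogue = next(iter(cohort.values()))[0].catalogue
    interactive = [l for l in catalogue.labels if catalogue.roles[l] == "interactive"]
    regression = None
    if interactive:
        target = interactive[0]
        xs, ys = [], []
        for (subject, cond), (e, log) in cohort.items():
            xs.append(e.seconds_of(target))
            ys.append(intake_mass(log, subject))
        if len(xs) >= 3 and np.ptp(xs) > 0:
            rr = duration_regression(xs, ys)
            regression = {
                "x": f"{target}_seconds",
                "y": "intake_g",
                "slope": round(rr.slope, 10),
                "intercept": round(rr.intercept, 10),
                "r": round(rr.r, 10),
                "p": round(rr.p, 12),
                "n": rr.n,
            }

    summary = {
        "config": {
            "scenario": cfg.scenario,
            "food_present": cfg.food_present,
            "n_subjects": len(subjects),
            "conditions": list(conditions),
            "baseline": cfg.baseline,
            "mode": cfg.mode,
            "threshold_pellets": cfg.threshold_pellets,
            "pellet_mass_g": cfg.pellet_mass_g,
            "duration_s": cfg.duration_s,
            "seed": cfg.seed,
        },
        "excluded": {
            "undefined_matrices": n_undefined,
            "censored_latencies": n_censored,
        },
        "feeding": {
            cond: {
                "mean_intake_g": round(
                    float(feed_df.loc[feed_df.condition == cond, "intake_g"].mean()), 10
                ),
                "fraction_reached": round(
                    float(feed_df.loc[feed_df.condition == cond, "reached_threshold"].mean()),
                    10,
                ),
            }
            for cond in conditions
        },
        "divergence": {
            cond: {
                "mean_cosine_distance": round(
                    float(div_df.loc[div_df.condition == cond, "cosine_distance"].mean()),
                    10,
                ),
                "n": int((div_df.condition == cond).sum()),
            }
            for cond in conditions
            if cond != cfg.baseline and (div_df.condition == cond).any()
        },
        "regression": regression,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    if cfg.make_plots:
        _render_bundle(cfg, outdir, cohort, group_avg, latencies_by_cond, conditions)
    logger.info("report bundle written to %s", outdir)
    return summary


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_raster(e: Ethogram, path) -> None:
    """Barcode raster: one colored tick row per behavior, x in seconds.

    Seconds labeled NONE stay blank, matching the published raster style.
    """
    import matplotlib.pyplot as plt

    labels = e.catalogue.labels
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(labels) + 1))
    for row, label in enumerate(labels):
        spans = [
            (b.start_s, b.duration_s)
            for b in segment_bouts(e)
            if b.label == label
        ]
        if spans:
            ax.broken_barh(spans, (row - 0.4, 0.8), color=e.catalogue.colors[label])
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_ylim(-0.6, len(labels) - 0.4)
    ax.invert_yaxis()
    ax.set_xlim(0, e.duration_s)
    ax.set_xlabel("time (s)")
    ax.set_title(f"{e.subject_id} / {e.condition}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_heatmap(m: TransitionMatrix, path, title: str = "") -> None:
    """Transition heatmap on a monotone colormap: lighter = less frequent,
    darker = more frequent; axes in catalogue order."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m.values, cmap="Greys", vmin=0.0, vmax=max(m.values.max(), 1e-9))
    ax.set_xticks(range(len(m.alphabet)))
    ax.set_xticklabels(m.alphabet, rotation=45, ha="right")
    ax.set_yticks(range(len(m.alphabet)))
    ax.set_yticklabels(m.alphabet)
    ax.set_xlabel("to")
    ax.set_ylabel("from")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=f"{m.mode} frequency")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_threshold_curves(latencies_by_cond: dict, duration_s: float, path) -> None:
    """Cumulative fraction-past-threshold step curves, one per condition."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, lats in latencies_by_cond.items():
        if not lats:
            continue
        times, fracs = cumulative_threshold_curve(lats, duration_s)
        ax.step(times, fracs, where="post", label=cond)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fraction past threshold")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _render_bundle(cfg, outdir, cohort, group_avg, latencies_by_cond, conditions):
    rasters = outdir / "rasters"
    rasters.mkdir(exist_ok=True)
    for (subject, cond), (e, _) in sorted(cohort.items()):
        render_raster(e, rasters / f"{subject}_{cond}.png")
    for cond, m in group_avg.items():
        render_heatmap(m, outdir / f"heatmap_{cond}.png", title=cond)
    render_threshold_curves(
        latencies_by_cond, float(cfg.duration_s), outdir / "threshold_curves.png"
    )


def export_cohort(cohort, outdir) -> None:
    """Write a cohort to disk in the pipeline's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (subject, cond), (e, log) in sorted(cohort.items()):
        stem = outdir / f"{subject}_{cond}"
        with open(stem.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
            write_ethogram(e, fh)
        write_pellet_log(log, stem.with_suffix(".csv"))
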
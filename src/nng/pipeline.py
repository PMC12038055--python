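"""Experiment orchestration and figure-style summary tables.

Runs multi-batch simulations for any of the agent models, computes the
time-course and coordination summaries used throughout the analysis
(cumulative improvement-rate courses over a 750-step per-batch window,
spike-triggered circular variance, within-group correlation matrices, MI
time courses, cross-correlation lags), and writes everything as tidy CSVs
with a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from .bounded_rational import BRConfig, make_br_ensemble
from .baselines import RLHyperParams, make_rl_ensemble
from .config import GameConfig
from .game import BatchRecord, assign_directions, run_batch
from .synthetic import make_scripted_ensemble
from .thompson import ThompsonHyperParams, make_ensemble

WINDOW = 750  # per-batch analysis window in discrete steps

AGENT_MODELS = ("thompson", "br", "rl", "scripted")


@dataclass
class ExperimentPlan:
    agent_model: str
    config: GameConfig = field(default_factory=GameConfig)
    n_batches: int = 35
    seed: int = 0
    out_dir: Optional[str] = None
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.agent_model not in AGENT_MODELS:
            raise ValueError(f"unknown agent model {self.agent_model!r}")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def simulate_batches(plan: ExperimentPlan) -> list:
    """Run ``n_batches`` batches and return the BatchRecords.

    Thompson and bounded-rational ensembles persist across batches with a
    reset at every batch boundary (the beliefs / the annealing clock restart);
    RL and scripted ensembles are rebuilt per batch because their ground-truth
    directions follow the assignment.
    """
    rng = np.random.default_rng(plan.seed)
    cfg = plan.config
    records = []
    persistent = None
    if plan.agent_model == "thompson":
        hyper = ThompsonHyperParams(**plan.model_params) if plan.model_params else ThompsonHyperParams()
        persistent = make_ensemble(cfg, hyper, rng)
    elif plan.agent_model == "br":
        br = BRConfig(**plan.model_params) if plan.model_params else BRConfig()
        persistent = make_br_ensemble(cfg, br, rng)
    for _ in range(plan.n_batches):
        assignment = assign_directions(cfg, rng)
        if persistent is not None:
            sensors, actors = persistent
        elif plan.agent_model == "rl":
            hyper = RLHyperParams(**plan.model_params) if plan.model_params else RLHyperParams()
            sensors, actors = make_rl_ensemble(cfg, assignment, hyper, rng)
        else:
            sensors, actors = make_scripted_ensemble(assignment, rng, **plan.model_params)
        records.append(run_batch(sensors, actors, cfg, rng, assignment=assignment))
        for agent in list(sensors) + list(actors):
            agent.reset()
    return records


# ---------------------------------------------------------------------------
# Per-batch time courses


def cumulative_rate(indicators: np.ndarray, window: int = WINDOW) -> np.ndarray:
    """Cumulative mean of a binary indicator series, nan-padded to window."""
    x = np.asarray(indicators, dtype=float)[:window]
    out = np.full(window, np.nan)
    if x.size:
        out[: x.size] = np.cumsum(x) / np.arange(1, x.size + 1)
    return out


def improvement_course(batch: BatchRecord, group: str, window: int = WINDOW) -> np.ndarray:
    """Cumulative improvement-rate course over the batch's first ``window``
    steps (trials concatenated; the comparison never crosses a boundary)."""
    return cumulative_rate(batch.improvement_indicators(group), window)


def correct_response_course(batch: BatchRecord, group: str, window: int = WINDOW) -> np.ndarray:
    """Mean over players of the cumulative correct-response rate."""
    dirs = (
        batch.assignment.sensor_directions
        if group == "sensor"
        else batch.assignment.actor_directions
    )
    blocks = []
    for trial in batch.trials:
        cur = trial.cursor(group)[:-1]
        tar = trial.target(group)[:-1]
        rel = tar - cur
        d0 = np.hypot(rel[:, 0], rel[:, 1])
        cols = []
        for mu in dirs:
            stepv = np.array([np.cos(mu), np.sin(mu)])
            d1 = np.hypot(rel[:, 0] - stepv[0], rel[:, 1] - stepv[1])
            cols.append(d0 - d1 > 0.0)
        blocks.append(np.stack(cols, axis=1))
    correct = np.concatenate(blocks, axis=0)[:window]
    spikes = batch.spikes(group)[:window].astype(float)
    n = min(correct.shape[0], spikes.shape[0])
    presses = np.cumsum(spikes[:n], axis=0)
    hits = np.cumsum(spikes[:n] * correct[:n], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(presses > 0, hits / presses, np.nan)
    course = np.full(window, np.nan)
    course[:n] = np.nanmean(rate, axis=1)
    return course


def circular_variance_course(batch: BatchRecord, group: str, window: int = WINDOW) -> np.ndarray:
    """Mean over players of the cumulative spike-triggered circular variance."""
    spikes = batch.spikes(group)[:window].astype(float)
    angles = batch.stimulus_angles(group)[:window]
    valid = ~np.isnan(angles)
    cosv = np.where(valid, np.cos(angles), 0.0)
    sinv = np.where(valid, np.sin(angles), 0.0)
    trig = spikes * valid[:, None]
    counts = np.cumsum(trig, axis=0)
    cx = np.cumsum(trig * cosv[:, None], axis=0)
    sx = np.cumsum(trig * sinv[:, None], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(counts > 0, 1.0 - np.hypot(cx, sx) / np.maximum(counts, 1), np.nan)
    course = np.full(window, np.nan)
    m = var.shape[0]
    course[:m] = np.nanmean(var, axis=1)
    return course


def aggregate_courses(courses: Sequence[np.ndarray]) -> np.ndarray:
    """Across-batch nan-mean at each time index."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack(courses), axis=0)


def bootstrap_band(courses, rng, n_boot: int = 200, level: float = 0.95):
    """Bootstrap (over batches) confidence band of the across-batch mean."""
    stack = np.stack(courses)
    n = stack.shape[0]
    boots = np.empty((n_boot, stack.shape[1]))
    for k in range(n_boot):
        idx = rng.integers(n, size=n)
        with np.errstate(invalid="ignore"):
            boots[k] = np.nanmean(stack[idx], axis=0)
    lo = np.nanpercentile(boots, 100 * (1 - level) / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 + level) / 2, axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# Acceptance-style summary statistics


def late_window_mean(courses, lo: int = 500, hi: int = WINDOW) -> float:
    """Mean of the across-batch course over the final third of the window."""
    mean_course = aggregate_courses(courses)
    seg = mean_course[lo:hi]
    return float(np.nanmean(seg))


def late_improvement_rate(records, group: str, lo: int = 500, hi: int = WINDOW) -> float:
    return late_window_mean([improvement_course(b, group) for b in records], lo, hi)


def late_circular_variance(records, group: str = "actor", lo: int = 500, hi: int = WINDOW) -> float:
    """Across units, trials and batches: spike-triggered circular variance of
    the stimuli at press times, computed per trial (the target direction is
    re-drawn each trial, so pooling trials would measure the trial-direction
    spread instead of response specialisation) for trials overlapping the
    late part of the batch window."""
    values = []
    hidden = None
    for batch in records:
        offset = 0
        for trial in batch.trials:
            n = trial.n_steps
            start, stop = offset, offset + n
            offset = stop
            if stop <= lo or start >= hi:
                continue
            spikes = trial.spikes(group)
            angles = trial.stimulus_angles(group, hidden_steps=batch.config.target_hidden_steps)
            a, b = max(lo - start, 0), min(hi - start, n)
            for i in range(spikes.shape[1]):
                v = M.spike_triggered_circular_variance(spikes[a:b, i], angles[a:b])
                if not np.isnan(v):
                    values.append(v)
    return float(np.mean(values)) if values else float("nan")


def sensor_actor_lags(records, max_window: int = 10) -> np.ndarray:
    """All defined sensor-to-actor maximising lags (actor following sensor),
    one per (batch, actor, sensor) combination."""
    lags = []
    for batch in records:
        spikes_s = batch.spikes("sensor")
        spikes_a = batch.spikes("actor")
        for j in range(spikes_a.shape[1]):
            for i in range(spikes_s.shape[1]):
                lag = M.cross_correlation_max_lag(spikes_a[:, j], spikes_s[:, i], max_window)
                if not np.isnan(lag):
                    lags.append(lag)
    return np.asarray(lags)


def modal_lag(lags: np.ndarray) -> float:
    """Most frequent lag; ties resolved toward the smallest |lag|."""
    vals, counts = np.unique(np.asarray(lags), return_counts=True)
    best = counts.max()
    cand = vals[counts == best]
    return float(cand[np.argmin(np.abs(cand))])


def correlation_matrix(records, group: str) -> np.ndarray:
    """Across-batch mean action-time correlation matrix (unit diagonal)."""
    mats = []
    for batch in records:
        spikes = batch.spikes(group)
        k = spikes.shape[1]
        mat = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                c = M.action_time_correlation(spikes[:, i], spikes[:, j])
                mat[i, j] = mat[j, i] = c
        mats.append(mat)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack(mats), axis=0)


def mi_course(batch: BatchRecord, bins: int = 8, window: int = 150, stride: int = 10):
    """Sliding-window MI between the discretised sensor stimulus and the
    joint actor action over the batch."""
    angles = batch.stimulus_angles("sensor")[:WINDOW]
    symbols = M.discretize_angles(angles, bins)
    actions = M.encode_action_vectors(batch.spikes("actor")[:WINDOW])
    return M.windowed_mutual_information(symbols, actions, window=window, stride=stride)


# ---------------------------------------------------------------------------
# run_experiment / figure tables / grid search


def run_experiment(plan: ExperimentPlan, force: bool = False) -> Path:
    """Simulate, persist batch records, metric tables and a manifest."""
    if plan.out_dir is None:
        raise ValueError("plan.out_dir is required")
    out = Path(plan.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    records = simulate_batches(plan)
    for k, batch in enumerate(records):
        batch.save(out / f"batch_{k:03d}")
    figure_tables(records, out)
    manifest = {
        "plan": {
            "agent_model": plan.agent_model,
            "n_batches": plan.n_batches,
            "seed": plan.seed,
            "model_params": plan.model_params,
            "config": plan.config.to_dict(),
        },
        "config_hash": hashlib.sha256(
            json.dumps(plan.config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_truncated": int(sum(t.truncated for b in records for t in b.trials)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def figure_tables(records, out_dir) -> None:
    """Emit the per-figure summary CSVs (time courses with bootstrap bands,
    correlation matrices, MI course)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(0)
    rows = []
    for group in ("sensor", "actor"):
        for name, fn in (
            ("improvement_rate", improvement_course),
            ("correct_response_rate", correct_response_course),
            ("circular_variance", circular_variance_course),
        ):
            courses = [fn(b, group) for b in records]
            mean = aggregate_courses(courses)
            lo, hi = bootstrap_band(courses, rng)
            for t in range(0, WINDOW, 10):
                rows.append((name, group, t, mean[t], lo[t], hi[t]))
    pd.DataFrame(rows, columns=["metric", "group", "t", "mean", "ci_lo", "ci_hi"]).to_csv(
        out / "fig2_time_courses.csv", index=False
    )
    for group in ("sensor", "actor"):
        mat = correlation_matrix(records, group)
        pd.DataFrame(mat).to_csv(out / f"fig3_correlation_{group}.csv", index=False)
    mi_rows = []
    for k, batch in enumerate(records):
        centres, values = mi_course(batch)
        mi_rows.extend((k, int(c), float(v)) for c, v in zip(centres, values))
    pd.DataFrame(mi_rows, columns=["batch", "t", "mi_bits"]).to_csv(
        out / "fig4_mutual_information.csv", index=False
    )
    lags = sensor_actor_lags(records)
    pd.DataFrame({"lag": lags}).to_csv(out / "fig4_lags.csv", index=False)


def summary_statistics(records) -> dict:
    """The comparison statistics used by the hyper-parameter search."""
    lengths = [t.n_steps for b in records for t in b.trials]
    angles = np.concatenate([b.stimulus_angles("sensor")[:WINDOW] for b in records])
    actions = np.concatenate([M.encode_action_vectors(b.spikes("actor")[:WINDOW]) for b in records])
    return {
        "trajectory_length": float(np.median(lengths)),
        "improvement_rate_actor": late_improvement_rate(records, "actor"),
        "improvement_rate_sensor": late_improvement_rate(records, "sensor"),
        "mutual_information": M.mutual_information(M.discretize_angles(angles, 8), actions),
    }


def grid_search(
    space: dict,
    plan: ExperimentPlan,
    rng: np.random.Generator,
    reference: Optional[pd.DataFrame] = None,
    completion_threshold: float = 0.5,
) -> pd.DataFrame:
    """Two-step hyper-parameter search.

    Stage 1 filters parameter combinations by task completion (fraction of
    non-truncated trials); stage 2 ranks survivors by normalised distance to
    the supplied reference statistics (columns ``stat``, ``value``). Returns a
    DataFrame sorted by rank with the stage-1 completion fraction attached;
    when stage 1 leaves no survivors, the returned frame carries them all with
    ``survived = False`` and no ranking.
    """
    names = sorted(space)
    rows = []
    for combo in itertools.product(*(space[n] for n in names)):
        params = dict(zip(names, combo))
        sub = dataclasses.replace(
            plan, model_params={**plan.model_params, **params}, seed=int(rng.integers(2**31))
        )
        records = simulate_batches(sub)
        trials = [t for b in records for t in b.trials]
        completion = float(np.mean([not t.truncated for t in trials]))
        row = {**params, "completion": completion, "survived": completion >= completion_threshold}
        if row["survived"]:
            row.update(summary_statistics(records))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if reference is None or not frame["survived"].any():
        return frame.sort_values("completion", ascending=False).reset_index(drop=True)
    ref = dict(zip(reference["stat"], reference["value"]))
    def distance(row):
        if not row["survived"]:
            return np.inf
        total = 0.0
        for stat, target in ref.items():
            if stat in row and np.isfinite(row[stat]):
                scale = abs(target) if target else 1.0
                total += ((row[stat] - target) / scale) ** 2
        return total
    frame["distance"] = frame.apply(distance, axis=1)
    return frame.sort_values(["survived", "distance"], ascending=[False, True]).reset_index(drop=True)
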
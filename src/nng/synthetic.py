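"""Synthetic recordings: scripted ground-truth agents, millisecond raw-event
emission in the documented lab-like CSV layout, and the time-discretisation
procedure used for the human button-press logs.

The raw format is one row per press (player_id, group, time_ms), with
trajectories in a parallel frame-resolution CSV. Discrete time is recovered by
finding the longest interval L such that successive presses of each individual
player are at least L apart and binning events into width-L intervals anchored
at the first event (the characteristic human L was 125-130 ms).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .game import BatchRecord, Stimulus
from .geometry import angle_to_unit

DEFAULT_INTERVAL_MS = 125.0
DEGENERATE_L_CAP_MS = 500.0


@dataclass
class ScriptedAgentSpec:
    """Ground-truth response policy for metric testing.

    Presses with probability ``p`` when a unit step along the assigned
    direction would strictly reduce distance-to-target, else with probability
    ``q``; ``activity_rate`` further gates granted decision slots.
    """

    assigned_direction: float
    correct_response_probability: float = 1.0
    false_press_probability: float = 0.0
    activity_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("correct_response_probability", "false_press_probability", "activity_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def press_is_correct(spec: ScriptedAgentSpec, stimulus: Stimulus) -> bool:
    """True iff a unit step along the assigned direction strictly reduces
    the distance to the target."""
    goal = stimulus.distance * angle_to_unit(stimulus.angle)
    after = goal - angle_to_unit(spec.assigned_direction)
    return float(np.hypot(*after)) < stimulus.distance


def scripted_decide(spec: ScriptedAgentSpec, stimulus: Stimulus, rng: np.random.Generator) -> int:
    """Binary action of the scripted policy for one stimulus."""
    if rng.random() >= spec.activity_rate:
        return 0
    p = (
        spec.correct_response_probability
        if press_is_correct(spec, stimulus)
        else spec.false_press_probability
    )
    return int(rng.random() < p)


class ScriptedAgent:
    """Playable wrapper around :class:`ScriptedAgentSpec` (agent contract)."""

    def __init__(self, spec: ScriptedAgentSpec, rng: Optional[np.random.Generator] = None) -> None:
        self.spec = spec
        self.rng = rng if rng is not None else np.random.default_rng()

    def decide(self, stimulus: Optional[Stimulus]) -> int:
        if stimulus is None:
            return 0
        return scripted_decide(self.spec, stimulus, self.rng)

    def forced_idle(self) -> int:
        return 0

    def observe(self, feedback) -> None:
        pass

    def reset(self) -> None:
        pass


def make_scripted_ensemble(assignment, rng, p: float = 1.0, q: float = 0.0, activity: float = 1.0):
    """Scripted (sensor_units, actor_units) playing their true directions."""
    sensors = [
        ScriptedAgent(
            ScriptedAgentSpec(a, p, q, activity), np.random.default_rng(rng.integers(2**31))
        )
        for a in assignment.sensor_directions
    ]
    actors = [
        ScriptedAgent(
            ScriptedAgentSpec(a, p, q, activity), np.random.default_rng(rng.integers(2**31))
        )
        for a in assignment.actor_directions
    ]
    return sensors, actors


# ---------------------------------------------------------------------------
# Raw event logs


@dataclass
class RawEventLog:
    """Millisecond-resolution press events emulating the lab recording format."""

    events: pd.DataFrame  # columns: player_id, group, time_ms
    trial_boundaries_ms: list = field(default_factory=list)
    trajectories: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ev = self.events
        for pid, sub in ev.groupby("player_id"):
            t = sub["time_ms"].to_numpy()
            if (np.diff(t) <= 0).any():
                raise ValueError(f"press times of player {pid!r} are not strictly increasing")

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(directory / "events.csv", index=False)
        if self.trajectories is not None:
            self.trajectories.to_csv(directory / "trajectories.csv", index=False)

    @classmethod
    def load(cls, directory) -> "RawEventLog":
        directory = Path(directory)
        events = pd.read_csv(directory / "events.csv")
        traj_path = directory / "trajectories.csv"
        traj = pd.read_csv(traj_path) if traj_path.exists() else None
        return cls(events=events, trajectories=traj)


def emit_raw_events(
    batch: BatchRecord,
    base_interval_ms: float = DEFAULT_INTERVAL_MS,
    jitter_ms: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> RawEventLog:
    """Turn a discrete BatchRecord into a millisecond raw-event log.

    Each press at (concatenated) discrete step t becomes a timestamp
    ``t * base_interval_ms + U(-jitter, jitter)``. Jitter must be below half
    the base interval so per-player ordering survives.
    """
    if jitter_ms < 0 or jitter_ms >= base_interval_ms / 2.0:
        raise ValueError("jitter_ms must satisfy 0 <= jitter < base_interval_ms / 2")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    offset = 0
    boundaries = []
    for trial in batch.trials:
        for group, spikes in (("sensor", trial.sensor_spikes), ("actor", trial.actor_spikes)):
            steps, players = np.nonzero(spikes)
            for t, i in zip(steps, players):
                time = (offset + t) * base_interval_ms
                if jitter_ms > 0:
                    time += rng.uniform(-jitter_ms, jitter_ms)
                rows.append((f"{group[0]}{i + 1}", group, time))
        offset += trial.n_steps
        boundaries.append(offset * base_interval_ms)
    events = pd.DataFrame(rows, columns=["player_id", "group", "time_ms"])
    events = events.sort_values(["time_ms", "player_id"], kind="stable").reset_index(drop=True)
    frames = []
    offset = 0
    for k, trial in enumerate(batch.trials):
        n = trial.positions.shape[0]
        df = pd.DataFrame(
            trial.positions,
            columns=["Ss_x", "Ss_y", "Sa_x", "Sa_y", "Ta_x", "Ta_y", "Ts_x", "Ts_y"],
        )
        df.insert(0, "time_ms", (offset + np.arange(n)) * base_interval_ms)
        df.insert(0, "trial", k)
        frames.append(df)
        offset += trial.n_steps
    return RawEventLog(
        events=events,
        trial_boundaries_ms=boundaries,
        trajectories=pd.concat(frames, ignore_index=True),
    )


def estimate_interval(log: RawEventLog, cap_ms: float = DEGENERATE_L_CAP_MS) -> float:
    """Longest L such that successive presses of each individual player are
    at least L apart: the minimum over players of their minimum inter-press
    interval. Players with fewer than two presses contribute no constraint;
    if no player constrains L, the configured cap is returned."""
    gaps = []
    for _, sub in log.events.groupby("player_id"):
        t = np.sort(sub["time_ms"].to_numpy())
        if t.size >= 2:
            gaps.append(float(np.diff(t).min()))
    if not gaps:
        return cap_ms
    return min(min(gaps), cap_ms)


def discretize_time(log: RawEventLog, cap_ms: float = DEGENERATE_L_CAP_MS):
    """Recover (L, spike matrices) from a raw event log.

    Events are binned into width-L intervals anchored at the first event;
    events of distinct players falling into the same bin are treated as
    simultaneous in discrete time, and by construction of L no player has two
    presses in one bin. Returns ``(L, {"sensor": N x k, "actor": N x k})``.
    """
    if log.events.shape[0] == 0:
        raise ValueError("raw event log contains no presses")
    interval = estimate_interval(log, cap_ms)
    t0 = float(log.events["time_ms"].min())
    bins = np.floor((log.events["time_ms"].to_numpy() - t0) / interval).astype(np.int64)
    n_steps = int(bins.max()) + 1
    matrices = {}
    for group in ("sensor", "actor"):
        mask = (log.events["group"] == group).to_numpy()
        pids = sorted(log.events.loc[mask, "player_id"].unique())
        mat = np.zeros((n_steps, max(len(pids), 1)), dtype=np.int8)
        for col, pid in enumerate(pids):
            sel = mask & (log.events["player_id"] == pid).to_numpy()
            mat[bins[sel], col] = 1
        matrices[group] = mat
    return interval, matrices
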
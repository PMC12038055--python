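"""Discrete-time world dynamics of the Nested Neuron Game.

Two groups of binary decision-making units play on two screens. Actor presses
displace the cursor on both screens (population-vector sum of the actors'
assigned directions, scaled by ``step_sensor_screen`` on the sensor screen and
``step_actor_screen`` on the actor screen). Sensor presses displace the target
on the actor screen only. The sensor-screen target is externally fixed within
a trial; a trial ends when the sensor cursor enters the target disc.

Agent contract
--------------
Any agent playable by :func:`run_batch` exposes

``decide(stimulus) -> int``
    Called when the unit is granted a decision slot; ``stimulus`` is a
    :class:`Stimulus` (angle + distance of the unit's own-screen
    target-difference vector) or ``None`` when degenerate (goal reached /
    target still hidden).
``forced_idle() -> int``
    Called instead of ``decide`` when no slot is granted; must record a
    zero action in the agent's own history and return 0.
``observe(feedback) -> None``
    Called once per step after the world update with the unit's own-screen
    :class:`Feedback`.
``reset() -> None``
    Forgets learned state (called by the driver between batches).

Agents may additionally implement ``begin_step(state, assignment,
global_step)``, used by group-level controllers (the bounded-rational
network) that need the full game state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .config import GameConfig
from .geometry import (
    TWO_PI,
    DegenerateStimulusError,
    angle_to_unit,
    target_difference_angle,
    wrap_angle,
)


class Stimulus(NamedTuple):
    """Target-difference stimulus on one screen: polar angle and distance."""

    angle: float
    distance: float


@dataclass
class DirectionAssignment:
    """Assigned movement directions (radians) for the two windroses."""

    sensor_directions: np.ndarray
    actor_directions: np.ndarray

    def __post_init__(self) -> None:
        self.sensor_directions = np.asarray(self.sensor_directions, dtype=float)
        self.actor_directions = np.asarray(self.actor_directions, dtype=float)

    def to_dict(self) -> dict:
        return {
            "sensor_directions": self.sensor_directions.tolist(),
            "actor_directions": self.actor_directions.tolist(),
        }


@dataclass
class GameState:
    """Cursor and target positions of both layers at one discrete time."""

    t: int
    sensor_cursor: np.ndarray
    actor_cursor: np.ndarray
    sensor_target: np.ndarray
    actor_target: np.ndarray

    def copy(self) -> "GameState":
        return GameState(
            self.t,
            self.sensor_cursor.copy(),
            self.actor_cursor.copy(),
            self.sensor_target.copy(),
            self.actor_target.copy(),
        )

    def stimulus(self, group: str) -> Stimulus:
        """Target-difference stimulus for ``group`` in {'sensor', 'actor'}.

        Raises :class:`DegenerateStimulusError` at zero target difference.
        """
        if group == "sensor":
            cursor, target = self.sensor_cursor, self.sensor_target
        elif group == "actor":
            cursor, target = self.actor_cursor, self.actor_target
        else:
            raise ValueError(f"unknown group {group!r}")
        angle = target_difference_angle(cursor, target)
        dist = float(np.hypot(*(target - cursor)))
        return Stimulus(angle, dist)


def windrose(n: int, rng: np.random.Generator, base: float = 0.0, jitter: float = 0.0) -> np.ndarray:
    """``n`` approximately equiangular directions: exact ``2*pi/n`` spacing
    around ``base`` plus independent uniform jitter in ``+-jitter``."""
    angles = base + np.arange(n) * (TWO_PI / n)
    if jitter > 0:
        angles = angles + rng.uniform(-jitter, jitter, size=n)
    return angles % TWO_PI


def assign_directions(config: GameConfig, rng: np.random.Generator) -> DirectionAssignment:
    """Draw the two rotated windroses and a random player-to-direction map.

    The actor windrose gets a uniform base rotation; the sensor windrose is
    offset from it by a uniform draw in [30 deg, 60 deg] so that sensor and
    actor directions never coincide (jitter is +-5 deg by default).
    """
    base = rng.uniform(0.0, TWO_PI)
    actor = windrose(config.n_actors, rng, base=base, jitter=config.windrose_jitter)
    offset = rng.uniform(math.radians(30.0), math.radians(60.0))
    sensor = windrose(config.n_sensors, rng, base=base + offset, jitter=config.windrose_jitter)
    actor = actor[rng.permutation(config.n_actors)]
    sensor = sensor[rng.permutation(config.n_sensors)]
    return DirectionAssignment(sensor_directions=sensor, actor_directions=actor)


def batch_trial_angles(config: GameConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-batch set of ``trials_per_batch`` approximately equiangular
    sensor-target directions, in randomised trial order."""
    n = config.trials_per_batch
    angles = windrose(n, rng, base=rng.uniform(0.0, TWO_PI), jitter=config.windrose_jitter)
    return angles[rng.permutation(n)]


def init_trial(config: GameConfig, trial_angle: float, rng: np.random.Generator) -> GameState:
    """Initial state of one trial.

    The sensor start is sampled uniformly in a centred box; the sensor target
    sits ``start_target_distance`` away along ``trial_angle``. Actor cursor
    and target start at the screen-centre origin.
    """
    half = config.start_target_distance / 2.0
    start = rng.uniform(-half, half, size=2)
    target = start + config.start_target_distance * angle_to_unit(wrap_angle(trial_angle))
    origin = np.zeros(2)
    return GameState(
        t=0,
        sensor_cursor=start,
        actor_cursor=origin.copy(),
        sensor_target=target,
        actor_target=origin.copy(),
    )


def _population_vector(actions: np.ndarray, directions: np.ndarray) -> np.ndarray:
    active = np.flatnonzero(actions)
    if active.size == 0:
        return np.zeros(2)
    angles = directions[active]
    return np.array([np.cos(angles).sum(), np.sin(angles).sum()])


def _check_actions(actions, n: int, name: str) -> np.ndarray:
    arr = np.asarray(actions)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} entries must be binary")
    return arr.astype(np.int8)


def step(
    state: GameState,
    sensor_actions,
    actor_actions,
    assignment: DirectionAssignment,
    config: GameConfig,
) -> GameState:
    """One transition of the world.

    Actor presses move both cursors along the actor population vector
    (alpha- and beta-scaled); sensor presses move the actor target along the
    sensor population vector (gamma-scaled); the sensor target is immobile.
    """
    a_s = _check_actions(sensor_actions, config.n_sensors, "sensor_actions")
    a_a = _check_actions(actor_actions, config.n_actors, "actor_actions")
    actor_vec = _population_vector(a_a, assignment.actor_directions)
    sensor_vec = _population_vector(a_s, assignment.sensor_directions)
    return GameState(
        t=state.t + 1,
        sensor_cursor=state.sensor_cursor + config.step_sensor_screen * actor_vec,
        actor_cursor=state.actor_cursor + config.step_actor_screen * actor_vec,
        sensor_target=state.sensor_target,
        actor_target=state.actor_target + config.step_target * sensor_vec,
    )


def trial_success(state: GameState, config: GameConfig) -> bool:
    """True iff the sensor cursor is inside the target disc (boundary in)."""
    d = float(np.hypot(*(state.sensor_target - state.sensor_cursor)))
    return d <= config.target_radius


@dataclass
class Feedback:
    """Per-step own-screen feedback handed to one group's units."""

    displacement: np.ndarray
    distance_delta: float  # previous minus new distance-to-target; > 0 improved


@dataclass
class TrialRecord:
    """Trajectories and spikes of one trial.

    ``positions`` has ``n_steps + 1`` rows (state before each action plus the
    terminal state) and columns (Ss_x, Ss_y, Sa_x, Sa_y, Ta_x, Ta_y,
    Ts_x, Ts_y); ``sensor_spikes`` / ``actor_spikes`` have ``n_steps`` rows.
    """

    positions: np.ndarray
    sensor_spikes: np.ndarray
    actor_spikes: np.ndarray
    truncated: bool

    @property
    def n_steps(self) -> int:
        return self.sensor_spikes.shape[0]

    def cursor(self, group: str) -> np.ndarray:
        return self.positions[:, 0:2] if group == "sensor" else self.positions[:, 2:4]

    def target(self, group: str) -> np.ndarray:
        return self.positions[:, 6:8] if group == "sensor" else self.positions[:, 4:6]

    def spikes(self, group: str) -> np.ndarray:
        return self.sensor_spikes if group == "sensor" else self.actor_spikes

    def stimulus_angles(self, group: str, hidden_steps: int = 0) -> np.ndarray:
        """Per-action-step target-difference angle; nan where degenerate
        (and, for the actor group, during the initial hidden period)."""
        cur = self.cursor(group)[:-1]
        tar = self.target(group)[:-1]
        diff = tar - cur
        out = np.arctan2(diff[:, 1], diff[:, 0]) % TWO_PI
        out[np.hypot(diff[:, 0], diff[:, 1]) == 0.0] = np.nan
        if group == "actor" and hidden_steps > 0:
            out[: min(hidden_steps, out.shape[0])] = np.nan
        return out

    def improvement_indicators(self, group: str) -> np.ndarray:
        """Binary per-step indicator of strict distance-to-target reduction."""
        cur = self.cursor(group)
        tar = self.target(group)
        d = np.hypot(*(tar - cur).T)
        return (d[:-1] - d[1:] > 0.0).astype(np.int8)


@dataclass
class BatchRecord:
    """All trials played under one direction assignment."""

    trials: list
    assignment: DirectionAssignment
    config: GameConfig
    trial_angles: np.ndarray = field(default=None)

    @property
    def n_steps(self) -> int:
        return sum(t.n_steps for t in self.trials)

    def spikes(self, group: str) -> np.ndarray:
        return np.concatenate([t.spikes(group) for t in self.trials], axis=0)

    def stimulus_angles(self, group: str) -> np.ndarray:
        hid = self.config.target_hidden_steps
        return np.concatenate(
            [t.stimulus_angles(group, hidden_steps=hid) for t in self.trials]
        )

    def improvement_indicators(self, group: str) -> np.ndarray:
        return np.concatenate([t.improvement_indicators(group) for t in self.trials])

    @property
    def trial_bounds(self) -> list:
        bounds, start = [], 0
        for t in self.trials:
            bounds.append((start, start + t.n_steps))
            start += t.n_steps
        return bounds

    def save(self, directory) -> None:
        """Write trajectories.csv, spikes.csv and meta.json into a directory."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pos_frames, spk_frames = [], []
        for k, tr in enumerate(self.trials):
            n = tr.positions.shape[0]
            pos = pd.DataFrame(
                tr.positions,
                columns=["Ss_x", "Ss_y", "Sa_x", "Sa_y", "Ta_x", "Ta_y", "Ts_x", "Ts_y"],
            )
            pos.insert(0, "t", np.arange(n))
            pos.insert(0, "trial", k)
            pos_frames.append(pos)
            spk = pd.DataFrame(
                np.concatenate([tr.sensor_spikes, tr.actor_spikes], axis=1),
                columns=[f"s{i + 1}" for i in range(tr.sensor_spikes.shape[1])]
                + [f"a{i + 1}" for i in range(tr.actor_spikes.shape[1])],
            )
            spk.insert(0, "t", np.arange(tr.n_steps))
            spk.insert(0, "trial", k)
            spk_frames.append(spk)
        pd.concat(pos_frames).to_csv(directory / "trajectories.csv", index=False)
        pd.concat(spk_frames).to_csv(directory / "spikes.csv", index=False)
        meta = {
            "assignment": self.assignment.to_dict(),
            "config": self.config.to_dict(),
            "trial_angles": None if self.trial_angles is None else list(map(float, self.trial_angles)),
            "truncated": [bool(t.truncated) for t in self.trials],
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "BatchRecord":
        import pandas as pd

        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        pos = pd.read_csv(directory / "trajectories.csv")
        spk = pd.read_csv(directory / "spikes.csv")
        config = GameConfig.from_dict(meta["config"])
        n_s, n_a = config.n_sensors, config.n_actors
        trials = []
        for k, truncated in enumerate(meta["truncated"]):
            p = pos[pos["trial"] == k].drop(columns=["trial", "t"]).to_numpy(float)
            s = spk[spk["trial"] == k].drop(columns=["trial", "t"]).to_numpy(np.int8)
            trials.append(TrialRecord(p, s[:, :n_s], s[:, n_s : n_s + n_a], truncated))
        return cls(
            trials=trials,
            assignment=DirectionAssignment(**meta["assignment"]),
            config=config,
            trial_angles=None
            if meta.get("trial_angles") is None
            else np.asarray(meta["trial_angles"]),
        )


def _query(agent, stimulus: Optional[Stimulus], granted: bool) -> int:
    if not granted:
        return int(agent.forced_idle())
    return int(agent.decide(stimulus))


def run_trial(
    sensor_agents: Sequence,
    actor_agents: Sequence,
    config: GameConfig,
    assignment: DirectionAssignment,
    trial_angle: float,
    rng: np.random.Generator,
    global_step: list,
) -> TrialRecord:
    """Play a single trial; agents keep their learned state."""
    state = init_trial(config, trial_angle, rng)
    n_s, n_a = config.n_sensors, config.n_actors
    positions = [_pack_positions(state)]
    spikes_s, spikes_a = [], []
    truncated = False
    agents = list(sensor_agents) + list(actor_agents)
    while True:
        if trial_success(state, config):
            break
        if state.t >= config.max_steps_per_trial:
            truncated = True
            break
        for agent in agents:
            hook = getattr(agent, "begin_step", None)
            if hook is not None:
                hook(state, assignment, global_step[0])
        try:
            stim_s = state.stimulus("sensor")
        except DegenerateStimulusError:
            stim_s = None
        if state.t < config.target_hidden_steps:
            stim_a = None
        else:
            try:
                stim_a = state.stimulus("actor")
            except DegenerateStimulusError:
                stim_a = None
        granted = rng.random(n_s + n_a) < config.decision_availability
        a_s = np.fromiter(
            (_query(ag, stim_s, g) for ag, g in zip(sensor_agents, granted[:n_s])),
            dtype=np.int8,
            count=n_s,
        )
        a_a = np.fromiter(
            (_query(ag, stim_a, g) for ag, g in zip(actor_agents, granted[n_s:])),
            dtype=np.int8,
            count=n_a,
        )
        new_state = step(state, a_s, a_a, assignment, config)
        d_s0 = float(np.hypot(*(state.sensor_target - state.sensor_cursor)))
        d_s1 = float(np.hypot(*(new_state.sensor_target - new_state.sensor_cursor)))
        d_a0 = float(np.hypot(*(state.actor_target - state.actor_cursor)))
        d_a1 = float(np.hypot(*(new_state.actor_target - new_state.actor_cursor)))
        fb_s = Feedback(new_state.sensor_cursor - state.sensor_cursor, d_s0 - d_s1)
        fb_a = Feedback(new_state.actor_cursor - state.actor_cursor, d_a0 - d_a1)
        for ag in sensor_agents:
            ag.observe(fb_s)
        for ag in actor_agents:
            ag.observe(fb_a)
        spikes_s.append(a_s)
        spikes_a.append(a_a)
        state = new_state
        positions.append(_pack_positions(state))
        global_step[0] += 1
    if not spikes_s:  # success at step 0 cannot happen (radius < distance)
        spikes_s = [np.zeros(n_s, np.int8)]
        spikes_a = [np.zeros(n_a, np.int8)]
        positions.append(_pack_positions(state))
    return TrialRecord(
        positions=np.asarray(positions, dtype=float),
        sensor_spikes=np.asarray(spikes_s, dtype=np.int8),
        actor_spikes=np.asarray(spikes_a, dtype=np.int8),
        truncated=truncated,
    )


def _pack_positions(state: GameState) -> np.ndarray:
    return np.concatenate(
        [state.sensor_cursor, state.actor_cursor, state.actor_target, state.sensor_target]
    )


def run_batch(
    sensor_agents: Sequence,
    actor_agents: Sequence,
    config: GameConfig,
    rng: np.random.Generator,
    assignment: Optional[DirectionAssignment] = None,
) -> BatchRecord:
    """Play ``trials_per_batch`` trials under one direction assignment.

    Each unit is granted a decision slot independently with probability
    ``decision_availability`` per step; otherwise its action is 0. Learned
    agent state persists across the batch (the caller resets agents between
    batches). Trials exceeding ``max_steps_per_trial`` are truncated and
    flagged.
    """
    if assignment is None:
        assignment = assign_directions(config, rng)
    angles = batch_trial_angles(config, rng)
    global_step = [0]
    trials = [
        run_trial(sensor_agents, actor_agents, config, assignment, ang, rng, global_step)
        for ang in angles
    ]
    return BatchRecord(trials=trials, assignment=assignment, config=config, trial_angles=angles)
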
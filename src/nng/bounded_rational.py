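"""Loopy two-layer network of bounded-rational binary decision-makers.

Each unit transforms its prior over {idle, press} into a posterior
``P(x) ~ p(x) * exp(beta * U_eff(x))`` and samples from it; ``beta``
interpolates between random behaviour (beta -> 0) and a fully rational
chooser (beta -> infinity). Learning is modelled descriptively as annealing
``beta`` from near zero to its target value over the early part of each
batch: the ensemble starts out noisy and becomes precise.

The effective utility of a unit combines the one-step task utility on its
own layer (expected reduction of its own distance-to-target, mean-field over
the other units of its layer) with a certainty-equivalent value of the
immediately downstream units: for a sensor, the (1/beta_j) * log-expectation
of the sensor-layer gain of each actor j's press, taken under actor j's
exponentially tilted response to the world as moved by the sensor's candidate
action. In the beta_j -> 0 limit the certainty equivalent degenerates to the
prior-expected utility.

At every game step the network produces a fresh *rollout*: ``2 * depth``
alternating group decisions (sensor, actor, sensor, ...), one per simulated
game step, starting from the current true world state. A sliding window of
``depth`` live rollouts is kept, and the game action at time t is drawn
uniformly among the candidate group decisions the live rollouts hold for
time t (sensor candidates sit at even rollout offsets, actor candidates at
odd offsets, so a window of 4 holds two candidates per group).
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import GameConfig
from .game import DirectionAssignment, GameState, Stimulus
from .geometry import TWO_PI

logger = logging.getLogger(__name__)

_BETA_EPS = 1e-9


@dataclass
class BRConfig:
    """Hyper-parameters of the bounded-rational network."""

    depth: int = 4
    beta_target: float = 2.3
    beta_min: float = 0.05
    ramp_steps: int = 500
    stimulus_bins: int = 8
    prior: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.beta_target <= 0:
            raise ValueError("beta_target must be > 0")
        if self.stimulus_bins < 4:
            raise ValueError("stimulus_bins must be >= 4")
        if not 0 < self.prior < 1:
            raise ValueError("prior must be in (0, 1)")


def discretize_stimulus(angle: Optional[float], bins: int):
    """Circular bin index of a stimulus angle; equal-width bins with bin 0
    centred at angle 0. ``None``/nan (goal reached) maps to ``None``."""
    if angle is None or (isinstance(angle, float) and math.isnan(angle)):
        return None
    width = TWO_PI / bins
    return int(math.floor((angle % TWO_PI) / width + 0.5)) % bins


def bin_center(bin_index: int, bins: int) -> float:
    return (bin_index * TWO_PI / bins) % TWO_PI


def anneal_beta(game_time: int, config: BRConfig) -> float:
    """Linear ramp from ``beta_min`` at t = 0 to ``beta_target`` at
    ``ramp_steps``; constant afterwards."""
    if game_time >= config.ramp_steps:
        return config.beta_target
    frac = game_time / config.ramp_steps
    return config.beta_min + (config.beta_target - config.beta_min) * frac


def node_posterior(prior: float, beta: float, u0: float, u1: float) -> float:
    """Posterior press probability p(1) ~ p0(1) * exp(beta * U(1)), in log
    space. beta = 0 returns the prior."""
    if beta <= _BETA_EPS:
        return prior
    a0 = math.log(1.0 - prior) + beta * u0
    a1 = math.log(prior) + beta * u1
    m = max(a0, a1)
    e0, e1 = math.exp(a0 - m), math.exp(a1 - m)
    return e1 / (e0 + e1)


def certainty_equivalent(probs, beta: float, values) -> float:
    """(1/beta) * log E_p[exp(beta * V)]; the beta -> 0 limit is E_p[V]."""
    probs = np.asarray(probs, dtype=float)
    values = np.asarray(values, dtype=float)
    if beta <= _BETA_EPS:
        return float(probs @ values)
    m = float(values.max())
    return m + math.log(float(probs @ np.exp(beta * (values - m)))) / beta


def _unit_vectors(angles: np.ndarray) -> np.ndarray:
    return np.stack([np.cos(angles), np.sin(angles)], axis=1)


def sensor_effective_utilities(
    sim: dict,
    dirs_s: np.ndarray,
    dirs_a: np.ndarray,
    config: GameConfig,
    br: BRConfig,
    beta: float,
    p_sensor: np.ndarray,
) -> np.ndarray:
    """Per-sensor effective utilities, shape (n_sensors, 2).

    A sensor press cannot move the sensor layer within one step, so its base
    utility vanishes; the candidate action is valued entirely through the
    anticipated actor response. The sensor observes the world through the
    discretized target-difference angle.
    """
    n_s = dirs_s.shape[0]
    n_a = dirs_a.shape[0]
    ss, ts, sa, ta = sim["Ss"], sim["Ts"], sim["Sa"], sim["Ta"]
    diff = ts - ss
    ds = math.hypot(diff[0], diff[1])
    out = np.zeros((n_s, 2))
    if ds == 0.0:
        return out
    psi_bin = discretize_stimulus(math.atan2(diff[1], diff[0]) % TWO_PI, br.stimulus_bins)
    psi_c = bin_center(psi_bin, br.stimulus_bins)
    goal = np.array([math.cos(psi_c), math.sin(psi_c)]) * ds  # target seen through psi-hat
    # sensor-layer gain of each actor's press (independent of sensor action),
    # in per-press units so the printed beta scale is meaningful
    gain = (ds - np.hypot(*(goal[None, :] - config.step_sensor_screen * dirs_a).T)) / config.step_sensor_screen
    for i in range(n_s):
        others = config.step_target * (
            (p_sensor @ dirs_s) - p_sensor[i] * dirs_s[i]
        )
        for x in (0, 1):
            ta_x = ta + others + (config.step_target * dirs_s[i] if x else 0.0)
            rel = ta_x - sa
            da0 = math.hypot(rel[0], rel[1])
            da1 = np.hypot(*(rel[None, :] - config.step_actor_screen * dirs_a).T)
            # actor j's own one-step utility of pressing, per-press units
            u_press = (da0 - da1) / config.step_actor_screen
            total = 0.0
            for j in range(n_a):
                q1 = node_posterior(br.prior, beta, 0.0, float(u_press[j]))
                total += certainty_equivalent(
                    np.array([1.0 - q1, q1]), beta, np.array([0.0, float(gain[j])])
                )
            out[i, x] = total
    return out


def actor_effective_utilities(
    sim: dict,
    dirs_a: np.ndarray,
    config: GameConfig,
    beta: float,
    p_actor: np.ndarray,
) -> np.ndarray:
    """Per-actor effective utilities, shape (n_actors, 2): the expected
    one-step reduction of the actor-layer distance, with the other actors at
    their current mean displacement. (The sensor layer's anticipated response
    is action-independent within one step and adds a constant.)"""
    n_a = dirs_a.shape[0]
    sa, ta = sim["Sa"], sim["Ta"]
    out = np.zeros((n_a, 2))
    mean_disp = config.step_actor_screen * (p_actor @ dirs_a)
    for j in range(n_a):
        base = sa + mean_disp - config.step_actor_screen * p_actor[j] * dirs_a[j]
        rel = ta - base
        d0 = math.hypot(rel[0], rel[1])
        own = config.step_actor_screen * dirs_a[j]
        d1 = math.hypot(rel[0] - own[0], rel[1] - own[1])
        out[j, 0] = 0.0
        out[j, 1] = (d0 - d1) / config.step_actor_screen
    return out


@dataclass
class Rollout:
    """Alternating group decisions, one per simulated game step."""

    start: int
    sensor_decisions: np.ndarray  # depth x n_sensors
    actor_decisions: np.ndarray  # depth x n_actors

    def to_dict(self) -> dict:
        """JSON-ready trace of the rollout (for inspection and tests)."""
        return {
            "start": self.start,
            "sensor_decisions": self.sensor_decisions.tolist(),
            "actor_decisions": self.actor_decisions.tolist(),
        }

    def candidate(self, offset: int):
        """Group decision vector scheduled at ``start + offset``; sensor
        vectors occupy even offsets, actor vectors odd offsets."""
        if offset < 0:
            return None
        group = "sensor" if offset % 2 == 0 else "actor"
        idx = offset // 2
        arr = self.sensor_decisions if group == "sensor" else self.actor_decisions
        if idx >= arr.shape[0]:
            return None
        return group, arr[idx]


class BRNetwork:
    """Shared decision network behind a group of :class:`BRUnit` views."""

    def __init__(
        self,
        game_config: GameConfig,
        br_config: Optional[BRConfig] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.game_config = game_config
        self.config = br_config or BRConfig()
        self.rng = rng if rng is not None else np.random.default_rng()
        self.reset()

    def reset(self) -> None:
        self.batch_time = 0
        self._last_step = None
        self._rollouts: deque = deque(maxlen=self.config.depth)
        self._actions = {"sensor": None, "actor": None}
        self._dirs = None

    # ------------------------------------------------------------------
    def begin_step(self, state: GameState, assignment: DirectionAssignment, global_step: int) -> None:
        if global_step == self._last_step:
            return
        self._last_step = global_step
        if state.t == 0:
            self._rollouts.clear()
        if self._dirs is None or self._dirs[2] is not assignment:
            self._dirs = (
                _unit_vectors(assignment.sensor_directions),
                _unit_vectors(assignment.actor_directions),
                assignment,
            )
        beta = anneal_beta(self.batch_time, self.config)
        self.batch_time += 1
        self._rollouts.append(self.rollout(state, beta, global_step))
        self._select_actions(state, beta, global_step)

    def rollout(self, state: GameState, beta: float, start: int) -> Rollout:
        cfg, br = self.game_config, self.config
        dirs_s, dirs_a, _ = self._dirs
        sim = {
            "Ss": state.sensor_cursor.copy(),
            "Ts": state.sensor_target.copy(),
            "Sa": state.actor_cursor.copy(),
            "Ta": state.actor_target.copy(),
        }
        p_s = np.full(cfg.n_sensors, br.prior)
        p_a = np.full(cfg.n_actors, br.prior)
        dec_s = np.zeros((br.depth, cfg.n_sensors), dtype=np.int8)
        dec_a = np.zeros((br.depth, cfg.n_actors), dtype=np.int8)
        for k in range(br.depth):
            u_s = sensor_effective_utilities(sim, dirs_s, dirs_a, cfg, br, beta, p_s)
            for i in range(cfg.n_sensors):
                p_s[i] = node_posterior(br.prior, beta, u_s[i, 0], u_s[i, 1])
            dec_s[k] = self.rng.random(cfg.n_sensors) < p_s
            sim["Ta"] = sim["Ta"] + cfg.step_target * (dec_s[k] @ dirs_s)
            u_a = actor_effective_utilities(sim, dirs_a, cfg, beta, p_a)
            for j in range(cfg.n_actors):
                p_a[j] = node_posterior(br.prior, beta, u_a[j, 0], u_a[j, 1])
            dec_a[k] = self.rng.random(cfg.n_actors) < p_a
            move = dec_a[k] @ dirs_a
            sim["Sa"] = sim["Sa"] + cfg.step_actor_screen * move
            sim["Ss"] = sim["Ss"] + cfg.step_sensor_screen * move
        return Rollout(start=start, sensor_decisions=dec_s, actor_decisions=dec_a)

    def _select_actions(self, state: GameState, beta: float, global_step: int) -> None:
        candidates = {"sensor": [], "actor": []}
        for ro in self._rollouts:
            cand = ro.candidate(global_step - ro.start)
            if cand is not None:
                candidates[cand[0]].append(cand[1])
        chosen = {}
        for group in ("sensor", "actor"):
            options = candidates[group]
            if options:
                chosen[group] = options[int(self.rng.integers(len(options)))]
            else:
                chosen[group] = self._fresh_sample(group, state, beta)
                logger.debug("no %s candidates at step %d; fresh posterior sample", group, global_step)
        self._actions = chosen

    def _fresh_sample(self, group: str, state: GameState, beta: float) -> np.ndarray:
        cfg, br = self.game_config, self.config
        dirs_s, dirs_a, _ = self._dirs
        sim = {
            "Ss": state.sensor_cursor,
            "Ts": state.sensor_target,
            "Sa": state.actor_cursor,
            "Ta": state.actor_target,
        }
        if group == "sensor":
            p = np.full(cfg.n_sensors, br.prior)
            u = sensor_effective_utilities(sim, dirs_s, dirs_a, cfg, br, beta, p)
        else:
            p = np.full(cfg.n_actors, br.prior)
            u = actor_effective_utilities(sim, dirs_a, cfg, beta, p)
        post = np.array([node_posterior(br.prior, beta, u[i, 0], u[i, 1]) for i in range(u.shape[0])])
        return (self.rng.random(post.shape[0]) < post).astype(np.int8)

    def action(self, group: str, index: int) -> int:
        return int(self._actions[group][index])


def sample_game_action(rollouts, game_time: int, rng: np.random.Generator):
    """Uniform draw of (sensor vector, actor vector) among the candidates the
    given rollouts hold for ``game_time``; raises if either set is empty."""
    candidates = {"sensor": [], "actor": []}
    for ro in rollouts:
        cand = ro.candidate(game_time - ro.start)
        if cand is not None:
            candidates[cand[0]].append(cand[1])
    out = []
    for group in ("sensor", "actor"):
        options = candidates[group]
        if not options:
            raise ValueError(f"no {group} candidates at time {game_time}")
        out.append(options[int(rng.integers(len(options)))])
    return tuple(out)


class BRUnit:
    """Per-unit view onto a shared :class:`BRNetwork` (agent contract)."""

    def __init__(self, network: BRNetwork, group: str, index: int) -> None:
        self.network = network
        self.group = group
        self.index = index

    def begin_step(self, state, assignment, global_step) -> None:
        self.network.begin_step(state, assignment, global_step)

    def decide(self, stimulus: Optional[Stimulus]) -> int:
        if stimulus is None:
            return 0
        return self.network.action(self.group, self.index)

    def forced_idle(self) -> int:
        return 0

    def observe(self, feedback) -> None:  # descriptive model: no learning
        pass

    def reset(self) -> None:
        self.network.reset()


def make_br_ensemble(
    game_config: GameConfig,
    br_config: Optional[BRConfig] = None,
    rng: Optional[np.random.Generator] = None,
):
    """(sensor_units, actor_units) sharing one decision network."""
    net = BRNetwork(game_config, br_config, rng)
    sensors = [BRUnit(net, "sensor", i) for i in range(game_config.n_sensors)]
    actors = [BRUnit(net, "actor", j) for j in range(game_config.n_actors)]
    return sensors, actors
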
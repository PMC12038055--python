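"""Model-free tabular reinforcement-learning units (negative-result baseline).

Each unit keeps a small value table over (discretised stimulus bin, action)
and acts epsilon-greedily. Updates spread the per-step reward (the one-step
reduction of the unit's own-layer distance-to-target) over the last few
decision slots with lagged eligibility weights — the model-free analogue of
the Bayesian units' extended sensitive period.

This learner solves the actor layer (immediate, if noisy, action
consequences) but fails on the sensor layer, whose reward signal is delayed
and scrambled by the actor group's imperfect responses; pretraining the
sensor units with a modest number of noiseless observations (actors assumed
to react perfectly) rescues it. The unit design is a deliberately simple
stand-in exhibiting this dichotomy, not a replication of any specific prior
architecture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .game import Stimulus
from .geometry import TWO_PI, angle_to_unit
from .metrics import discretize_angles
from .thompson import DEFAULT_ALPHA_WEIGHTS


@dataclass
class RLHyperParams:
    bins: int = 360  # 1-degree stimulus resolution, as in the response-profile probes
    learning_rate: float = 0.1
    epsilon: float = 0.1
    init_noise: float = 0.05
    eligibility_weights: tuple = DEFAULT_ALPHA_WEIGHTS

    def __post_init__(self) -> None:
        if self.bins < 4:
            raise ValueError("bins must be >= 4")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")


class RLUnit:
    """Tabular two-action contextual learner (agent contract)."""

    def __init__(
        self,
        assigned_direction: float,
        hyper: Optional[RLHyperParams] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.hyper = hyper or RLHyperParams()
        self.assigned_direction = assigned_direction % TWO_PI
        self.rng = rng if rng is not None else np.random.default_rng()
        # tiny random init breaks the tie toward idling: an untrained unit
        # responds to about half of the stimulus bins (chance level), which
        # keeps the game dynamic enough for the actor layer to learn
        self.values = self.rng.uniform(0.0, self.hyper.init_noise, (self.hyper.bins, 2))
        self.counts = np.ones((self.hyper.bins, 2))
        self._history: list = []  # (bin or None, action, was_decision_slot)

    # -- acting ------------------------------------------------------------
    def _bin(self, angle: float) -> int:
        return int(discretize_angles(np.array([angle]), self.hyper.bins)[0])

    def greedy_action(self, bin_index: int) -> int:
        v0, v1 = self.values[bin_index]
        return int(v1 > v0)  # exact tie -> idle

    def decide(self, stimulus: Optional[Stimulus]) -> int:
        if stimulus is None:
            self._history.append((None, 0, True))
            self._trim()
            return 0
        angle = stimulus.angle if isinstance(stimulus, Stimulus) else float(stimulus)
        b = self._bin(angle)
        if self.rng.random() < self.hyper.epsilon:
            action = int(self.rng.random() < 0.5)
        else:
            action = self.greedy_action(b)
        self._history.append((b, action, True))
        self._trim()
        return action

    def forced_idle(self) -> int:
        self._history.append((None, 0, False))
        self._trim()
        return 0

    def _trim(self) -> None:
        w = len(self.hyper.eligibility_weights)
        if len(self._history) > w:
            del self._history[0]

    # -- learning ----------------------------------------------------------
    def observe(self, feedback) -> None:
        """Binary improvement reward spread over the last few decision slots.

        The reward is 1 when the unit's own-layer distance-to-target strictly
        decreased this step, else 0. This is the model-free learner's whole
        problem: on the sensor layer the indicator fires mostly through the
        other players' actions, so pressing and idling earn almost the same
        reward and the value table random-walks at chance.
        """
        reward = 1.0 if float(feedback.distance_delta) > 0.0 else 0.0
        weights = self.hyper.eligibility_weights
        for lag in range(min(len(weights), len(self._history))):
            b, action, was_slot = self._history[-1 - lag]
            if not was_slot or b is None:
                continue
            # adaptive (sample-average) learning rate: the cell tracks the
            # mean reward of that action in that stimulus bin; the step size
            # shrinks with the effective visit count
            self.counts[b, action] += weights[lag]
            self.values[b, action] += (
                weights[lag] / self.counts[b, action] * (reward - self.values[b, action])
            )

    def reset(self) -> None:
        self.values = self.rng.uniform(0.0, self.hyper.init_noise, self.values.shape)
        self.counts = np.ones(self.values.shape)
        self._history = []

    # -- probing ------------------------------------------------------------
    def probe_actions(self, angles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Frozen-policy batched decisions (no history, no learning)."""
        bins = discretize_angles(np.asarray(angles, dtype=float), self.hyper.bins)
        greedy = (self.values[bins, 1] > self.values[bins, 0]).astype(np.int8)
        explore = rng.random(bins.shape[0]) < self.hyper.epsilon
        coin = (rng.random(bins.shape[0]) < 0.5).astype(np.int8)
        return np.where(explore, coin, greedy)


def rl_decide(unit: RLUnit, psi_bin: int, rng: np.random.Generator) -> int:
    """Epsilon-greedy action for a stimulus bin (functional form)."""
    if rng.random() < unit.hyper.epsilon:
        return int(rng.random() < 0.5)
    return unit.greedy_action(psi_bin)


def rl_update(unit: RLUnit, bin_history, action_history, reward_history) -> None:
    """Replay a recorded episode through the lagged delta-rule update.

    ``value(psi_t-l, a_t-l) += w[l] / count * (r_t - value)`` for each step t and
    lag l; histories are aligned, oldest first, and every entry counts as a
    granted decision slot.
    """
    weights = unit.hyper.eligibility_weights
    n = len(reward_history)
    for t in range(n):
        r = float(reward_history[t])
        for lag in range(min(len(weights), t + 1)):
            b, a = bin_history[t - lag], action_history[t - lag]
            unit.counts[b, a] += weights[lag]
            unit.values[b, a] += weights[lag] / unit.counts[b, a] * (r - unit.values[b, a])


def pretrain_noiseless(
    units: Sequence[RLUnit],
    n: int = 150,
    rng: Optional[np.random.Generator] = None,
    step: float = 8.0,
    probe_distance: float = 100.0,
) -> None:
    """Pretrain sensor units on noiseless stimulus-action-reward triples.

    Each observation presents a uniform stimulus angle and a fair-coin action;
    the reward assumes the actor group reacts perfectly, i.e. a press
    effectively displaces the cursor by ``step`` along the unit's own assigned
    direction, with no interference from other units.
    """
    rng = rng if rng is not None else np.random.default_rng()
    for unit in units:
        mu = angle_to_unit(unit.assigned_direction)
        for _ in range(n):
            psi = rng.uniform(0.0, TWO_PI)
            action = int(rng.random() < 0.5)
            if action:
                goal = probe_distance * angle_to_unit(psi)
                improved = probe_distance - float(np.hypot(*(goal - step * mu))) > 0.0
                reward = 1.0 if improved else 0.0
            else:
                reward = 0.0  # nothing moves without a press in the noiseless world
            b = unit._bin(psi)
            unit.counts[b, action] += 1.0
            unit.values[b, action] += (reward - unit.values[b, action]) / unit.counts[b, action]


def response_profile_histogram(
    agent,
    n_stimuli: int = 72000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """360-bin polar activation histogram of a frozen agent.

    Presents ``n_stimuli`` stimuli uniformly distributed over all directions
    and returns, per 1-degree bin, the percentage of probes answered with a
    press (100 = always active). The agent must expose ``probe_actions``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    angles = rng.uniform(0.0, TWO_PI, size=n_stimuli)
    actions = np.asarray(agent.probe_actions(angles, rng))
    deg = np.floor(np.degrees(angles)).astype(int) % 360
    pressed = np.bincount(deg, weights=actions, minlength=360)
    total = np.bincount(deg, minlength=360)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * pressed / np.maximum(total, 1)
    return pct


def profile_alignment(histogram_pct: np.ndarray, assigned_direction: float) -> tuple:
    """Resultant length of the activation profile and the cosine of the gap
    between its circular mean and the assigned direction.

    Returns ``(resultant, cos_gap)``; a specialised unit has a large
    resultant with ``cos_gap`` near 1, a chance-level responder has a small
    resultant.
    """
    h = np.asarray(histogram_pct, dtype=float)
    angles = np.radians(np.arange(360) + 0.5)
    total = h.sum()
    if total <= 0:
        return 0.0, 0.0
    mx = float((h * np.cos(angles)).sum() / total)
    my = float((h * np.sin(angles)).sum() / total)
    r = math.hypot(mx, my)
    if r < 1e-12:
        return r, 0.0
    mean_angle = math.atan2(my, mx)
    return r, math.cos(mean_angle - assigned_direction)


def alignment_permutation_p(
    histogram_pct: np.ndarray,
    assigned_direction: float,
    rng: np.random.Generator,
    n_perm: int = 999,
) -> float:
    """Permutation p-value for directional concentration at the assigned
    direction: the observed |resultant component along the assigned
    direction| against a null that shuffles the per-degree activation rates
    across bins (a direction-blind responder with the same rate histogram)."""
    h = np.asarray(histogram_pct, dtype=float)
    r, cos_gap = profile_alignment(h, assigned_direction)
    observed = abs(r * cos_gap)
    null = np.empty(n_perm)
    for k in range(n_perm):
        r_n, cos_n = profile_alignment(rng.permutation(h), assigned_direction)
        null[k] = abs(r_n * cos_n)
    return float((1 + (null >= observed).sum()) / (n_perm + 1))


def save_histogram_csv(histogram_pct: np.ndarray, path) -> None:
    """Write a 360-bin response profile as CSV (bin_deg, activation_pct)."""
    import pandas as pd

    pd.DataFrame(
        {"bin_deg": np.arange(360), "activation_pct": np.asarray(histogram_pct, float)}
    ).to_csv(path, index=False)


def make_rl_ensemble(config, assignment, hyper: Optional[RLHyperParams] = None, rng=None):
    """Fresh (sensor_units, actor_units) with the true assigned directions
    recorded on each unit (used for rewards in pretraining and analysis; the
    policy itself never reads them)."""
    rng = rng if rng is not None else np.random.default_rng()
    hyper = hyper or RLHyperParams()
    sensors = [
        RLUnit(a, hyper, np.random.default_rng(rng.integers(2**31)))
        for a in assignment.sensor_directions
    ]
    actors = [
        RLUnit(a, hyper, np.random.default_rng(rng.integers(2**31)))
        for a in assignment.actor_directions
    ]
    return sensors, actors
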
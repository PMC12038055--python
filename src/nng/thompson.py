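"""Thompson-sampling decision units with von Mises beliefs.

Each unit holds a directional belief about the consequence of its own press,
summarised by the weighted resultant ``a + b*i = sum_t alpha(t) * exp(i*psi_t)``
with resultant length ``R``, resultant angle ``Theta`` and accumulated
observation weight ``T``. Before acting, the unit draws a von Mises parameter
pair (mu, kappa) from the joint posterior

    p(mu, kappa | R, Theta, T) = exp(kappa * R * cos(Theta - mu))
                                 / (K(R, T) * I0(kappa)**T),

computes the expected activation utility f = pi/2 - E[angular distance between
the stimulus and the believed displacement direction], and presses with
probability sigmoid(rho * f), preceded by an epsilon-greedy coin flip.

Observations are derived from the per-step net displacement of the unit's
own-screen cursor, weighted by a lagged learning rate alpha(t) over the
unit's own last three actions (the "extended sensitive period"): idle units
learn nothing, and an active unit keeps learning for two further steps,
which is what lets sensor units credit the delayed reaction of the actor
group. Because every unit watches the same cursor, the raw displacement is
dominated by the group's joint movement; each unit therefore credits the
*contrast* between the observed movement direction and its running estimate
of the ambient movement, and the observation count entering the posterior is
tempered (see :class:`ThompsonHyperParams`). Without these two corrections
the coupled two-layer game is not identifiable: all units of a layer
converge onto the common drift direction and the ensemble deadlocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import i0e

from .game import Stimulus
from .geometry import TWO_PI, wrap_angle

DEFAULT_ALPHA_WEIGHTS = (0.51, 1.03, 0.89)


@dataclass
class ThompsonHyperParams:
    """Shared hyper-parameters of a group of Thompson units.

    ``rho`` (sigmoid slope) and ``epsilon`` (exploration probability) are the
    values used for the model simulations; ``alpha_weights`` are the learning
    weights applied at lags 0, 1, 2 of the unit's own actions.

    ``press_cost`` is a fixed effort intercept subtracted from the expected
    activation utility before the sigmoid: pressing a button is not free, and
    without the intercept an uninformed unit presses on half of its decision
    slots, which contradicts the sparse pressing the game's players actually
    show and floods the shared cursor with noise.

    The last three parameters calibrate how raw cursor displacements are
    turned into belief observations (see :meth:`ThompsonUnit.observe`):
    ``baseline_decay`` sets the memory of the running mean movement that is
    subtracted from each displacement (credit assignment against the ambient
    group drift), ``contrast_threshold`` drops steps whose movement is not
    discernibly different from that baseline, and ``evidence_discount``
    tempers the observation count entering the posterior - the iid von Mises
    likelihood badly overstates the evidence carried by multi-agent
    displacement data, where most angular variance is exogenous.
    """

    rho: float = 2.73
    epsilon: float = 0.23
    alpha_weights: tuple = DEFAULT_ALPHA_WEIGHTS
    press_cost: float = 1.0
    baseline_decay: float = 0.05
    contrast_threshold: float = 0.8
    evidence_discount: float = 0.15
    kappa_grid_size: int = 512
    kappa_max: float = 500.0
    utility_grid_size: int = 720

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")
        w = np.asarray(self.alpha_weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("alpha_weights must be nonnegative and not all zero")

    @property
    def sensitive_window(self) -> int:
        return len(self.alpha_weights)


@dataclass
class DirectionBelief:
    """Sufficient statistics of the directional posterior."""

    a: float = 0.0
    b: float = 0.0
    weight_T: float = 0.0

    @property
    def R(self) -> float:
        return math.hypot(self.a, self.b)

    @property
    def theta(self) -> float:
        """Resultant angle in [0, 2*pi); nan when R = 0 (no information)."""
        if self.R < 1e-12:
            return float("nan")
        return math.atan2(self.b, self.a) % TWO_PI

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "weight_T": self.weight_T}


@dataclass
class SampledVonMises:
    """One posterior draw: mean direction and concentration."""

    mu_hat: float
    kappa_hat: float

    def __post_init__(self) -> None:
        if self.kappa_hat < 0:
            raise ValueError("kappa_hat must be >= 0")
        self.mu_hat = wrap_angle(self.mu_hat)


def learning_weight(recent_own_actions, hyper: ThompsonHyperParams) -> float:
    """alpha(t) = w0*A_t + w1*A_{t-1} + w2*A_{t-2}.

    ``recent_own_actions`` is ordered oldest-first with the current action
    last; missing history counts as idle.
    """
    w = hyper.alpha_weights
    acts = list(recent_own_actions)[-len(w) :]
    acts = [0] * (len(w) - len(acts)) + acts
    return float(sum(w[lag] * acts[-1 - lag] for lag in range(len(w))))


def update_belief(
    belief: DirectionBelief,
    observed_angle: float,
    weight: float,
    count_weight: Optional[float] = None,
) -> DirectionBelief:
    """Incorporate one observed displacement angle with weight alpha(t).

    ``count_weight`` (defaults to ``weight``) is what enters the accumulated
    observation count T; the playable unit passes a tempered count.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if weight == 0:
        return belief
    belief.a += weight * math.cos(observed_angle)
    belief.b += weight * math.sin(observed_angle)
    belief.weight_T += weight if count_weight is None else count_weight
    return belief


# ---------------------------------------------------------------------------
# Posterior over (mu, kappa)

_GRID_CACHE: dict = {}


def kappa_grid(size: int = 512, kappa_max: float = 500.0):
    """Log-spaced kappa grid on (1e-3, kappa_max] with trapezoid widths."""
    key = (size, kappa_max)
    cached = _GRID_CACHE.get(key)
    if cached is None:
        grid = np.logspace(-3, math.log10(kappa_max), size)
        edges = np.empty(size + 1)
        edges[1:-1] = 0.5 * (grid[1:] + grid[:-1])
        edges[0] = 0.0
        edges[-1] = kappa_max
        widths = np.diff(edges)
        log_i0 = np.log(i0e(grid)) + grid  # log I0 without overflow
        cached = (grid, widths, log_i0)
        _GRID_CACHE[key] = cached
    return cached


def posterior_kappa_probabilities(
    belief: DirectionBelief, hyper: Optional[ThompsonHyperParams] = None
):
    """Grid, and normalised probabilities of the kappa marginal
    p(kappa | R, T) ~ I0(R*kappa) / I0(kappa)**T on the truncated grid
    (probabilities include the trapezoid bin widths)."""
    hyper = hyper or ThompsonHyperParams()
    grid, widths, log_i0 = kappa_grid(hyper.kappa_grid_size, hyper.kappa_max)
    r, t = belief.R, belief.weight_T
    logw = (np.log(i0e(r * grid)) + r * grid) - t * log_i0 + np.log(widths)
    if r >= t and t > 0:
        warnings.warn(
            "kappa marginal is improper (R >= T); truncating at kappa_max",
            RuntimeWarning,
            stacklevel=2,
        )
    logw -= logw.max()
    w = np.exp(logw)
    return grid, w / w.sum()


def sample_posterior(
    belief: DirectionBelief,
    rng: np.random.Generator,
    hyper: Optional[ThompsonHyperParams] = None,
) -> SampledVonMises:
    """Draw (mu, kappa) from the joint posterior.

    kappa is drawn from its grid-discretised marginal, then mu from the
    conditional von Mises with mean Theta and concentration R*kappa. A belief
    with zero accumulated weight carries no information and yields a uniform
    mu with kappa = 0.
    """
    if belief.weight_T <= 0:
        return SampledVonMises(rng.uniform(0.0, TWO_PI), 0.0)
    grid, probs = posterior_kappa_probabilities(belief, hyper)
    kappa = float(grid[np.searchsorted(np.cumsum(probs), rng.random())])
    conc = belief.R * kappa
    if conc <= 0 or math.isnan(belief.theta):
        mu = rng.uniform(0.0, TWO_PI)
    else:
        mu = wrap_angle(float(rng.vonmises(belief.theta - math.pi, conc)) + math.pi)
    return SampledVonMises(mu, kappa)


def sample_posterior_kappas(
    belief: DirectionBelief,
    rng: np.random.Generator,
    n: int,
    hyper: Optional[ThompsonHyperParams] = None,
) -> np.ndarray:
    """Vectorised draw of ``n`` kappa values from the marginal (for tests
    and batched response-profile probing)."""
    grid, probs = posterior_kappa_probabilities(belief, hyper)
    return grid[np.searchsorted(np.cumsum(probs), rng.random(n)).clip(max=len(grid) - 1)]


# ---------------------------------------------------------------------------
# Expected activation utility and the decision rule

_UTILITY_CACHE: dict = {}


def _utility_grid(n: int):
    cached = _UTILITY_CACHE.get(n)
    if cached is None:
        offsets = np.arange(n) * (TWO_PI / n)
        dist = np.minimum(offsets, TWO_PI - offsets)  # distance from stimulus
        cached = (offsets, dist)
        _UTILITY_CACHE[n] = cached
    return cached


def expected_activation_utility(
    sample: SampledVonMises, stimulus: float, n_grid: int = 720
) -> float:
    """f = pi/2 - E[angular distance(stimulus, v)], v ~ VM(mu_hat, kappa_hat).

    Quadrature over ``n_grid`` equally spaced displacement directions anchored
    at the stimulus, so a flat belief gives exactly f = 0.
    """
    offsets, dist = _utility_grid(n_grid)
    kappa = sample.kappa_hat
    if kappa == 0:
        return 0.0
    # pdf ~ exp(kappa * cos(stimulus + offset - mu)); max-subtracted for stability
    c = np.cos((stimulus - sample.mu_hat) + offsets)
    w = np.exp(kappa * (c - 1.0))
    return float(math.pi / 2.0 - (w @ dist) / w.sum())


def activation_probability(f: float, hyper: ThompsonHyperParams) -> float:
    """Press probability: epsilon-greedy coin, else sigmoid(rho * f)."""
    sig = 1.0 / (1.0 + math.exp(-hyper.rho * f))
    return hyper.epsilon * 0.5 + (1.0 - hyper.epsilon) * sig


def decide(f: float, hyper: ThompsonHyperParams, rng: np.random.Generator) -> int:
    """Sample the binary action: with probability epsilon a fair coin,
    otherwise Bernoulli(sigmoid(rho * f))."""
    if rng.random() < hyper.epsilon:
        return int(rng.random() < 0.5)
    sig = 1.0 / (1.0 + math.exp(-hyper.rho * f))
    return int(rng.random() < sig)


# ---------------------------------------------------------------------------
# The playable unit


class ThompsonUnit:
    """One Thompson-sampling decision unit (sensor or actor).

    Satisfies the agent contract of :mod:`nng.game`.
    """

    def __init__(
        self,
        hyper: Optional[ThompsonHyperParams] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.hyper = hyper or ThompsonHyperParams()
        self.rng = rng if rng is not None else np.random.default_rng()
        self.belief = DirectionBelief()
        self._history: list = []
        self._baseline = np.zeros(2)

    # -- acting ------------------------------------------------------------
    def decide(self, stimulus: Optional[Stimulus]) -> int:
        if stimulus is None:
            self._push(0)
            return 0
        angle = stimulus.angle if isinstance(stimulus, Stimulus) else float(stimulus)
        sample = sample_posterior(self.belief, self.rng, self.hyper)
        f = expected_activation_utility(sample, angle, self.hyper.utility_grid_size)
        action = decide(f - self.hyper.press_cost, self.hyper, self.rng)
        self._push(action)
        return action

    def forced_idle(self) -> int:
        self._push(0)
        return 0

    def _push(self, action: int) -> None:
        self._history.append(action)
        if len(self._history) > self.hyper.sensitive_window:
            del self._history[0]

    # -- learning ----------------------------------------------------------
    def observe(self, feedback) -> None:
        """Incorporate one step's own-screen cursor displacement.

        The displacement direction is credited against a slowly adapting
        baseline (the unit's running estimate of the ambient group movement):
        the belief is updated with the direction of the *contrast* between
        the observed movement and that baseline, weighted by the lagged
        learning rate alpha(t) of the unit's own recent actions. Steps whose
        movement is indistinguishable from the baseline (contrast below
        ``contrast_threshold``) carry no credit, and the observation count is
        tempered by ``evidence_discount``. Zero-displacement steps are
        skipped entirely.
        """
        disp = feedback.displacement
        dx, dy = float(disp[0]), float(disp[1])
        mag = math.hypot(dx, dy)
        if mag == 0.0:
            return
        ux, uy = dx / mag, dy / mag
        weight = learning_weight(self._history, self.hyper)
        if weight > 0:
            cx = ux - self._baseline[0]
            cy = uy - self._baseline[1]
            cm = math.hypot(cx, cy)
            if cm >= self.hyper.contrast_threshold:
                update_belief(
                    self.belief,
                    math.atan2(cy, cx),
                    weight,
                    count_weight=weight * self.hyper.evidence_discount,
                )
        d = self.hyper.baseline_decay
        self._baseline[0] = (1.0 - d) * self._baseline[0] + d * ux
        self._baseline[1] = (1.0 - d) * self._baseline[1] + d * uy

    def reset(self) -> None:
        self.belief = DirectionBelief()
        self._history = []
        self._baseline = np.zeros(2)

    # -- inspection ---------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "belief": self.belief.to_dict(),
            "history": list(self._history),
            "baseline": self._baseline.tolist(),
        }

    def probe_actions(self, angles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Frozen-belief batched decisions for response-profile probing.

        No learning and no history recording; one fresh posterior draw per
        probe, matching :meth:`decide` in distribution.
        """
        angles = np.asarray(angles, dtype=float)
        n = angles.size
        kappas = sample_posterior_kappas(self.belief, rng, n, self.hyper)
        if self.belief.weight_T <= 0:
            kappas = np.zeros(n)
        conc = self.belief.R * kappas
        theta = self.belief.theta
        if math.isnan(theta):
            mus = rng.uniform(0.0, TWO_PI, size=n)
        else:
            mus = (rng.vonmises(theta - math.pi, np.maximum(conc, 1e-12)) + math.pi) % TWO_PI
            mus = np.where(conc > 0, mus, rng.uniform(0.0, TWO_PI, size=n))
        offsets, dist = _utility_grid(self.hyper.utility_grid_size)
        f = np.empty(n)
        chunk = 2048
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            c = np.cos((angles[lo:hi] - mus[lo:hi])[:, None] + offsets[None, :])
            w = np.exp(kappas[lo:hi, None] * (c - 1.0))
            f[lo:hi] = math.pi / 2.0 - (w * dist).sum(axis=1) / w.sum(axis=1)
        sig = 1.0 / (1.0 + np.exp(-self.hyper.rho * (f - self.hyper.press_cost)))
        p = self.hyper.epsilon * 0.5 + (1.0 - self.hyper.epsilon) * sig
        return (rng.random(n) < p).astype(np.int8)


def make_ensemble(
    config, hyper: Optional[ThompsonHyperParams] = None, rng: Optional[np.random.Generator] = None
):
    """Fresh (sensor_units, actor_units) lists for one game config."""
    rng = rng if rng is not None else np.random.default_rng()
    hyper = hyper or ThompsonHyperParams()
    sensors = [ThompsonUnit(hyper, np.random.default_rng(rng.integers(2**31))) for _ in range(config.n_sensors)]
    actors = [ThompsonUnit(hyper, np.random.default_rng(rng.integers(2**31))) for _ in range(config.n_actors)]
    return sensors, actors
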